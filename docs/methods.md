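# Methods

`geograin` implements a geostatistical surveillance workflow for mapping
micronutrient concentrations (Ca, Fe, Se, Zn) in staple-crop grain from
georeferenced point surveys, and for linking those concentrations to
human-status biomarkers and to soil/environmental covariates. This note
records the models, the numerical choices, and what the synthetic testbed
does and does not establish.

## Analysis scale

Grain element concentrations are often right-skewed, approximately
log-normal. Before any spatial analysis the package decides the working
scale from the **octile skewness**

    skew_8 = (O7 + O1 − 2 O4) / (O7 − O1),

with O1, O4, O7 the 12.5th, 50th and 87.5th percentiles. Data stay on the
original mg kg⁻¹ scale when skew_8 ∈ [−0.2, 0.2] (closed interval). A log_e
transform is applied only when skew_8 is positive, outside the interval,
*and* reduces the absolute skewness — left-skewed data are never
transformed. Percentiles use linear interpolation of order statistics
(type 7); the convention is recorded in the run metadata because the rule's
boundary behaviour depends on it.

## Variograms

Spatial dependence is summarised by the semivariogram γ(h) on great-circle
distances (single haversine metric, sphere radius 6,378,137 m, used
identically in every module). Three lag-binned estimators are available:
Matheron's classical estimator, and the Cressie–Hawkins and Dowd robust
estimators, which resist both marginal outliers and spatial outliers (e.g.
mis-located samples). Bins are half-open `[lower, upper)` km, contiguous
from zero; each bin is represented by the mean distance of its member
pairs, not the midpoint. Defaults follow surveillance practice at regional
scale: 10-km bins to a maximum lag of order one third of the domain.

The **exponential model** γ(h) = c₀ + c(1 − e^(−h/a)) is fitted by weighted
least squares with weights w_j = N_j / γ(h_j; θ)², refreshed over three
reweighting rounds; plain N_j weighting is available by option. The
exponential family is used because it guarantees positive-definite
covariance matrices for great-circle distances on the sphere. The optimizer
is bounded L-BFGS-B from five starting points derived from the bin
statistics (nugget from the first bin, sill from the tail mean, a =
max-lag/3) with multiplicative perturbations; ties break by lowest weighted
RSS then lowest nugget. A fit with c ≈ 0 is returned flagged as degenerate
(pure nugget) rather than rejected.

The identity of the robust pair is a documented package choice:
Cressie–Hawkins and Dowd are the two robust estimators conventionally used
alongside Matheron's in this style of survey analysis. The Cressie–Hawkins
bias correction is applied in its two-term form 2(0.457 + 0.494/N).

## Ordinary, block and cross-validated kriging

Prediction uses global ordinary kriging (locally constant unknown mean):
solve `[Γ 1; 1ᵀ 0][λ; ψ] = [γ₀; 1]`, predict Σλᵢzᵢ, with kriging variance
σ²ₖ = Σλᵢγ₀ᵢ + ψ. The default neighbourhood is *all* observations; a
nearest-n option (for large n) restricts the system per target. For grids
the augmented matrix is factorised once and solved against all right-hand
sides. Kriging variances in (−10⁻⁸, 0) from rounding are clipped to zero.

Model validity is tested by leave-one-out cross-validation through the
standardized squared prediction error θᵢ = (zᵢ − Ẑ₋ᵢ)²/σ²ₖ,₋ᵢ. Under a
valid model with Gaussian errors θ ~ χ²₁, whose median is 0.455. The sample
median is compared with a distribution-free acceptance interval obtained by
mapping the Beta((n+1)/2, (n+1)/2) order-statistic quantiles of the sample
median through the χ²₁ quantile function. Model selection keeps the
Matheron fit outright when it validates (it is the statistically efficient
estimator); otherwise the robust fits are cross-validated and the one with
median SSPE closest to 0.455 is taken, with a warning when none validates.

For log-scale analyses the point prediction map is back-transformed by
exponentiation — a median-unbiased predictor appropriate for skewed
variables — while the kriging variance stays on the log_e scale, since a
kriging variance cannot be meaningfully back-transformed.

Block kriging predicts the spatial mean over a polygon (e.g. an
administrative unit) by discretizing its interior on a regular lon/lat
grid (default 1-km spacing or ≥ 100 nodes, refined automatically; polygon
holes respected) and replacing point semivariances with point-to-block and
within-block means; the block variance subtracts γ̄(B,B). A one-node block
reduces exactly to point kriging, which is tested.

## Uncertainty masking and dietary surfaces

Map nodes where the kriging variance exceeds (strictly) 75% of the data
variance are masked as too uncertain to display; the fraction is
configurable. Dietary contribution is computed nodewise as

    percent of EAR = 100 · concentration · (intake/1000) / EAR,

with FAO per-capita intakes (wheat 97.6, teff 89.3, maize 342.8 g day⁻¹)
and EARs for an adult woman aged 18–24 on an unrefined high-phytate diet
(Ca 860 mg, Fe 22.4 mg, Zn 10.2 mg, Se 45 µg day⁻¹). The selenium
requirement is deliberately on the microgram scale to match µg kg⁻¹ grain
Se concentrations; pairing a mg-scale Se EAR with µg kg⁻¹ concentrations
is rejected as a unit error rather than silently rescaled. Percentages are
not capped at 100. Display classes are quartiles of the unmasked nodes.

## Spatial linear mixed models

Biomarker and covariate analyses use y = Xβ + u + e with u a
Matérn-correlated Gaussian random effect,

    ρ(h) = 2^(1−ν)/Γ(ν) · (h/φ)^ν K_ν(h/φ),

and e iid noise. ν = 0.5 recovers the exponential model, making the LMM
covariance exactly the simulator's. The Matérn is evaluated in log space
via the scaled Bessel function; extreme smoothness falls back to the
Gaussian limit exp(−h²/(4νφ²)) with a warning. Variance parameters are
estimated by REML (or ML) through L-BFGS-B on (log σ²ₛ, log σ²ₙ, log φ)
from three data-driven starts; the weakly identified smoothness ν is
profiled over the grid {0.25, 0.5, 1, 2} rather than optimised
continuously, keeping fits reproducible. Ties break by highest likelihood
then smallest φ. Fixed effects and their standard errors come from
generalised (weighted) least squares at the estimated covariance.

Nested mean structures are compared by L = 2(ℓ_full − ℓ_null) against
χ² — ML fits only, since REML likelihoods are not comparable across fixed
effects. Covariate screening is forward selection in a stated order
(environment: precipitation, temperature, topographic index; soil: pH,
organic carbon), provisional retention at p < 0.05, followed by
Benjamini–Hochberg FDR control at 0.05 over all tests performed and a
final refit with the survivors. Enumeration-area biomarker means are
linked to the great-circle-nearest grain sample (any crop), unweighted by
enumeration-area sample size.

## Synthetic testbed

The generator reproduces the statistical structure the analysis assumes:
Gaussian or log-Gaussian fields with nugget + exponential covariance
(dense Cholesky with diagonal jitter 10⁻¹⁰ × sill; a pure-nugget model
takes an iid fast path so 10⁴-point draws need no dense matrix), survey
geometries with spread main sites plus close pairs at 100–1,000 m (the
close pairs exist to pin down short-range structure, i.e. the nugget),
covariates linked linearly to a response with a Matérn residual field, and
enumeration-area biomarker means regressed on nearest-grain concentration.
Main-site spread uses compact-strata coverage sampling — k-means strata on
a dense uniform candidate set, centroids as sites — rather than
inclusion-probability balanced sampling: the artifact tests estimation and
prediction, which need spread plus close pairs, not design-based
inference machinery. Strata are compact but only approximately
equal-count. A plain-random variant of the same design is provided for
large simulation experiments where the k-means partition would dominate
runtime, and serves as the baseline that coverage sampling is compared
against. Enumeration-area centroids are uniform in the frame (a neutral
choice; real enumeration areas are not a simple random sample).
Coordinates are generated in a mid-latitude band to avoid metric
distortion near the poles. All generators are byte-reproducible from
their seed.

What the synthetic tests do **not** show: behaviour under laboratory
measurement-error structure (detection limits, digestion batches),
cropland-mask/road-access sampling bias, or non-stationary real-world
fields; passing recovery tests demonstrates the estimators work under the
stated model, not that any particular real survey satisfies it.

## Simulation sizes and tolerances

Recovery experiments use sizes at which the checked property is actually
identified, chosen once by repeated simulation:

* Variogram WLS recovery: 2,000-point surveys (1,800 main + 200 close
  pairs) in a 300-km square, truth c₀ = 0.2, c = 0.8, a = 30 km, 10-km
  bins to 150 km. Single-field estimates of c₀ and a fluctuate by 30–50%
  (few independent correlation ranges fit in the domain), so recovery is
  asserted on estimates averaged over five replicate fields, within 25%.
* SSPE calibration: leave-one-out on 500-point fields under the true
  model; the median-SSPE verdict is `consistent` in ≥ 90% of 20 seeds.
* Biomarker slope: generative slope 0.09 (log biomarker per mg kg⁻¹ grain
  Se) recovered within 2 estimated SEs in ≥ 90% of 20 replicates at 300
  enumeration areas.
* LRT calibration: null rejection rate in [0.03, 0.08] over 200
  simulations of n = 100. Simulation-heavy checks fix ν = 0.5 (the
  generative truth) and use reduced multi-starts; interactive fits default
  to the full ν grid.
* The median-unbiasedness of the log back-transform is asserted on the
  ratio of holdout medians averaged over five replicate fields, because a
  single 200-site holdout median carries ~10% sampling noise.

## Known limitations

* No anisotropy, nested variogram structures, or REML-based variogram
  estimation; no lognormal kriging variance correction, co-kriging, or
  external drift.
* The octile-skewness percentile convention is fixed (type 7); other
  conventions shift boundary cases.
* Joint multi-nutrient spatial models are out of scope.
* GeoTIFF export and figure styling are not part of the tested surface;
  long-format CSV is the canonical map format.
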