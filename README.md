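# geograin

Geostatistical mapping of micronutrient concentrations (Ca, Fe, Se, Zn) in
staple-crop grain, for micronutrient-deficiency surveillance. Given a
georeferenced grain survey, `geograin` estimates spatial structure with
robust variograms, produces kriged concentration maps with uncertainty
masks, converts them into dietary percent-of-EAR surfaces, aggregates to
administrative units by block kriging, and fits spatial mixed models
linking grain concentrations to biomarkers and to soil/environmental
covariates. A synthetic-survey generator with known ground truth makes
every stage testable end to end.

It is aimed at biostatisticians and nutrition-surveillance analysts working
with national-scale crop surveys (hundreds to thousands of samples over
10–300 km correlation ranges).

## The model

Concentrations z(x) (log_e-transformed when the octile skewness
(O₇ + O₁ − 2O₄)/(O₇ − O₁) indicates positive skew outside [−0.2, 0.2]) are
treated as a stationary random field with exponential semivariogram on
great-circle distances,

    γ(h) = c₀ + c (1 − e^(−h/a)),

estimated by Matheron's estimator plus the Cressie–Hawkins and Dowd robust
alternatives in 10-km lag bins, fitted by weighted least squares
(w_j = N_j/γ(h_j)²). A fitted model is accepted when the leave-one-out
standardized squared prediction error θᵢ = (zᵢ − Ẑ₋ᵢ)²/σ²ₖ,₋ᵢ has median
compatible with 0.455, the median of χ²₁. Prediction is ordinary (point or
block) kriging; log-scale predictions are back-transformed by
exponentiation (median-unbiased), and nodes whose kriging variance exceeds
75% of the data variance are masked. Dietary supply per node is
100 · ẑ · (intake/1000)/EAR. Biomarker and covariate links use the linear
mixed model y = Xβ + u + e with Matérn-correlated u (REML/ML, ν profiled
over a grid), likelihood-ratio tests, and forward covariate selection with
Benjamini–Hochberg FDR control. Details and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import pandas as pd
import geograin as gg

# synthetic maize survey with known truth: log-normal field,
# c0 = 0.2, c = 0.8, a = 30 km on the log_e scale
design = gg.SurveyDesign(gg.square_frame(side_km=300), n_main=300,
                         n_close_pairs=30, seed=42)
spec = gg.FieldSpec(mean=3.0, model=gg.VariogramModel(0.2, 0.8, 30.0),
                    log_scale=True, seed=42)
survey = gg.generate_grain_survey(design, spec, crop="maize")

decision = gg.choose_scale(survey["value"])
work = survey.assign(value=np.log(survey["value"]))

emp = gg.empirical_variogram(work, max_lag_km=150, bin_width_km=10)
fit = gg.fit_exponential_wls(emp)
report = gg.cross_validate(work, fit.model)

grid = pd.DataFrame({"lon": np.repeat(np.linspace(36.2, 38.4, 12), 12),
                     "lat": np.tile(np.linspace(0.2, 2.4, 12), 12)})
gmap = gg.krige_grid(work, fit.model, grid, scale="log_e")
mask = gg.variance_mask(gmap["variance"], float(np.var(work["value"], ddof=1)))
pct = gg.percent_ear_for(gg.IntakeEarTable(), "maize", "Zn", gmap["prediction"])
```

This prints (via the corresponding f-strings):

```
octile skewness 0.443 -> scale: log_e
fitted exponential model: c0=0.230, c=0.602, a=33.2 km
median SSPE 0.378, 95% interval (0.351, 0.580) -> consistent
Zn percent-of-EAR over 144 unmasked nodes: median 64.9%, range 15.3-269.8%
```

Reading the output: the survey is right-skewed (octile skewness 0.44), so
the analysis runs on the log_e scale; the weighted-least-squares fit
recovers the generating variogram to within sampling error; the
cross-validation median SSPE 0.378 falls inside its 95% acceptance
interval, so the model is accepted; and at the default FAO maize intake
(342.8 g day⁻¹) and Zn EAR (10.2 mg day⁻¹) the mapped grain would meet a
median 65% of the zinc requirement, exceeding 100% in the richest areas.

The same workflow is scriptable from the shell (`geograin simulate`,
`explore`, `variogram`, `validate`, `krige`, `blockkrige`, `dietary`,
`lmm`, or `geograin run --config run.yaml` for the full pipeline).

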