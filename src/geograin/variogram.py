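"""Empirical variogram estimation and exponential-model fitting.

Three estimators of the semivariance are provided for lag-binned pair
differences d_i within a bin holding N pairs:

* ``matheron`` (standard):      gamma = sum(d_i^2) / (2 N)
* ``cressie_hawkins`` (robust): gamma = (mean |d_i|^(1/2))^4 / (2 (0.457 + 0.494/N))
* ``dowd`` (robust):            gamma = 2.198 * median(|d_i|)^2 / 2

The robust pair resists both marginal and spatial outliers. Lags are
great-circle distances in km; the exponential model
``gamma(h) = c0 + c (1 - exp(-h/a))`` is fitted by weighted least squares
with weights N_j / gamma(h_j; theta)^2, iteratively reweighted. The
exponential family is used because it yields positive-definite covariances
for distances on the sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, kve

from .distance import pairwise_distances

ESTIMATORS = ("matheron", "cressie_hawkins", "dowd")


@dataclass(frozen=True)
class VariogramModel:
    """Exponential nugget model: gamma(h) = c0 + c (1 - exp(-h/a)).

    Parameters
    ----------
    nugget : float
        c0, variance at vanishing lag (squared value units), >= 0.
    partial_sill : float
        c, spatially structured variance (squared value units), >= 0.
    range_a : float
        Distance parameter a in km (> 0); effective range ~ 3a.
    scale : str
        Analysis scale of the values the model describes.
    """

    nugget: float
    partial_sill: float
    range_a: float
    scale: str = "original"

    def __post_init__(self):
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.partial_sill > 0 and not self.range_a > 0:
            raise ValueError("distance parameter a must be > 0 when partial sill > 0")
        if self.range_a <= 0:
            object.__setattr__(self, "range_a", 1.0)  # inert when c == 0

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def to_dict(self) -> dict:
        return {"nugget": float(self.nugget), "partial_sill": float(self.partial_sill),
                "range_a_km": float(self.range_a), "scale": self.scale}


def exponential_semivariance(h_km, model: VariogramModel):
    """gamma(h) of the exponential model; gamma(0) = 0 by variogram convention."""
    h = np.asarray(h_km, dtype=float)
    if np.any(h < 0):
        raise ValueError("negative lag distance")
    g = model.nugget + model.partial_sill * (1.0 - np.exp(-h / model.range_a))
    g = np.where(h == 0.0, 0.0, g)
    return g if g.ndim else float(g)


def exponential_covariance(h_km, model: VariogramModel):
    """Covariance C(h) = sill - gamma(h): c0 + c at h = 0, c exp(-h/a) beyond."""
    h = np.asarray(h_km, dtype=float)
    c = model.partial_sill * np.exp(-h / model.range_a)
    c = np.where(h == 0.0, model.nugget + model.partial_sill, c)
    return c if c.ndim else float(c)


@dataclass
class EmpiricalVariogram:
    """Lag-binned semivariance estimates gamma_hat(h) with pair counts N(h).

    Bins are half-open [lower, upper) km, contiguous from 0 to max_lag.
    Empty bins keep NaN semivariance and count 0 and are excluded from
    fitting. ``lag`` is the mean pair distance within the bin, not the
    midpoint.
    """

    bin_lower: np.ndarray
    bin_upper: np.ndarray
    lag: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    estimator: str
    bin_width: float
    max_lag: float
    scale: str = "original"

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "bin_lower_km": self.bin_lower, "bin_upper_km": self.bin_upper,
            "lag_km": self.lag, "semivariance": self.gamma, "n_pairs": self.counts,
        })

    def plot(self, ax=None, model: VariogramModel | None = None, **kwargs):
        """Scatter the estimates (optionally with a fitted model curve)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        occ = self.occupied
        ax.plot(self.lag[occ], self.gamma[occ], "o", **kwargs)
        if model is not None:
            hh = np.linspace(1e-9, self.max_lag, 200)
            ax.plot(hh, exponential_semivariance(hh, model), "-")
        ax.set_xlabel("lag (km)")
        ax.set_ylabel("semivariance")
        ax.set_title(f"{self.estimator} variogram")
        return ax


def _semivariance_of_diffs(d: np.ndarray, estimator: str) -> float:
    n = d.size
    if estimator == "matheron":
        return float(np.sum(d * d) / (2.0 * n))
    if estimator == "cressie_hawkins":
        m = np.mean(np.sqrt(np.abs(d)))
        return float(m ** 4 / (2.0 * (0.457 + 0.494 / n)))
    if estimator == "dowd":
        return float(2.198 * np.median(np.abs(d)) ** 2 / 2.0)
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def empirical_variogram(samples, max_lag_km: float, bin_width_km: float = 10.0,
                        estimator: str = "matheron") -> EmpiricalVariogram:
    """Estimate the variogram from all point pairs up to ``max_lag_km``.

    Parameters
    ----------
    samples : DataFrame
        Columns ``lon``, ``lat`` (decimal degrees) and ``value`` on the
        analysis scale.
    max_lag_km, bin_width_km : float
        Lag bins are [0, w), [w, 2w), ... up to max_lag; max_lag must be a
        positive multiple of the width.
    estimator : str
        One of ``matheron``, ``cressie_hawkins``, ``dowd``.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if not (max_lag_km > 0 and bin_width_km > 0):
        raise ValueError("max_lag and bin width must be positive")
    n_bins = max_lag_km / bin_width_km
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("max_lag must be a positive multiple of bin_width")
    n_bins = int(round(n_bins))

    lon = np.asarray(samples["lon"], dtype=float)
    lat = np.asarray(samples["lat"], dtype=float)
    z = np.asarray(samples["value"], dtype=float)
    if lon.size < 30:
        warnings.warn(f"only {lon.size} samples; variogram estimates will be noisy",
                      stacklevel=2)

    d_km = pairwise_distances(lon, lat) / 1000.0
    iu = np.triu_indices(lon.size, k=1)
    h = d_km[iu]
    dz = z[iu[0]] - z[iu[1]]
    keep = h < max_lag_km
    h, dz = h[keep], dz[keep]

    edges = np.arange(n_bins + 1) * bin_width_km
    idx = np.minimum((h // bin_width_km).astype(int), n_bins - 1)

    lag = np.full(n_bins, np.nan)
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        n = int(np.count_nonzero(sel))
        counts[b] = n
        if n:
            lag[b] = float(np.mean(h[sel]))
            gamma[b] = _semivariance_of_diffs(dz[sel], estimator)
    if not counts.any():
        raise ValueError("no point pairs within max_lag: all bins empty")

    scale = samples.attrs.get("scale", "original") if hasattr(samples, "attrs") else "original"
    return EmpiricalVariogram(edges[:-1], edges[1:], lag, gamma, counts,
                              estimator, bin_width_km, max_lag_km, scale)


@dataclass
class VariogramFit:
    """A fitted exponential model plus weighted-least-squares diagnostics."""

    model: VariogramModel
    weighted_rss: float
    converged: bool
    n_bins: int
    message: str = ""
    degenerate: bool = False  # c ~ 0 (pure nugget) fit

    def to_dict(self) -> dict:
        d = self.model.to_dict()
        d.update(weighted_rss=float(self.weighted_rss), converged=bool(self.converged),
                 n_bins=int(self.n_bins), degenerate=bool(self.degenerate))
        return d


def _wls_objective(theta, h, g, n, weights):
    c0, c, a = theta
    fit = c0 + c * (1.0 - np.exp(-h / a))
    return float(np.sum(weights * (g - fit) ** 2))


def fit_exponential_wls(emp: EmpiricalVariogram, init: VariogramModel | None = None,
                        weight_scheme: str = "npairs_over_gamma2",
                        reweight_rounds: int = 3,
                        n_starts: int = 5) -> VariogramFit:
    """Fit the exponential model to an empirical variogram by weighted LS.

    Minimises sum_j w_j (gamma_hat_j - gamma(h_j; c0, c, a))^2 over
    c0 >= 0, c >= 0, a > 0. Default weights w_j = N_j / gamma(h_j; theta)^2
    are refreshed over ``reweight_rounds`` rounds (theta from the previous
    round); ``weight_scheme="npairs"`` uses plain w_j = N_j. A bounded
    quasi-Newton search is run from ``n_starts`` perturbed auto-inits
    (plus ``init`` if given); ties break by lowest weighted RSS then lowest
    nugget.
    """
    occ = emp.occupied
    h = emp.lag[occ]
    g = emp.gamma[occ]
    n = emp.counts[occ].astype(float)
    if h.size < 3:
        raise ValueError("need at least 3 non-empty lag bins to fit")
    if weight_scheme not in ("npairs_over_gamma2", "npairs"):
        raise ValueError("weight_scheme must be 'npairs_over_gamma2' or 'npairs'")

    gmax = float(np.max(g))
    scale = gmax if gmax > 0 else 1.0
    # auto-init from bin statistics: nugget from the first bin, sill from the tail
    sill0 = float(np.mean(g[-max(1, h.size // 3):]))
    c0_0 = float(np.clip(g[0], 1e-12 * scale, sill0))
    base = np.array([c0_0, max(sill0 - c0_0, 0.05 * scale), max(emp.max_lag / 3.0, emp.bin_width)])

    rng = np.random.default_rng(0)
    starts = [base]
    for k in range(max(0, n_starts - 1)):
        f = np.exp(rng.uniform(-1.2, 1.2, size=3))
        starts.append(base * f + np.array([0.0, 1e-12 * scale, 0.0]))
    if init is not None:
        starts.append(np.array([init.nugget, init.partial_sill, max(init.range_a, 1e-6)]))

    bounds = [(0.0, 10.0 * scale), (0.0, 10.0 * scale), (1e-6, 100.0 * emp.max_lag)]
    best = None
    for x0 in starts:
        theta = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        theta[2] = max(theta[2], 1e-6)
        res = None
        for _ in range(max(1, reweight_rounds)):
            if weight_scheme == "npairs":
                w = n.copy()
            else:
                gfit = np.maximum(theta[0] + theta[1] * (1.0 - np.exp(-h / theta[2])),
                                  1e-12 * scale)
                w = n / gfit ** 2
            res = minimize(_wls_objective, theta, args=(h, g, n, w),
                           method="L-BFGS-B", bounds=bounds)
            theta = res.x
        # score candidates under a common final weighting for comparability
        gfit = np.maximum(theta[0] + theta[1] * (1.0 - np.exp(-h / theta[2])), 1e-12 * scale)
        w_final = n / gfit ** 2 if weight_scheme == "npairs_over_gamma2" else n
        rss = _wls_objective(theta, h, g, n, w_final)
        cand = (rss, theta[0], theta, bool(res.success), res.message)
        if best is None or (cand[0], cand[1]) < (best[0], best[1]):
            best = cand
    rss, _, theta, ok, msg = best
    degenerate = theta[1] <= 1e-9 * scale
    if degenerate:
        warnings.warn("degenerate fit: partial sill ~ 0 (pure nugget)", stacklevel=2)
    model = VariogramModel(nugget=float(theta[0]), partial_sill=float(theta[1]),
                           range_a=float(theta[2]), scale=emp.scale)
    return VariogramFit(model=model, weighted_rss=float(rss), converged=ok,
                        n_bins=int(h.size), message=str(msg), degenerate=degenerate)


def matern_correlation(h_km, phi_km: float, nu: float):
    """Matern correlation rho(h) = 2^(1-nu)/Gamma(nu) (h/phi)^nu K_nu(h/phi).

    rho(0) = 1; monotone non-increasing in h; nu = 0.5 reduces to
    exp(-h/phi). Evaluated in log space via the scaled Bessel function; for
    extreme smoothness where that still overflows, the Gaussian-limit
    approximation exp(-h^2 / (4 nu phi^2)) is returned with a warning.
    """
    if not (phi_km > 0 and nu > 0):
        raise ValueError("phi and nu must be positive")
    h = np.asarray(h_km, dtype=float)
    if np.any(h < 0):
        raise ValueError("negative lag distance")
    u = h / phi_km
    out = np.ones_like(u)
    pos = u > 0
    if np.any(pos):
        up = u[pos]
        with np.errstate(over="ignore", invalid="ignore"):
            # log rho = (1-nu) log 2 - lgamma(nu) + nu log u + log K_nu(u)
            logk = np.log(kve(nu, up)) - up  # kve = K_nu(u) e^u
            logrho = (1.0 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(up) + logk
        vals = np.exp(logrho)
        bad = ~np.isfinite(vals)
        if np.any(bad):
            warnings.warn("Matern evaluation overflowed; using Gaussian-limit "
                          "approximation for extreme smoothness", stacklevel=2)
            vals[bad] = np.exp(-(up[bad] ** 2) / (4.0 * nu))
        out[pos] = np.clip(vals, 0.0, 1.0)
    return out if out.ndim else float(out)
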