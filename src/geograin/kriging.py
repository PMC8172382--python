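"""Ordinary kriging: point, grid and block prediction, LOO validation.

The ordinary kriging predictor at x0 is the linear combination
Z_hat(x0) = sum_i lambda_i z_i whose weights solve

    [ Gamma  1 ] [ lambda ]   [ gamma0 ]
    [ 1^T    0 ] [  psi   ] = [   1    ]

with Gamma the matrix of model semivariances between data points, gamma0
the semivariances between data and target, and psi a Lagrange multiplier
enforcing sum(lambda) = 1 (unbiasedness under a locally constant unknown
mean). The kriging variance sigma2_k = sum_i lambda_i gamma(x0, x_i) + psi
does not depend on the observed values.

Model validity is checked by leave-one-out cross-validation through the
standardized squared prediction error (SSPE)
theta_i = (z_i - Z_hat_{-i}(x_i))^2 / sigma2_{k,-i}; under a valid model
with Gaussian kriging errors theta is chi-square with 1 df, whose median is
0.455. The sample median is compared with a distribution-free
order-statistic 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import lu_factor, lu_solve

from .distance import cross_distances, pairwise_distances
from .variogram import VariogramModel, exponential_semivariance

#: Median of the squared standard normal (chi-square, 1 df).
SSPE_MEDIAN = float(stats.chi2.median(df=1))

_WEIGHT_TOL = 1e-8


@dataclass
class KrigingResult:
    prediction: float
    variance: float
    weights: np.ndarray
    lagrange: float


@dataclass
class ValidationReport:
    """Per-site SSPE values and the median test against its null interval."""

    sspe: np.ndarray
    median_sspe: float
    interval: tuple[float, float]
    verdict: str  # "consistent" | "inconsistent"
    n: int

    @property
    def consistent(self) -> bool:
        return self.verdict == "consistent"

    def to_dict(self) -> dict:
        return {"median_sspe": float(self.median_sspe),
                "interval_95": [float(self.interval[0]), float(self.interval[1])],
                "verdict": self.verdict, "n": int(self.n),
                "expected_median": SSPE_MEDIAN}


def median_sspe_interval(n: int, conf: float = 0.95) -> tuple[float, float]:
    """95% interval for the median of n iid squared-standard-normal draws.

    Distribution-free order-statistic construction: the sample median of n
    iid uniforms is Beta((n+1)/2, (n+1)/2); its conf-level quantiles are
    mapped through the chi-square(1) quantile function.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    a = (n + 1) / 2.0
    alpha = (1.0 - conf) / 2.0
    qlo, qhi = stats.beta.ppf([alpha, 1.0 - alpha], a, a)
    lo, hi = stats.chi2.ppf([qlo, qhi], df=1)
    return float(lo), float(hi)


def _gamma_matrix(lon, lat, model: VariogramModel) -> np.ndarray:
    h_km = pairwise_distances(lon, lat) / 1000.0
    return exponential_semivariance(h_km, model)


def _augmented_system(lon, lat, model: VariogramModel) -> np.ndarray:
    n = len(lon)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = _gamma_matrix(lon, lat, model)
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def _solve_ok(A: np.ndarray, rhs: np.ndarray, sites=None) -> np.ndarray:
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        msg = "singular ordinary kriging system"
        if sites is not None:
            msg += f" (check for duplicate sites with zero nugget among {sites})"
        raise np.linalg.LinAlgError(msg) from exc


def _clip_variance(v):
    v = np.asarray(v, dtype=float)
    v = np.where((v < 0) & (v > -1e-8), 0.0, v)
    return v if v.ndim else float(v)


def ordinary_krige(samples, model: VariogramModel, target,
                   neighborhood: int | None = None) -> KrigingResult:
    """Ordinary kriging prediction at one (lon, lat) target.

    ``neighborhood=None`` uses all observations (global kriging);
    an integer restricts the system to that many nearest data points.
    """
    lon = np.asarray(samples["lon"], dtype=float)
    lat = np.asarray(samples["lat"], dtype=float)
    z = np.asarray(samples["value"], dtype=float)
    if lon.size < 2:
        raise ValueError("ordinary kriging needs at least 2 samples")
    t_lon, t_lat = float(target[0]), float(target[1])
    h0_km = cross_distances([t_lon], [t_lat], lon, lat)[0] / 1000.0
    if neighborhood is not None and neighborhood < lon.size:
        keep = np.argsort(h0_km)[:neighborhood]
        lon, lat, z, h0_km = lon[keep], lat[keep], z[keep], h0_km[keep]
    n = lon.size
    A = _augmented_system(lon, lat, model)
    rhs = np.empty(n + 1)
    rhs[:n] = exponential_semivariance(h0_km, model)
    rhs[n] = 1.0
    ids = samples["site_id"].tolist() if "site_id" in getattr(samples, "columns", []) else None
    sol = _solve_ok(A, rhs, sites=ids)
    lam, psi = sol[:n], sol[n]
    if abs(lam.sum() - 1.0) > _WEIGHT_TOL:
        raise np.linalg.LinAlgError("kriging weights failed the unbiasedness "
                                    f"constraint (sum = {lam.sum():.3e})")
    pred = float(lam @ z)
    var = _clip_variance(lam @ rhs[:n] + psi)
    return KrigingResult(prediction=pred, variance=var, weights=lam, lagrange=float(psi))


def krige_points(samples, model: VariogramModel, targets,
                 neighborhood: int | None = None):
    """Kriging predictions and variances at many targets.

    With a global neighbourhood the augmented system is factorised once and
    solved for all targets; returns (predictions, variances) arrays aligned
    with ``targets`` rows (columns ``lon``, ``lat``).
    """
    lon = np.asarray(samples["lon"], dtype=float)
    lat = np.asarray(samples["lat"], dtype=float)
    z = np.asarray(samples["value"], dtype=float)
    t_lon = np.asarray(targets["lon"], dtype=float)
    t_lat = np.asarray(targets["lat"], dtype=float)
    n, m = lon.size, t_lon.size
    if neighborhood is not None and neighborhood < n:
        preds = np.empty(m)
        vars_ = np.empty(m)
        for j in range(m):
            r = ordinary_krige(samples, model, (t_lon[j], t_lat[j]), neighborhood)
            preds[j], vars_[j] = r.prediction, r.variance
        return preds, vars_
    A = _augmented_system(lon, lat, model)
    g0 = exponential_semivariance(cross_distances(lon, lat, t_lon, t_lat) / 1000.0, model)
    rhs = np.vstack([g0, np.ones(m)])
    lu = lu_factor(A)
    sol = lu_solve(lu, rhs)
    lam, psi = sol[:n, :], sol[n, :]
    if np.any(np.abs(lam.sum(axis=0) - 1.0) > _WEIGHT_TOL):
        raise np.linalg.LinAlgError("kriging weights failed the unbiasedness constraint")
    preds = lam.T @ z
    vars_ = _clip_variance(np.einsum("ij,ij->j", lam, g0) + psi)
    return preds, vars_


def cross_validate(samples, model: VariogramModel) -> ValidationReport:
    """Leave-one-out cross-validation of a variogram model by the SSPE."""
    lon = np.asarray(samples["lon"], dtype=float)
    lat = np.asarray(samples["lat"], dtype=float)
    z = np.asarray(samples["value"], dtype=float)
    n = lon.size
    if n < 10:
        raise ValueError("cross-validation needs at least 10 samples")
    G = _gamma_matrix(lon, lat, model)
    sspe = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = n - 1
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = G[np.ix_(keep, keep)]
        A[m, :m] = 1.0
        A[:m, m] = 1.0
        A[m, m] = 0.0
        rhs = np.empty(m + 1)
        rhs[:m] = G[keep, i]
        rhs[m] = 1.0
        sol = _solve_ok(A, rhs)
        lam, psi = sol[:m], sol[m]
        pred = lam @ z[keep]
        var = float(lam @ rhs[:m] + psi)
        if var <= 0.0:
            raise ValueError(f"zero kriging variance at site index {i}: "
                             "model degenerate for leave-one-out validation")
        sspe[i] = (z[i] - pred) ** 2 / var
    med = float(np.median(sspe))
    lo, hi = median_sspe_interval(n)
    verdict = "consistent" if lo <= med <= hi else "inconsistent"
    return ValidationReport(sspe=sspe, median_sspe=med, interval=(lo, hi),
                            verdict=verdict, n=n)


@dataclass
class ModelSelection:
    """Chosen variogram model with the cross-validation audit trail."""

    estimator: str
    model: VariogramModel
    reports: dict
    rationale: str
    warning: bool = False


def select_model(samples, candidates: dict) -> ModelSelection:
    """Select a variogram model by the cross-validation decision rule.

    ``candidates`` maps estimator name -> fitted VariogramModel and must
    include ``"matheron"``. The Matheron fit is kept outright when its
    median SSPE lies in the 95% interval (it is the statistically efficient
    estimator); otherwise the robust fits are cross-validated too and the
    one with median SSPE closest to the chi-square(1) median 0.455 is
    chosen, with a warning flag when none validates.
    """
    if "matheron" not in candidates:
        raise ValueError("candidates must include a 'matheron' fit")
    reports = {"matheron": cross_validate(samples, candidates["matheron"])}
    if reports["matheron"].consistent:
        return ModelSelection("matheron", candidates["matheron"], reports,
                              "Matheron fit consistent in cross-validation; "
                              "robust alternatives not considered")
    for name, mod in candidates.items():
        if name != "matheron":
            reports[name] = cross_validate(samples, mod)
    others = {k: v for k, v in reports.items() if k != "matheron"} or reports
    best = min(others, key=lambda k: abs(others[k].median_sspe - SSPE_MEDIAN))
    any_ok = any(r.consistent for r in reports.values())
    if not any_ok:
        warnings.warn("no candidate variogram model validates; returning the "
                      "closest-to-0.455 fit", stacklevel=2)
    rationale = ("Matheron fit inconsistent; selected the candidate with median "
                 f"SSPE closest to {SSPE_MEDIAN:.3f}")
    return ModelSelection(best, candidates[best], reports, rationale, warning=not any_ok)


def krige_grid(samples, model: VariogramModel, grid,
               scale: str = "original", neighborhood: int | None = None):
    """Ordinary kriging over grid nodes, with log back-transformation.

    Returns a DataFrame (lon, lat, prediction, variance). When
    ``scale == "log_e"`` the prediction column is the exponential of the
    log-scale kriging prediction — the median-unbiased back-transform —
    while the variance column stays on the log_e scale (a kriging variance
    cannot be meaningfully back-transformed). Nodes whose system fails are
    reported with NaN rather than aborting the map.
    """
    import pandas as pd

    t_lon = np.asarray(grid["lon"], dtype=float)
    t_lat = np.asarray(grid["lat"], dtype=float)
    if t_lon.size == 0:
        raise ValueError("empty prediction grid")
    try:
        preds, vars_ = krige_points(samples, model, grid, neighborhood)
    except np.linalg.LinAlgError:
        preds = np.full(t_lon.size, np.nan)
        vars_ = np.full(t_lon.size, np.nan)
        for j in range(t_lon.size):
            try:
                r = ordinary_krige(samples, model, (t_lon[j], t_lat[j]), neighborhood)
                preds[j], vars_[j] = r.prediction, r.variance
            except np.linalg.LinAlgError:
                pass  # node marked missing
    if scale == "log_e":
        preds = np.exp(preds)
    return pd.DataFrame({"lon": t_lon, "lat": t_lat,
                         "prediction": preds, "variance": vars_})


def discretize_polygon(polygon, spacing_km: float = 1.0, min_nodes: int = 100):
    """Regular lon/lat nodes covering a shapely polygon's interior.

    The grid spacing is refined (halved) until at least ``min_nodes``
    interior nodes exist or the spacing floor is hit; holes are excluded by
    the polygon's own containment test.
    """
    from shapely.geometry import Point

    minx, miny, maxx, maxy = polygon.bounds
    lat_mid = 0.5 * (miny + maxy)
    s = float(spacing_km)
    for _ in range(12):
        dlat = s / 111.195
        dlon = s / (111.195 * max(np.cos(np.radians(lat_mid)), 1e-6))
        xs = np.arange(minx + dlon / 2, maxx, dlon)
        ys = np.arange(miny + dlat / 2, maxy, dlat)
        if xs.size and ys.size:
            gx, gy = np.meshgrid(xs, ys)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            inside = np.fromiter((polygon.contains(Point(x, y)) for x, y in pts),
                                 dtype=bool, count=len(pts))
            nodes = pts[inside]
            if len(nodes) >= min_nodes:
                return nodes[:, 0], nodes[:, 1]
        s /= 2.0
        if s < 1e-4:
            break
    if 'nodes' in locals() and len(nodes) >= 1:
        return nodes[:, 0], nodes[:, 1]
    raise ValueError("polygon has no interior nodes at the requested spacing; "
                     "use a finer discretization")


def block_krige(samples, model: VariogramModel, polygon,
                spacing_km: float = 1.0, min_nodes: int = 100) -> KrigingResult:
    """Ordinary block kriging of the spatial mean over a polygon.

    The block is approximated by regular interior nodes; the system uses
    point-to-block mean semivariances gamma_bar(x_i, B) and the block
    variance subtracts the within-block mean gamma_bar(B, B):
    sigma2_B = sum_i lambda_i gamma_bar(x_i, B) + psi - gamma_bar(B, B).
    """
    from shapely.geometry import Point, Polygon  # noqa: F401  (type reference)

    if hasattr(polygon, "geom_type"):
        b_lon, b_lat = discretize_polygon(polygon, spacing_km, min_nodes)
    else:  # pre-discretized nodes (lon_array, lat_array)
        b_lon, b_lat = (np.asarray(v, dtype=float) for v in polygon)
    lon = np.asarray(samples["lon"], dtype=float)
    lat = np.asarray(samples["lat"], dtype=float)
    z = np.asarray(samples["value"], dtype=float)
    n = lon.size
    A = _augmented_system(lon, lat, model)
    g_pb = exponential_semivariance(
        cross_distances(lon, lat, b_lon, b_lat) / 1000.0, model).mean(axis=1)
    g_bb = float(np.mean(exponential_semivariance(
        pairwise_distances(b_lon, b_lat) / 1000.0, model)))
    rhs = np.concatenate([g_pb, [1.0]])
    sol = _solve_ok(A, rhs)
    lam, psi = sol[:n], sol[n]
    if abs(lam.sum() - 1.0) > _WEIGHT_TOL:
        raise np.linalg.LinAlgError("block kriging weights failed the unbiasedness constraint")
    pred = float(lam @ z)
    var = _clip_variance(lam @ g_pb + psi - g_bb)
    return KrigingResult(prediction=pred, variance=var, weights=lam, lagrange=float(psi))


def variance_mask(variance, data_variance: float, fraction: float = 0.75):
    """Boolean mask: True where kriging variance exceeds fraction * data variance.

    The comparison is a strict inequality ("exceeded"); masked nodes flag
    areas where sampling is too sparse for the map to be trusted.
    """
    if not data_variance > 0:
        raise ValueError("data variance must be positive")
    v = np.asarray(variance, dtype=float)
    return v > fraction * data_variance
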