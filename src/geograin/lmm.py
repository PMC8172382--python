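"""Spatial linear mixed models with Matern-correlated random effects.

The model for a response y observed at n georeferenced locations is

    y = X beta + u + e,   u ~ N(0, sigma2_s R(phi, nu)),  e ~ N(0, sigma2_n I)

with R the Matern correlation matrix on great-circle distances (km).
Variance parameters (sigma2_s, sigma2_n, phi) are estimated by residual
maximum likelihood (REML) or maximum likelihood (ML) with the smoothness nu
profiled over a small grid; fixed effects are then the generalised
(weighted) least-squares solution beta = (X' V^-1 X)^-1 X' V^-1 y with
standard errors from (X' V^-1 X)^-1. Nested fixed-effect structures are
compared by the log-likelihood ratio statistic L = 2 (l_full - l_null)
against chi-square (ML fits only), and covariates are screened by forward
selection with Benjamini-Hochberg false-discovery-rate control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from statsmodels.stats.multitest import multipletests

from .distance import cross_distances, pairwise_distances
from .variogram import matern_correlation

DEFAULT_NU_GRID = (0.25, 0.5, 1.0, 2.0)

_LOG2PI = float(np.log(2.0 * np.pi))


class SpatialLMM:
    """Linear mixed model with a Matern-correlated spatial random effect.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response on the analysis scale (log_e where appropriate, e.g. serum
        selenium).
    exog : array-like, shape (n, p)
        Fixed-effect design matrix including the intercept column.
    coords : array-like, shape (n, 2)
        (lon, lat) in decimal degrees; correlation uses great-circle
        distances in km.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, coords, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            self.exog = self.exog.T
        coords = np.asarray(coords, dtype=float)
        self.coords = coords
        n, p = self.exog.shape
        if n < 10:
            raise ValueError("spatial LMM needs at least 10 observations")
        if not np.all(np.isfinite(self.exog)) or not np.all(np.isfinite(self.endog)):
            raise ValueError("predictor and response columns must be complete and finite")
        self.exog_names = (list(exog_names) if exog_names is not None
                           else ["const"] + [f"x{i}" for i in range(1, p)])
        sv = np.linalg.svd(self.exog, compute_uv=False)
        if sv[-1] < 1e-10 * sv[0]:
            raise ValueError(f"near-singular design matrix; collinear predictors "
                             f"among {self.exog_names}")
        self.dist_km = pairwise_distances(coords[:, 0], coords[:, 1]) / 1000.0
        self.nobs = n

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors,
                       lon: str = "lon", lat: str = "lat") -> "SpatialLMM":
        """Build the model from a table with coordinate columns."""
        predictors = list(predictors)
        X = np.column_stack([np.ones(len(data))]
                            + [np.asarray(data[p], dtype=float) for p in predictors])
        coords = np.column_stack([data[lon], data[lat]])
        return cls(data[response], X, coords, exog_names=["const"] + predictors)

    # -- likelihood ------------------------------------------------------

    def _cov(self, sigma2_s, sigma2_n, phi, nu):
        R = matern_correlation(self.dist_km, phi, nu)
        V = sigma2_s * R
        V[np.diag_indices_from(V)] += sigma2_n + 1e-10 * (sigma2_s + sigma2_n)
        return V

    def loglike(self, sigma2_s, sigma2_n, phi, nu, method="REML"):
        """Profile log-likelihood at the given variance parameters.

        beta is profiled out by generalised least squares; REML adds the
        -0.5 log|X' V^-1 X| adjustment and the (n - p) normalising constant.
        """
        y, X = self.endog, self.exog
        n, p = X.shape
        V = self._cov(sigma2_s, sigma2_n, phi, nu)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vi_y = cho_solve((c, low), y)
        Vi_X = cho_solve((c, low), X)
        XtViX = X.T @ Vi_X
        try:
            beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        except np.linalg.LinAlgError:
            return -np.inf
        r = y - X @ beta
        quad = float(r @ cho_solve((c, low), r))
        if method == "ML":
            return -0.5 * (n * _LOG2PI + logdetV + quad)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetXtViX + quad)

    def _gls(self, V):
        c, low = cho_factor(V, lower=True)
        Vi_y = cho_solve((c, low), self.endog)
        Vi_X = cho_solve((c, low), self.exog)
        XtViX = self.exog.T @ Vi_X
        cov_beta = np.linalg.inv(XtViX)
        beta = cov_beta @ (self.exog.T @ Vi_y)
        return beta, cov_beta

    def fit(self, method: str = "REML", nu_grid=DEFAULT_NU_GRID,
            n_starts: int = 3, maxiter: int = 200) -> "SpatialLMMResults":
        """Estimate variance parameters and fixed effects.

        Optimisation is quasi-Newton (L-BFGS-B) in (log sigma2_s,
        log sigma2_n, log phi) from ``n_starts`` heuristic starting points,
        repeated for each smoothness on ``nu_grid``; ties break by highest
        log-likelihood then smallest phi.
        """
        if method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        y = self.endog
        var_y = max(float(np.var(y)), 1e-12)
        d = self.dist_km[np.triu_indices(self.nobs, k=1)]
        d_pos = d[d > 0]
        med_d = float(np.median(d_pos)) if d_pos.size else 1.0
        q1 = float(np.quantile(d_pos, 0.25)) if d_pos.size else med_d / 2
        q3 = float(np.quantile(d_pos, 0.75)) if d_pos.size else med_d * 2
        starts = [(0.5 * var_y, 0.5 * var_y, med_d),
                  (0.9 * var_y, 0.1 * var_y, q1),
                  (0.1 * var_y, 0.9 * var_y, q3)][:max(1, n_starts)]
        lb = np.log(var_y) - 18.0
        ub = np.log(var_y) + 8.0
        bounds = [(lb, ub), (lb, ub),
                  (np.log(max(q1 / 20.0, 1e-4)), np.log(max(q3 * 50.0, 1.0)))]

        def neg_ll(x, nu):
            s2s, s2n, phi = np.exp(x)
            ll = self.loglike(s2s, s2n, phi, nu, method=method)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        converged = False
        for nu in nu_grid:
            for s in starts:
                x0 = np.clip(np.log(np.asarray(s, dtype=float)),
                             [b[0] for b in bounds], [b[1] for b in bounds])
                res = minimize(neg_ll, x0, args=(nu,), method="L-BFGS-B",
                               bounds=bounds, options={"maxiter": maxiter})
                key = (-res.fun, -np.exp(res.x[2]))  # highest ll, then smallest phi
                if best is None or key > best[0]:
                    best = (key, res, nu)
                    converged = bool(res.success)
        if best is None or not np.isfinite(best[1].fun):
            raise RuntimeError("spatial LMM optimizer failed to converge; "
                               f"trace: {best[1] if best else 'no evaluations'}")
        _, res, nu = best
        if not converged and not res.success:
            warnings.warn(f"variance-parameter optimizer did not report convergence: "
                          f"{res.message}", stacklevel=2)
        sigma2_s, sigma2_n, phi = np.exp(res.x)
        V = self._cov(sigma2_s, sigma2_n, phi, nu)
        beta, cov_beta = self._gls(V)
        llf = self.loglike(sigma2_s, sigma2_n, phi, nu, method=method)
        return SpatialLMMResults(
            model=self, params=beta, cov_params=cov_beta,
            sigma2_s=float(sigma2_s), sigma2_n=float(sigma2_n),
            phi=float(phi), nu=float(nu), llf=float(llf), method=method,
            converged=bool(res.success))


@dataclass
class SpatialLMMResults:
    """Fitted spatial LMM: fixed effects, variance components, likelihood."""

    model: SpatialLMM
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_s: float
    sigma2_n: float
    phi: float
    nu: float
    llf: float
    method: str
    converged: bool = True

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_model(self) -> int:
        return self.model.exog.shape[1]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta": {n: float(b) for n, b in zip(self.model.exog_names, self.params)},
            "beta_se": {n: float(s) for n, s in zip(self.model.exog_names, self.bse)},
            "sigma2_s": self.sigma2_s, "sigma2_n": self.sigma2_n,
            "phi_km": self.phi, "nu": self.nu, "loglik": self.llf,
            "n": self.nobs, "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Spatial linear mixed model (Matern correlation)",
            "=" * 56,
            f"No. observations: {self.nobs:>6}    Method: {self.method}",
            f"Log-likelihood:   {self.llf:>12.4f}",
            f"sigma2_spatial:   {self.sigma2_s:>12.6g}    phi (km): {self.phi:.4g}",
            f"sigma2_nugget:    {self.sigma2_n:>12.6g}    nu:       {self.nu:.4g}",
            "-" * 56,
            f"{'term':<16}{'coef':>12}{'std err':>12}{'z':>10}",
        ]
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"{name:<16}{b:>12.5g}{s:>12.5g}{b / s:>10.3f}")
        lines.append("=" * 56)
        return "\n".join(lines)


def lrt_fixed_effect(fit_full: SpatialLMMResults,
                     fit_null: SpatialLMMResults) -> tuple[float, float]:
    """Log-likelihood ratio test of nested fixed-effect structures.

    L = 2 (l_full - l_null), p from the upper chi-square tail with df the
    difference in fixed-effect counts. Both fits must be by ML: REML
    likelihoods of models with different fixed effects are not comparable.
    """
    if fit_full.method != "ML" or fit_null.method != "ML":
        raise ValueError("likelihood-ratio tests of fixed effects require ML fits; "
                         "REML likelihoods differ by the fixed-effect projection "
                         "and are not comparable across mean structures")
    df = fit_full.df_model - fit_null.df_model
    if df < 0:
        raise ValueError("null model has more fixed effects than the full model")
    L = 2.0 * (fit_full.llf - fit_null.llf)
    if df == 0:
        return float(L), 1.0
    L = max(L, 0.0)
    p = float(stats.chi2.sf(L, df=df))
    return float(L), p


def chi2_lrt_pvalue(L: float, df: int = 1) -> float:
    """Upper-tail chi-square probability for a likelihood-ratio statistic."""
    return float(stats.chi2.sf(L, df=df))


@dataclass
class SelectionResult:
    """Forward-selection record: per-test statistics and the FDR decision."""

    tests: pd.DataFrame  # predictor, L, pvalue, provisional, bh_selected
    selected: list
    final_fit: SpatialLMMResults | None
    alpha: float


def benjamini_hochberg(pvalues, q: float = 0.05):
    """BH step-up rejections at FDR level q (boolean array)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def forward_select_with_fdr(data: pd.DataFrame, response: str, predictors_in_order,
                            alpha: float = 0.05, lon: str = "lon", lat: str = "lat",
                            nu_grid=DEFAULT_NU_GRID, n_starts: int = 3,
                            final_method: str = "REML") -> SelectionResult:
    """Forward covariate selection with FDR control.

    Each predictor, in the stated order, is tested by an ML likelihood-ratio
    test against the current model and provisionally retained at p < 0.05;
    the family of p-values from all tests performed is then screened by
    Benjamini-Hochberg at FDR ``alpha``, and the final model is refitted
    (``final_method``) with the surviving predictors only.
    """
    predictors_in_order = list(predictors_in_order)
    if not predictors_in_order:
        raise ValueError("no predictors to consider")
    current: list = []
    rows = []
    fit_kws = dict(nu_grid=nu_grid, n_starts=n_starts)
    null_fit = SpatialLMM.from_dataframe(data, response, current, lon, lat).fit(
        method="ML", **fit_kws)
    for pred in predictors_in_order:
        full_fit = SpatialLMM.from_dataframe(
            data, response, current + [pred], lon, lat).fit(method="ML", **fit_kws)
        L, p = lrt_fixed_effect(full_fit, null_fit)
        provisional = p < 0.05
        rows.append({"predictor": pred, "L": L, "pvalue": p,
                     "provisional": provisional})
        if provisional:
            current = current + [pred]
            null_fit = full_fit
    tests = pd.DataFrame(rows)
    bh = benjamini_hochberg(tests["pvalue"].to_numpy(), q=alpha)
    tests["bh_selected"] = bh
    selected = [r.predictor for r, keep in zip(tests.itertuples(), bh)
                if keep and r.provisional]
    final_fit = SpatialLMM.from_dataframe(data, response, selected, lon, lat).fit(
        method=final_method, **fit_kws)
    return SelectionResult(tests=tests, selected=selected,
                           final_fit=final_fit, alpha=alpha)


def nearest_grain_link(ea_table: pd.DataFrame, grain_table: pd.DataFrame,
                       lon: str = "lon", lat: str = "lat") -> pd.DataFrame:
    """Join each enumeration area to its nearest grain sample site.

    Distances are great-circle; the result carries ``nearest_site_id``,
    ``grain_value`` and ``distance_km`` columns plus a ``median_distance_km``
    entry in ``DataFrame.attrs``.
    """
    if len(ea_table) == 0 or len(grain_table) == 0:
        raise ValueError("both tables must be non-empty")
    D = cross_distances(ea_table[lon], ea_table[lat],
                        grain_table[lon], grain_table[lat]) / 1000.0
    j = np.argmin(D, axis=1)
    out = ea_table.copy()
    ids = (grain_table["site_id"].to_numpy() if "site_id" in grain_table.columns
           else grain_table.index.to_numpy())
    out["nearest_site_id"] = ids[j]
    out["grain_value"] = grain_table["value"].to_numpy()[j]
    out["distance_km"] = D[np.arange(len(ea_table)), j]
    out.attrs["median_distance_km"] = float(np.median(out["distance_km"]))
    return out
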