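"""Trait-environment models: GLS with spatially correlated errors.

The model is y = X beta + e with e ~ N(0, sigma^2 * Sigma(theta)), where
Sigma is built from a distance-decay correlation family over plot
coordinates:

    corr(d) = (1 - nugget) * rho_family(d / range)   for d > 0,  corr(0) = 1

with rho exponential (exp(-u)), gaussian (exp(-u^2)) or spherical.
Correlation parameters are estimated by maximum likelihood (profiled over
beta and sigma^2) via numeric optimization; ``family="none"`` reduces
exactly to ordinary least squares.  ML (not REML) is used throughout so
that log-likelihoods are comparable across fixed-effects structures, which
the Nagelkerke pseudo-R-squared and the variance partitioning both require.

Explanatory power is summarized by Nagelkerke's pseudo-R^2

    R^2 = [1 - exp(2 (ll0 - llm) / n)] / [1 - exp(2 ll0 / n)]

against an intercept-only GLS null that re-estimates its own correlation
parameters.  Coefficient tests are two-sided t-type tests on n - k degrees
of freedom.  No multiple-testing correction is applied across predictors
or responses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("cwmitv.spatial")

__all__ = [
    "CorrelationModel",
    "SpatialGlsFit",
    "fit_gls",
    "fit_gls_r2",
    "nagelkerke_r2",
    "vif",
    "partial_prediction",
    "species_level_models",
    "summarize_species_models",
]

_FAMILIES = ("exponential", "gaussian", "spherical", "none")


@dataclass
class CorrelationModel:
    """Spatial correlation specification.

    ``range_=None`` requests ML estimation of the range (initialized at the
    median inter-plot distance).  ``nugget`` is the proportion of variance
    that is spatially unstructured; it is held fixed unless
    ``estimate_nugget`` is set.
    """

    family: str = "exponential"
    range_: float | None = None
    nugget: float = 0.0
    estimate_nugget: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown correlation family {self.family!r}")
        if self.family != "none" and self.range_ is not None and self.range_ <= 0:
            raise ValueError("correlation range must be positive")
        if not 0.0 <= self.nugget < 1.0:
            raise ValueError("nugget must be in [0, 1)")


def _rho(family: str, u: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return np.exp(-u)
    if family == "gaussian":
        return np.exp(-(u**2))
    if family == "spherical":
        out = np.where(u < 1.0, 1.0 - 1.5 * u + 0.5 * u**3, 0.0)
        return out
    raise ValueError(family)


def correlation_matrix(dist: np.ndarray, family: str, range_: float,
                       nugget: float) -> np.ndarray:
    u = dist / range_
    C = (1.0 - nugget) * _rho(family, u)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SpatialGlsFit:
    """ML fit of a spatial GLS model.

    ``params`` has one row per term (including ``(Intercept)``) with columns
    coef / se / t / p; predictors were standardized to mean 0, SD 1 before
    fitting, so coefficients are directly comparable.  ``loglik`` is the
    maximized ML log-likelihood; ``aic = 2k - 2 loglik`` with k counting
    mean, variance and estimated correlation parameters.
    """

    params: pd.DataFrame
    family: str
    range_: float | None
    nugget: float
    loglik: float
    aic: float
    n: int
    sigma2: float
    converged: bool
    response: str = "y"
    predictor_means: pd.Series = field(default_factory=pd.Series)
    predictor_sds: pd.Series = field(default_factory=pd.Series)

    @property
    def coefficients(self) -> pd.Series:
        return self.params["coef"]


def _prepare(y, X, coords):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        Xdf = pd.DataFrame(index=range(n))
    else:
        Xdf = pd.DataFrame(X).reset_index(drop=True)
    if len(Xdf) != n:
        raise ValueError("response and predictors have different lengths")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response")
    if len(Xdf.columns) and not np.all(np.isfinite(Xdf.to_numpy(float))):
        raise ValueError("non-finite values in predictors")
    if coords is not None:
        coords = np.asarray(pd.DataFrame(coords), dtype=float)
        if coords.shape != (n, 2):
            raise ValueError("coords must be n x 2")
    return y, Xdf, coords, n


def _design(Xdf: pd.DataFrame, standardize: bool):
    names = ["(Intercept)"] + list(Xdf.columns)
    n = len(Xdf) if len(Xdf) else None
    if not len(Xdf.columns):
        return np.ones((len(Xdf.index) or 0, 1)), names, pd.Series(dtype=float), pd.Series(dtype=float)
    Xv = Xdf.to_numpy(float)
    means = pd.Series(Xv.mean(axis=0), index=Xdf.columns)
    sds = pd.Series(Xv.std(axis=0, ddof=0), index=Xdf.columns)
    if standardize:
        zero = list(sds.index[sds == 0])
        if zero:
            raise ValueError(f"zero-variance predictor(s): {zero}")
        Xv = (Xv - means.to_numpy()) / sds.to_numpy()
    M = np.column_stack([np.ones(Xv.shape[0]), Xv])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        collinear = _collinear_columns(Xv, list(Xdf.columns))
        raise ValueError(f"singular design; collinear column(s): {collinear}")
    return M, names, means, sds


def _collinear_columns(Xv: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(Xv.shape[1]):
        others = np.delete(Xv, j, axis=1)
        A = np.column_stack([np.ones(Xv.shape[0]), others])
        beta, *_ = np.linalg.lstsq(A, Xv[:, j], rcond=None)
        resid = Xv[:, j] - A @ beta
        tot = Xv[:, j] - Xv[:, j].mean()
        if tot @ tot == 0 or 1 - (resid @ resid) / (tot @ tot) > 1 - 1e-10:
            bad.append(names[j])
    return bad or names


def _profiled_loglik(M: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Profile beta and sigma^2 out of the Gaussian log-likelihood for a
    fixed correlation matrix C; returns (loglik, beta, sigma2_ml, cov_unscaled)."""
    from scipy.linalg import solve_triangular
    n = y.size
    L = np.linalg.cholesky(C)
    Xw = solve_triangular(L, M, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    rss = float(r @ r)
    # degenerate (e.g. constant) responses: keep the likelihood finite so that
    # identical full and null fits still give a well-defined pseudo-R^2 of 0
    sigma2 = max(rss / n, 1e-24)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return ll, beta, sigma2, xtx_inv, rss


def fit_gls(y, X=None, coords=None, corr: CorrelationModel | None = None,
            standardize: bool = True, response: str = "y") -> SpatialGlsFit:
    """Fit a (spatial) GLS model by maximum likelihood.

    Parameters
    ----------
    y : array-like of per-plot response values
    X : DataFrame of predictors (None or empty for intercept-only)
    coords : n x 2 plot coordinates in meters (required unless family="none")
    corr : correlation specification; default exponential with ML range
    standardize : standardize predictors to mean 0, SD 1 before fitting
    """
    corr = corr or CorrelationModel()
    y, Xdf, coords, n = _prepare(y, X, coords)
    M, names, means, sds = _design(Xdf, standardize)
    p = M.shape[1]
    if n <= p:
        raise ValueError("need more observations than mean parameters")

    if corr.family == "none":
        C = np.eye(n)
        ll, beta, sigma2, xtx_inv, rss = _profiled_loglik(M, y, C)
        range_hat, nugget_hat, n_corr, converged = None, 0.0, 0, True
    else:
        if coords is None:
            raise ValueError("coords required for spatial correlation")
        dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(n, 1)
        pos = dist[iu]
        med = float(np.median(pos))
        dmax = float(pos.max())
        dmin = float(pos[pos > 0].min()) if np.any(pos > 0) else 1.0

        def nll(theta):
            r = np.exp(theta[0])
            g = corr.nugget if not corr.estimate_nugget else 1.0 / (1.0 + np.exp(-theta[1]))
            try:
                C = correlation_matrix(dist, corr.family, r, g)
                ll, *_ = _profiled_loglik(M, y, C)
            except np.linalg.LinAlgError:
                return 1e10
            return -ll

        n_corr = (0 if corr.range_ is not None else 1) + (1 if corr.estimate_nugget else 0)
        if corr.range_ is not None and not corr.estimate_nugget:
            range_hat, nugget_hat, converged = corr.range_, corr.nugget, True
        elif not corr.estimate_nugget:
            lo, hi = np.log(max(dmin * 1e-2, 1e-8)), np.log(dmax * 100.0)
            res = optimize.minimize_scalar(lambda t: nll([t]), bounds=(lo, hi),
                                           method="bounded",
                                           options={"xatol": 1e-6})
            range_hat, nugget_hat = float(np.exp(res.x)), corr.nugget
            converged = bool(res.success)
        else:
            x0 = [np.log(corr.range_ if corr.range_ is not None else med), 0.0]
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
            range_hat = float(corr.range_ if corr.range_ is not None else np.exp(res.x[0]))
            nugget_hat = float(1.0 / (1.0 + np.exp(-res.x[1])))
            converged = bool(res.success)
        if not converged:
            logger.warning("GLS correlation optimizer did not converge (%s)", response)
        C = correlation_matrix(dist, corr.family, range_hat, nugget_hat)
        ll, beta, sigma2, xtx_inv, rss = _profiled_loglik(M, y, C)

    # t tests with the (n - p)-denominator residual variance, as in standard
    # GLS software; the ML variance (n denominator) enters the likelihood only
    se = np.sqrt(np.diag(xtx_inv) * rss / (n - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    params = pd.DataFrame({"coef": beta, "se": se, "t": tval, "p": pval}, index=names)
    k = p + 1 + n_corr
    aic = 2.0 * k - 2.0 * ll
    return SpatialGlsFit(params=params, family=corr.family, range_=range_hat,
                         nugget=nugget_hat, loglik=float(ll), aic=float(aic), n=n,
                         sigma2=float(sigma2), converged=converged, response=response,
                         predictor_means=means, predictor_sds=sds)


def nagelkerke_r2(fit: SpatialGlsFit, null_fit: SpatialGlsFit,
                  tol: float = 1e-4) -> float:
    """Nagelkerke pseudo-R^2 of ``fit`` against its intercept-only null.

    Falls back to the (un-normalized) Cox-Snell numerator when the
    Nagelkerke denominator is non-positive, which can happen with continuous
    likelihoods whose null log-likelihood is positive.
    """
    if fit.n != null_fit.n:
        raise ValueError("full and null fits use different plot sets")
    ll0, llm, n = null_fit.loglik, fit.loglik, fit.n
    if llm < ll0 - tol:
        logger.warning("full-model log-likelihood below null (%g < %g): "
                       "a fit likely failed", llm, ll0)
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - llm) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if denom <= 0:
        logger.warning("Nagelkerke denominator non-positive (ll0=%g); "
                       "returning Cox-Snell value", ll0)
        return float(cox_snell)
    return float(cox_snell / denom)


def fit_gls_r2(y, X, coords, corr: CorrelationModel | None = None,
               response: str = "y"):
    """Fit the model and its own intercept-only null; return (fit, null, R^2).

    The null re-estimates its own correlation parameters, so R^2 compares
    maximized likelihoods of two independently optimized models.
    """
    corr = corr or CorrelationModel()
    fit = fit_gls(y, X, coords, corr, response=response)
    null = fit_gls(y, None, coords, corr, response=response)
    return fit, null, nagelkerke_r2(fit, null)


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j) from regressing
    predictor j on all others (with intercept).  Exactly collinear columns
    report ``inf``."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    X = np.column_stack([np.ones(len(predictors)), predictors.to_numpy(float)])
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(predictors.columns, start=1):
            v = variance_inflation_factor(X, j)
            out[name] = float(v) if np.isfinite(v) else np.inf
    return pd.Series(out, name="vif")


def partial_prediction(fit: SpatialGlsFit, focal: str, grid) -> pd.DataFrame:
    """Predicted response over a grid of the focal predictor (standardized
    scale), holding all other predictors at their mean (0)."""
    if focal not in fit.params.index or focal == "(Intercept)":
        raise ValueError(f"unknown predictor {focal!r}")
    grid = np.asarray(grid, dtype=float)
    pred = fit.params.loc["(Intercept)", "coef"] + fit.params.loc[focal, "coef"] * grid
    return pd.DataFrame({focal: grid, "predicted": pred})


def species_level_models(traits: pd.DataFrame, env: pd.DataFrame,
                         predictors: list[str], min_plots: int = 10,
                         corr: CorrelationModel | None = None,
                         trait_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-species trait-environment GLS fits on plot-specific species means.

    Species present in fewer than ``min_plots`` plots are skipped.  Returns
    a tidy table with one row per retained species x trait x predictor.
    ``env`` must be indexed by (or contain) plot_id and carry x / y columns.
    """
    from .cwm import compute_species_means
    corr = corr or CorrelationModel()
    e = env.set_index("plot_id") if "plot_id" in env.columns else env
    means = compute_species_means(traits, trait_cols)
    cols = trait_cols or means.traits
    rows = []
    for sp, npl in means.n_plots_present.items():
        if npl < min_plots:
            logger.info("species %s present in %d < %d plots; skipped", sp, npl, min_plots)
            continue
        sub = means.specific.xs(sp, level="species_id")
        plots = sub.index
        X = e.loc[plots, predictors]
        coords = e.loc[plots, ["x", "y"]]
        for t in cols:
            try:
                fit = fit_gls(sub[t], X, coords, corr, response=f"{sp}:{t}")
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("species %s trait %s: fit failed (%s)", sp, t, exc)
                continue
            for pred in predictors:
                rows.append({"species_id": sp, "trait": t, "n_plots": int(npl),
                             "predictor": pred,
                             "coef": fit.params.loc[pred, "coef"],
                             "se": fit.params.loc[pred, "se"],
                             "p": fit.params.loc[pred, "p"],
                             "converged": fit.converged})
    return pd.DataFrame(rows)


def summarize_species_models(fits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per species x trait: number of predictors and how many test significant."""
    if fits.empty:
        return pd.DataFrame(columns=["species_id", "trait", "n_predictors",
                                     "n_significant", "any_significant"])
    g = fits.groupby(["species_id", "trait"])
    out = g.agg(n_predictors=("predictor", "size"),
                n_significant=("p", lambda p: int((p < alpha).sum())))
    out["any_significant"] = out["n_significant"] > 0
    return out.reset_index()
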