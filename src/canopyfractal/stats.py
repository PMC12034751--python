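"""Statistical analyses for tree- and stand-level structural complexity.

Covers the analysis toolkit of the study design this package serves:
Spearman rank correlations between D_b and architecture, Welch's t-test
for species contrasts, multiple linear regression with bidirectional
stepwise AIC selection and VIF screening, random-intercept linear mixed
models with marginal/conditional (variance-partition) R^2, Moran's I on
residuals, and the simple tree-to-stand regressions of stand D_b on the
sum/max/SD of member-tree D_b.

OLS and mixed models are fit with statsmodels; rank correlation and the
Welch test come from scipy. Moran's I, VIF (auxiliary regressions), the
stepwise search and the R^2 variance partition are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ModelResult",
    "spearman",
    "welch_t",
    "ols_fit",
    "vif",
    "stepwise_aic",
    "lmm_random_intercept",
    "morans_i",
    "tree_to_stand_regression",
    "standardize",
    "MODEL1_COEFFICIENTS",
    "simulate_architecture_table",
    "recover_model1",
]


@dataclass
class ModelResult:
    """A fitted model: coefficients, fit criteria, residuals."""

    formula: str
    params: dict
    bse: dict
    pvalues: dict
    aic: float
    n: int
    rmse: float
    residuals: np.ndarray = field(repr=False, default=None)
    r2: float = None  # adjusted R^2 for OLS
    r2_marginal: float = None
    r2_conditional: float = None
    flags: list = field(default_factory=list)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank-order correlation (mid-rank ties) with two-sided p."""
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p)."""
    res = scipy.stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _design(table: pd.DataFrame, predictors) -> pd.DataFrame:
    x = table[list(predictors)].astype(float)
    if x.isna().any().any():
        raise ValueError("missing values in predictors")
    return sm.add_constant(x, has_constant="add")


def ols_fit(table: pd.DataFrame, response: str, predictors) -> ModelResult:
    """Ordinary least squares of ``response`` on ``predictors`` (+ intercept).

    Reports adjusted R^2, AIC under the Gaussian log-likelihood convention
    used by statsmodels (-2 logL + 2k with k including intercept and the
    error variance absorbed into logL), and RMSE = sqrt(RSS / n).
    """
    y = table[response].astype(float)
    if y.isna().any():
        raise ValueError("missing values in response")
    x = _design(table, predictors)
    fit = sm.OLS(y, x).fit()
    resid = np.asarray(fit.resid)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ModelResult(
        formula=f"{response} ~ " + " + ".join(predictors) if predictors else f"{response} ~ 1",
        params=dict(fit.params),
        bse=dict(fit.bse),
        pvalues=dict(fit.pvalues),
        aic=float(fit.aic),
        n=int(fit.nobs),
        rmse=rmse,
        residuals=resid,
        r2=float(fit.rsquared_adj) if len(predictors) else 0.0,
    )


def vif(table: pd.DataFrame, predictors) -> dict:
    """Variance inflation factors via auxiliary regressions, 1 / (1 - R_j^2).

    Values above 5 indicate collinearity the modeling pipeline warns about.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        return {p: 1.0 for p in predictors}
    out = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        y = table[p].astype(float)
        x = sm.add_constant(table[others].astype(float), has_constant="add")
        r2 = sm.OLS(y, x).fit().rsquared
        out[p] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def stepwise_aic(table: pd.DataFrame, response: str, candidates) -> ModelResult:
    """Bidirectional stepwise AIC minimization starting from the full model.

    At each step the single add or drop with the lowest AIC is taken; ties
    break toward fewer terms, then lexicographically. The final AIC can
    never exceed the full model's, since the search starts there and only
    accepts improvements.
    """
    candidates = list(candidates)
    current = sorted(candidates)

    def aic_of(terms):
        return ols_fit(table, response, terms).aic

    current_aic = aic_of(current)
    while True:
        moves = []
        for p in current:
            terms = [q for q in current if q != p]
            moves.append((aic_of(terms), len(terms), tuple(sorted(terms)), terms))
        for p in candidates:
            if p not in current:
                terms = sorted(current + [p])
                moves.append((aic_of(terms), len(terms), tuple(terms), terms))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best = moves[0]
        if best[0] < current_aic - 1e-10:
            current_aic = best[0]
            current = sorted(best[3])
        else:
            break
    return ols_fit(table, response, current)


def standardize(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Center to mean 0 and scale to SD 1 (population SD, as R's scale())."""
    out = table.copy()
    for c in columns:
        v = out[c].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {c!r} is constant; cannot standardize")
        out[c] = (v - v.mean()) / sd
    return out


def lmm_random_intercept(
    table: pd.DataFrame, response: str, fixed, group: str, standardize_fixed: bool = True
) -> ModelResult:
    """Linear mixed model with a single random intercept per group.

    Fixed-effect predictors are standardized (mean 0, SD 1) before the
    fit so effect sizes are comparable. Estimation is by maximum
    likelihood (not REML) so AICs are comparable across fixed-effect
    structures. Marginal and conditional R^2 follow the variance-partition
    definition: fixed-effect variance over total, and fixed-plus-random
    over total. A singular fit (group variance ~ 0) is flagged but the
    model is still returned.
    """
    fixed = list(fixed)
    data = table[[response, group] + fixed].dropna().copy()
    if standardize_fixed and fixed:
        data = standardize(data, fixed)
    exog = sm.add_constant(data[fixed].astype(float), has_constant="add")
    model = sm.MixedLM(data[response].astype(float), exog, groups=data[group])
    fit = model.fit(reml=False, method="lbfgs", maxiter=200)
    var_resid = float(fit.scale)
    var_group = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    fitted_fixed = np.asarray(exog) @ np.asarray(fit.fe_params)
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + var_group + var_resid
    r2m = var_fixed / total
    r2c = (var_fixed + var_group) / total
    flags = []
    if var_group < 1e-8 * total:
        flags.append("singular_fit_group_variance_zero")
    if not fit.converged:
        flags.append("not_converged")
    try:
        resid = np.asarray(fit.resid)
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effects covariance: conditional residuals are
        # unavailable, fall back to marginal residuals y - X beta
        resid = np.asarray(data[response], dtype=float) - fitted_fixed
        flags.append("marginal_residuals_only")
    return ModelResult(
        formula=f"{response} ~ " + " + ".join(fixed) + f" + (1 | {group})",
        params=dict(fit.fe_params),
        bse=dict(fit.bse_fe),
        pvalues=dict(fit.pvalues[: len(fit.fe_params)]),
        aic=float(fit.aic),
        n=int(fit.nobs),
        rmse=float(np.sqrt(np.mean(resid**2))),
        residuals=resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        flags=flags,
    )


def morans_i(residuals, coordinates) -> tuple[float, float]:
    """Moran's I with inverse-distance weights and a normal-approximation p.

    Weights are 1/d_ij between observation coordinates (zero diagonal, no
    row standardization). The two-sided p-value uses the expectation
    E[I] = -1/(n-1) and the variance under the normality assumption.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 observations")
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.all(np.isfinite(w)):
        raise ValueError("coincident coordinates give infinite weights")
    zc = z - z.mean()
    s0 = w.sum()
    num = float(zc @ w @ zc)
    den = float(np.sum(zc**2))
    i_obs = (n / s0) * num / den
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    zscore = (i_obs - e_i) / math.sqrt(var_i)
    p = 2 * scipy.stats.norm.sf(abs(zscore))
    return float(i_obs), float(p)


def tree_to_stand_regression(plot_table: pd.DataFrame, stand_col: str = "stand_db") -> dict:
    """Simple OLS of stand-level D_b on each tree-D_b summary separately.

    ``plot_table`` has one row per plot with columns db_sum, db_max, db_sd
    and the stand D_b. Returns {predictor: ModelResult}.
    """
    out = {}
    for pred in ("db_sum", "db_max", "db_sd"):
        sub = plot_table[[stand_col, pred]].dropna()
        fit = ols_fit(sub, stand_col, [pred])
        # simple regression: report plain R^2 alongside adjusted
        y = sub[stand_col].astype(float)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum(fit.residuals**2))
        fit.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[pred] = fit
    return out


# ---------------------------------------------------------------------------
# Generative parameter-recovery experiment for the best architecture model
# ---------------------------------------------------------------------------

#: D_b = 1.95 + 0.067 log(CL) + 0.155 log(CV) - 0.312 log(TTH) + eps,
#: the best multiple-regression model of tree D_b from crown length, crown
#: volume and total height (natural logs; the log base only rescales
#: coefficients). sigma is the residual noise used in simulation.
MODEL1_COEFFICIENTS = {
    "const": 1.95,
    "log_cl": 0.067,
    "log_cv": 0.155,
    "log_tth": -0.312,
}
MODEL1_SIGMA = 0.10


def simulate_architecture_table(n: int, rng) -> pd.DataFrame:
    """Simulate a tree table from the generative form of the best model.

    Heights are lognormal around 12 m; crown length is a uniform fraction
    of height; crown volume scales with crown radius^2 x crown length, so
    the three log predictors are correlated the way the synthetic suite's
    trees are, without being collinear.
    """
    log_tth = rng.normal(math.log(12.0), 0.35, n)
    tth = np.exp(log_tth)
    cl = rng.uniform(0.3, 0.9, n) * tth
    mcr = 0.18 * tth**0.9 * rng.lognormal(0.0, 0.25, n)
    cv = math.pi * mcr**2 * cl * rng.lognormal(0.0, 0.30, n)
    log_cl = np.log(cl)
    log_cv = np.log(cv)
    c = MODEL1_COEFFICIENTS
    db = (
        c["const"]
        + c["log_cl"] * log_cl
        + c["log_cv"] * log_cv
        + c["log_tth"] * log_tth
        + rng.normal(0.0, MODEL1_SIGMA, n)
    )
    return pd.DataFrame(
        {"db": db, "log_cl": log_cl, "log_cv": log_cv, "log_tth": log_tth}
    )


def recover_model1(n_reps: int = 200, n: int = 546, seed: int = 0) -> pd.DataFrame:
    """Refit OLS on ``n_reps`` simulated tree tables of size ``n``.

    Returns one row per replicate with the fitted coefficients and their
    standard errors; used to check that the generative coefficients are
    recovered within sampling error.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        table = simulate_architecture_table(n, rng)
        fit = ols_fit(table, "db", ["log_cl", "log_cv", "log_tth"])
        rows.append(
            {
                **{k: float(v) for k, v in fit.params.items()},
                **{f"se_{k}": float(v) for k, v in fit.bse.items()},
            }
        )
    return pd.DataFrame(rows)
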