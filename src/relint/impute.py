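"""Chained-equations multiple imputation and pooling rules.

Missing cells are filled by iterated conditional draws, one variable at a
time, with the method chosen by variable type:

* continuous (age, income): predictive mean matching — a Bayesian draw of
  the linear-regression coefficients produces predictions for the missing
  rows, each of which then receives the *observed* value of one of its 5
  nearest donors, so imputations respect the variable's support and skew;
* binary (past-year quit attempt): logistic fit, posterior draw of the
  coefficients, Bernoulli draw;
* unordered categorical (education, region, urges, collapsed motivation):
  multinomial-logit fit, posterior draw, categorical draw.

The conditioning set is every analysis variable except the target (the
intersectionality covariates, urges, calendar year and both outcomes).  The
collapsed 3-category motivation outcome is imputed, not the 7-level scale,
and only for current smokers — it is never assessed for recent ex-smokers,
which is structural missingness, not item non-response.  Each of the m
imputations runs its own independent chain.

Pooling follows Rubin's rules (scalar estimates, Barnard-Rubin degrees of
freedom) and the Meng-Rubin (D3) likelihood-ratio pooling for tests across
imputed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import glm
from .glm import (ModelSpec, build_design, fit_logistic, fit_multinomial,
                  _logistic_loglik, _multinomial_loglik, freeze_knots)

__all__ = ["ImputationSet", "chained_imputation", "pool_scalar", "pool_lr",
           "PooledScalar"]

#: default analysis variables entering every conditional model
_PREDICTORS = ("age", "sex", "education", "region", "income", "urges",
               "year", "qa", "mtss3")

_CONTINUOUS = {"age", "income"}
_BINARY = {"qa"}
_RIDGE = 1e-6  # tiny ridge in the conditional fits, for bootstrap-grade stability


@dataclass
class ImputationSet:
    completed: list[pd.DataFrame]
    m: int
    iterations: int
    seed: int
    variables_imputed: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.m != len(self.completed):
            raise ValueError("m must equal the number of completed tables")


def _complete_set(table: pd.DataFrame, m: int, seed: int) -> ImputationSet:
    return ImputationSet(completed=[table.copy() for _ in range(m)], m=m,
                         iterations=0, seed=seed, variables_imputed=[])


def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Dummy/linear encoding of the conditioning set, excluding the target.

    The motivation outcome gets an explicit "not_assessed" level for recent
    ex-smokers so its structural missingness never blocks other variables.
    """
    cols = [np.ones(len(df))]
    for name in _PREDICTORS:
        if name == exclude or name not in df.columns:
            continue
        if name in _CONTINUOUS:
            cols.append(df[name].to_numpy(dtype=float))
        elif name == "year":
            cols.append(df[name].to_numpy(dtype=float)
                        - float(df[name].min()))
        else:
            levels = list(glm.LEVELS.get(name, []))
            if name == "qa":
                levels = ["no", "yes"]
            elif name == "mtss3":
                levels = glm.MTSS3_LEVELS + ["not_assessed"]
            vals = df[name].astype(object).to_numpy()
            if name == "mtss3" and "smoker_status" in df.columns:
                vals = vals.copy()
                vals[df["smoker_status"].to_numpy() == "recent_ex"] = "not_assessed"
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
    return np.column_stack(cols)


def _draw_beta(rng, beta, cov):
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(beta)))
    return beta + L @ rng.standard_normal(len(beta))


def _impute_continuous(rng, X, y, obs, mis, donors=5):
    """Bayesian linear regression + predictive mean matching (type 1)."""
    Xo, yo = X[obs], y[obs]
    XtX = Xo.T @ Xo + _RIDGE * np.eye(X.shape[1])
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(len(yo) - X.shape[1], 1)
    sigma2 = (resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    beta_star = _draw_beta(rng, beta_hat, sigma2 * XtX_inv)
    pred_obs = Xo @ beta_hat
    pred_mis = X[mis] @ beta_star
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    out = np.empty(mis.sum() if mis.dtype == bool else len(mis))
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_obs = len(yo)
    for i, (pm, p0) in enumerate(zip(pred_mis, pos)):
        lo = max(p0 - donors, 0)
        hi = min(p0 + donors, n_obs)
        window = order[lo:hi]
        d = np.abs(pred_obs[window] - pm)
        nearest = window[np.argsort(d)[:donors]]
        out[i] = yo[rng.choice(nearest)]
    return out


def _impute_binary(rng, X, y01, obs, mis):
    f = fit_logistic(X[obs], y01[obs], penalty=_RIDGE)
    beta = _draw_beta(rng, f.coefficients, f.covariance)
    p = expit(X[mis] @ beta)
    return (rng.random(len(p)) < p).astype(int)


def _impute_categorical(rng, X, codes, obs, mis, K):
    f = fit_multinomial(X[obs], codes[obs], n_categories=K, penalty=_RIDGE)
    flat = _draw_beta(rng, f.coefficients.ravel(), f.covariance)
    B = flat.reshape(K - 1, X.shape[1])
    P = glm._multinomial_probs(X[mis], B)
    u = rng.random(len(P))
    cum = np.cumsum(P, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def chained_imputation(table: pd.DataFrame, m: int, iterations: int = 10,
                       seed: int = 0) -> ImputationSet:
    """Produce ``m`` completed copies of ``table`` by chained equations.

    Requires ``m >= 2`` and the recoded outcome columns (``mtss3``, ``qa``)
    to be present.  A table without missing cells returns ``m`` identical
    copies.  Chain non-convergence is not detected; ``iterations`` defaults
    to 10 sweeps, a conventional choice.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    df = table.copy()

    targets = []
    for name in ("education", "region", "urges", "income", "age", "qa", "mtss3"):
        if name not in df.columns:
            continue
        if name == "mtss3":
            eligible = df["smoker_status"].to_numpy() == "current" \
                if "smoker_status" in df.columns else np.ones(len(df), bool)
        else:
            eligible = np.ones(len(df), dtype=bool)
        if name in _CONTINUOUS:
            miss = ~np.isfinite(df[name].to_numpy(dtype=float)) & eligible
        else:
            miss = df[name].isna().to_numpy() & eligible
        if miss.any():
            if not (~miss & eligible).any():
                raise ValueError(f"variable {name!r} is 100% missing")
            targets.append((name, miss, eligible))
    if not targets:
        out = _complete_set(df, m, seed)
        out.iterations = iterations
        return out

    completed = []
    for imp in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, imp]))
        work = df.copy()
        # initial fill: random draws from the observed margin
        for name, miss, eligible in targets:
            obsvals = work.loc[(~miss) & eligible, name].dropna().to_numpy()
            fill = rng.choice(obsvals, size=int(miss.sum()))
            col = work[name].copy()
            col.iloc[np.flatnonzero(miss)] = fill
            work[name] = col
        for _ in range(iterations):
            for name, miss, eligible in targets:
                X = _encode_predictors(work, exclude=name)
                obs = (~miss) & eligible
                mi = np.flatnonzero(miss)
                if name in _CONTINUOUS:
                    y = work[name].to_numpy(dtype=float)
                    vals = _impute_continuous(rng, X, y, obs, miss)
                    col = y.copy()
                    col[mi] = vals
                    work[name] = col
                elif name in _BINARY:
                    y01 = (work[name].astype(str) == "yes").to_numpy(dtype=int)
                    vals = _impute_binary(rng, X, y01, obs, miss)
                    col = work[name].astype(object)
                    col.iloc[mi] = np.where(vals == 1, "yes", "no")
                    work[name] = col
                else:
                    levels = (glm.MTSS3_LEVELS if name == "mtss3"
                              else glm.LEVELS[name])
                    codes = pd.Categorical(work[name].astype(str),
                                           categories=levels).codes.astype(int)
                    vals = _impute_categorical(rng, X, codes, obs, miss,
                                               K=len(levels))
                    col = work[name].astype(object)
                    col.iloc[mi] = [levels[v] for v in vals]
                    work[name] = col
        # keep raw outcome columns consistent with imputed recodes
        completed.append(work)
    return ImputationSet(completed=completed, m=m, iterations=iterations,
                         seed=seed, variables_imputed=[t[0] for t in targets])


@dataclass
class PooledScalar:
    estimate: float
    total_variance: float
    within: float
    between: float
    df: float
    ci_low: float
    ci_high: float


def pool_scalar(estimates, variances, dfcom: float | None = None,
                alpha: float = 0.05) -> PooledScalar:
    """Rubin's rules for one scalar across m imputations.

    Pooled estimate = mean; total variance T = W + (1 + 1/m) B with W the
    mean within-imputation variance and B the between-imputation variance.
    Degrees of freedom follow Barnard-Rubin when the complete-data df is
    supplied, else the classic large-sample formula.  With B = 0 the CI is
    normal-based (df -> infinity).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = len(q)
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1)) if m > 1 else 0.0
    T = W + (1 + 1 / m) * B
    if B > 0 and m > 1:
        rm = (1 + 1 / m) * B / W if W > 0 else np.inf
        gamma = (1 + 1 / m) * B / T
        nu_old = (m - 1) * (1 + 1 / rm) ** 2 if np.isfinite(rm) else m - 1
        if dfcom is not None and np.isfinite(dfcom):
            nu_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - gamma)
            nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            nu = nu_old
        tq = stats.t.ppf(1 - alpha / 2, nu)
    else:
        nu = np.inf
        tq = stats.norm.ppf(1 - alpha / 2)
    half = tq * np.sqrt(T)
    return PooledScalar(estimate=qbar, total_variance=T, within=W, between=B,
                        df=float(nu), ci_low=qbar - half, ci_high=qbar + half)


def _loglik_at(spec: ModelSpec, df: pd.DataFrame, coef: np.ndarray) -> float:
    d = build_design(df, spec)
    if spec.outcome == "qa":
        return _logistic_loglik(d.X, d.y, coef)
    return _multinomial_loglik(d.X, d.y, coef.reshape(-1, d.X.shape[1]))


def pool_lr(full_spec: ModelSpec, reduced_spec: ModelSpec,
            imputation_set: ImputationSet):
    """Meng-Rubin (D3) pooled likelihood-ratio test across imputations.

    Per imputation the usual LR statistic is computed at the per-imputation
    MLEs; the statistics are then recomputed at the *pooled* (mean)
    parameter estimates, the average relative increase in variance r~ is
    formed, and D3 = d_L / (k (1 + r~)) is referred to an F(k, nu)
    distribution.  With identical imputations (no missing data) this
    reduces exactly to the single-dataset chi-square test.

    Returns (D3 statistic, k, pooled p-value, mean LR statistic).
    """
    if imputation_set.m < 2:
        raise ValueError("pooled LR test needs m >= 2 imputations")
    m = imputation_set.m
    d_mle = []
    coefs_full, coefs_red = [], []
    k = None
    for dfi in imputation_set.completed:
        ff = glm.fit_model(dfi, full_spec, freeze=False)
        fr = glm.fit_model(dfi, reduced_spec, freeze=False)
        if k is None:
            k = ff.n_params - fr.n_params
            if k <= 0:
                raise ValueError("reduced model is not a strict submodel")
        d_mle.append(2.0 * (ff.loglik - fr.loglik))
        coefs_full.append(np.atleast_2d(ff.coefficients).ravel())
        coefs_red.append(np.atleast_2d(fr.coefficients).ravel())
    bf = np.mean(coefs_full, axis=0)
    br = np.mean(coefs_red, axis=0)
    d_pooled = [2.0 * (_loglik_at(full_spec, dfi, bf)
                       - _loglik_at(reduced_spec, dfi, br))
                for dfi in imputation_set.completed]
    dbar_m = float(np.mean(d_mle))
    dbar_L = float(np.mean(d_pooled))
    r = (m + 1) / (k * (m - 1)) * (dbar_m - dbar_L)
    r = max(r, 0.0)
    D3 = dbar_L / (k * (1.0 + r))
    a = k * (m - 1)
    if r <= 1e-12:
        p = float(stats.chi2.sf(dbar_L, k))
        return D3, k, p, dbar_m
    if a > 4:
        nu = 4 + (a - 4) * (1 + (1 - 2 / a) / r) ** 2
    else:
        nu = a * (1 + 1 / k) * (1 + 1 / r) ** 2 / 2
    p = float(stats.f.sf(D3, k, nu))
    return D3, k, p, dbar_m
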