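"""Pooled odds-ratio tables, marginal probability surfaces, external validation.

These are the pipeline's result products: an OR table pooling the winning
model's coefficients across imputations by Rubin's rules (spline-coded
covariates reported as contrasts at substantively chosen values against a
reference value), average-marginal-prediction grids that visualise the
interaction surfaces, and the learning-vs-validation accuracy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct

import numpy as np
import pandas as pd

from .glm import (FitResult, ModelSpec, build_design, fit_model,
                  predict_probs_design)
from .impute import ImputationSet, pool_scalar
from .scoring import ScoreReport, accuracy_change, brier_score, pdi
from .splines import evaluate_contrast

__all__ = ["pooled_or_table", "marginal_probabilities", "external_validate",
           "DEFAULT_CONTRASTS"]

#: default evaluation points (value grid, reference) for spline-coded covariates
DEFAULT_CONTRASTS = {
    "age": ((20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0), 20.0),
    "income": ((0.5, 1.5, 2.5, 3.5), 0.5),
}


def _check_same_spec(fits: list[FitResult]):
    if not fits:
        raise ValueError("no fits to pool")
    s0 = fits[0].spec.to_json()
    if any(f.spec.to_json() != s0 for f in fits[1:]):
        raise ValueError("all fits must share one model spec")


def pooled_or_table(fits: list[FitResult],
                    contrast_values: dict | None = None) -> pd.DataFrame:
    """Rubin-pooled OR table across m imputation fits.

    Plain coefficients are pooled on the log-odds scale and exponentiated;
    reference levels appear as OR = 1 rows.  Continuous covariates modelled
    with splines are reported as contrasts at the configured values against
    their reference value, each contrast pooled the same way.
    """
    _check_same_spec(fits)
    spec = fits[0].spec
    contrast_values = {**DEFAULT_CONTRASTS, **(contrast_values or {})}
    m = len(fits)
    p = len(fits[0].column_names)
    rows = []
    for gi, contrast in enumerate(fits[0].contrast_names):
        # reference rows for categorical terms
        for t in spec.terms:
            if t.form == "categorical":
                ref = spec.reference_levels.get(t.name)
                rows.append({"contrast": contrast, "term": f"{t.name}[{ref}]",
                             "or": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                             "reference": True})
        for j, name in enumerate(fits[0].column_names):
            base = name.split("[")[0].split("'")[0]
            term = next((t for t in spec.terms if t.name == base), None)
            if term is not None and term.spline_k is not None and ":" not in name:
                continue  # spline columns reported as contrasts below
            ests, vars_ = [], []
            for f in fits:
                coef = np.atleast_2d(f.coefficients)
                ests.append(coef[gi, j])
                vars_.append(f.covariance[gi * p + j, gi * p + j])
            pl = pool_scalar(ests, vars_)
            rows.append({"contrast": contrast, "term": name,
                         "or": float(np.exp(pl.estimate)),
                         "ci_low": float(np.exp(pl.ci_low)),
                         "ci_high": float(np.exp(pl.ci_high)),
                         "reference": False})
        for t in spec.terms:
            if t.spline_k is None:
                continue
            values, ref = contrast_values.get(t.name, ((), None))
            if ref is None:
                continue
            per_fit = [evaluate_contrast(f, t.name, values, ref) for f in fits]
            per_fit = [[r for r in rs if r["category"] == contrast]
                       for rs in per_fit]
            for vi, v in enumerate(values):
                ests = [rs[vi]["log_or"] for rs in per_fit]
                vars_ = [rs[vi]["se"] ** 2 for rs in per_fit]
                pl = pool_scalar(ests, vars_)
                rows.append({"contrast": contrast,
                             "term": f"{t.name}[{v:g} vs {ref:g}]",
                             "or": float(np.exp(pl.estimate)),
                             "ci_low": float(np.exp(pl.ci_low)),
                             "ci_high": float(np.exp(pl.ci_high)),
                             "reference": False})
    return pd.DataFrame(rows)


def _amp_and_gradient(fit: FitResult, X: np.ndarray):
    """Average marginal prediction per category + gradient w.r.t. parameters."""
    P = predict_probs_design(fit, X)
    if P.ndim == 1:
        P = np.column_stack([1 - P, P])
        multi = False
    else:
        multi = True
    pbar = P.mean(axis=0)
    p_cols = X.shape[1]
    K = P.shape[1]
    grads = []
    for k in range(1, K):
        if multi:
            # d pbar_k / d beta_{g,j} over contrasts g = 1..K-1
            g = np.empty((K - 1) * p_cols)
            for gcon in range(1, K):
                w = P[:, k] * ((1.0 if gcon == k else 0.0) - P[:, gcon])
                g[(gcon - 1) * p_cols:gcon * p_cols] = (w[:, None] * X).mean(axis=0)
            grads.append((k, pbar[k], g))
        else:
            w = P[:, 1] * (1 - P[:, 1])
            grads.append((k, pbar[1], (w[:, None] * X).mean(axis=0)))
    return grads


def marginal_probabilities(fits: list[FitResult], tables: list[pd.DataFrame],
                           grid_axes: dict[str, list]) -> pd.DataFrame:
    """Average-marginal-prediction grid, Rubin-pooled across imputations.

    For every grid cell the grid covariates are set to the cell values for
    *all* records and predictions are averaged over the empirical
    distribution of the remaining covariates (marginal standardisation).
    Point estimates and delta-method variances are pooled on the logit
    scale, and the CI back-transformed, keeping it inside [0, 1].
    """
    if len(fits) != len(tables):
        raise ValueError("need one fitted model per imputed table")
    _check_same_spec(fits)
    spec = fits[0].spec
    axes = list(grid_axes)
    mesh = list(iproduct(*(grid_axes[a] for a in axes)))
    out = []
    # observed ranges for the extrapolation flag
    obs_range = {a: (tables[0][a].min(), tables[0][a].max())
                 for a in axes if np.issubdtype(tables[0][a].dtype, np.number)}
    cat_names = (["qa"] if spec.outcome == "qa" else fits[0].contrast_names)
    for cell in mesh:
        per_imp: dict[str, list] = {}
        for f, tab in zip(fits, tables):
            t = tab.copy()
            for a, v in zip(axes, cell):
                t[a] = v
            d = build_design(t, spec)
            for k, pbar, grad in _amp_and_gradient(f, d.X):
                var = float(grad @ f.covariance @ grad)
                name = cat_names[k - 1] if spec.outcome != "qa" else "qa"
                per_imp.setdefault(name, []).append((pbar, var))
        extrap = any(
            a in obs_range and not obs_range[a][0] <= v <= obs_range[a][1]
            for a, v in zip(axes, cell))
        probs = {}
        for name, vals in per_imp.items():
            ps = np.array([v[0] for v in vals])
            vs = np.array([v[1] for v in vals])
            # pool on the logit scale (delta method for the variance)
            ps_c = np.clip(ps, 1e-12, 1 - 1e-12)
            lg = np.log(ps_c / (1 - ps_c))
            lv = vs / (ps_c * (1 - ps_c)) ** 2
            pl = pool_scalar(lg, lv)
            probs[name] = (float(ps.mean()),
                           float(1 / (1 + np.exp(-pl.ci_low))),
                           float(1 / (1 + np.exp(-pl.ci_high))))
        if spec.outcome == "mtss3":
            # reference-category estimate completes the simplex
            pa = 1.0 - sum(v[0] for v in probs.values())
            probs = {"absence": (pa, np.nan, np.nan), **probs}
        for name, (pt, lo, hi) in probs.items():
            row = {a: v for a, v in zip(axes, cell)}
            row.update({"category": name, "probability": pt,
                        "ci_low": lo, "ci_high": hi, "extrapolated": extrap})
            out.append(row)
    return pd.DataFrame(out)


@dataclass
class ValidationReport:
    rule: str
    score_learn: float
    score_valid: float
    accuracy_change_pct: float


def external_validate(winner: ModelSpec, learn_set: ImputationSet,
                      valid_set: ImputationSet, rule: str) -> ValidationReport:
    """Refit the winner on learning imputations, score on validation data.

    The learning score is the mean in-sample score over the learning
    imputations.  For the validation score the Rubin point estimate (mean
    coefficient vector) of the learning fits predicts each validation
    imputation with the learning-data knots, and the scores are averaged.
    Positive accuracy change = degradation on external data.
    """
    if winner is None:
        raise ValueError("no winning model spec to validate")
    from .search import _analysis_frame  # local import to avoid a cycle

    fits = [fit_model(_analysis_frame(dfi, winner.outcome), winner, freeze=False)
            for dfi in learn_set.completed]
    learn_scores = []
    for f, dfi in zip(fits, learn_set.completed):
        d = build_design(_analysis_frame(dfi, winner.outcome), winner)
        P = predict_probs_design(f, d.X)
        learn_scores.append(brier_score(d.y, P).value if rule == "brier"
                            else pdi(d.y, P).value)
    coef_mean = np.mean([np.atleast_2d(f.coefficients) for f in fits], axis=0)
    pooled_fit = FitResult(
        spec=winner, coefficients=coef_mean if coef_mean.shape[0] > 1 else coef_mean[0],
        covariance=fits[0].covariance, loglik=np.nan, n_obs=fits[0].n_obs,
        n_params=fits[0].n_params, converged=all(f.converged for f in fits),
        separation=False, column_names=fits[0].column_names,
        contrast_names=fits[0].contrast_names)
    valid_scores = []
    for dfi in valid_set.completed:
        d = build_design(_analysis_frame(dfi, winner.outcome), winner)
        P = predict_probs_design(pooled_fit, d.X)
        valid_scores.append(brier_score(d.y, P).value if rule == "brier"
                            else pdi(d.y, P).value)
    sl, sv = float(np.mean(learn_scores)), float(np.mean(valid_scores))
    return ValidationReport(rule=rule, score_learn=sl, score_valid=sv,
                            accuracy_change_pct=accuracy_change(sl, sv, rule))
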