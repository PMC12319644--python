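"""Scoring rules and model diagnostics.

Two proper scoring rules drive model selection:

* **Brier score** for the binary quit-attempt outcome — the mean squared
  difference between outcome and predicted probability; lower is better.
* **Polytomous discrimination index (PDI)** for the 3-category motivation
  outcome — draw one observation from each outcome category; PDI_j is the
  probability that the observation truly in category j receives the highest
  predicted probability *for* category j among the drawn tuple, and PDI is
  the mean of PDI_j over categories.  Ties at the maximum split credit
  1/t, so a completely uninformative model scores exactly 1/K.

The Brant test diagnoses the proportional-odds assumption of an ordinal
model by fitting all cumulative binary splits and Wald-testing equality of
their slopes (Brant 1990 covariance construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct

import numpy as np
from scipy import stats

from .glm import fit_logistic

__all__ = ["ScoreReport", "brier_score", "pdi", "brant_test", "accuracy_change"]


@dataclass
class ScoreReport:
    rule: str                  # "brier" or "pdi"
    value: float
    n_eval: int
    per_category: np.ndarray | None = None


def brier_score(y, p) -> ScoreReport:
    """Mean of (y_i - p_i)^2 for a binary outcome."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return ScoreReport(rule="brier", value=float(np.mean((y - p) ** 2)), n_eval=len(y))


def pdi(y, P) -> ScoreReport:
    """Polytomous discrimination index with 1/t tie-splitting.

    ``y``: integer category codes 0..K-1; ``P``: (n, K) predicted probability
    matrix.  Every category must be represented at least once.

    Computed by a per-category sort-and-count scheme: for category j, rank
    every observation's predicted probability *for category j*; for each
    category-j member, count (via binary search on the other categories'
    sorted values) the tuples in which it is strictly highest, and award
    fractional credit over ties.  O(n log n) per category versus the
    O(prod n_c) of naive tuple enumeration.
    """
    y = np.asarray(y, dtype=int)
    P = np.asarray(P, dtype=float)
    n, K = P.shape
    if len(y) != n:
        raise ValueError("y and P must have equal length")
    counts = np.bincount(y, minlength=K)
    if np.any(counts == 0):
        raise ValueError("PDI undefined: every category must appear at least once")
    total_tuples = float(np.prod(counts.astype(float)))

    per_cat = np.empty(K)
    for j in range(K):
        v = P[:, j]
        vj = v[y == j]
        others = [np.sort(v[y == c]) for c in range(K) if c != j]
        lt = [np.searchsorted(g, vj, side="left").astype(float) for g in others]
        eq = [np.searchsorted(g, vj, side="right").astype(float) - l
              for g, l in zip(others, lt)]
        credit = np.zeros_like(vj)
        # sum over which of the other categories contribute a tied member
        for pick in iproduct((0, 1), repeat=len(others)):
            term = np.ones_like(vj)
            for c, tied in enumerate(pick):
                term = term * (eq[c] if tied else lt[c])
            credit += term / (1.0 + sum(pick))
        per_cat[j] = credit.sum() / total_tuples
    return ScoreReport(rule="pdi", value=float(per_cat.mean()), n_eval=n,
                       per_category=per_cat)


def brant_test(y_ord, X, column_names=None):
    """Brant test of the proportional-odds assumption.

    ``y_ord``: integer ordinal codes 0..J-1 (J >= 3); ``X``: (n, p) slope
    design *without* an intercept column.  Fits the J-1 cumulative binary
    models P(y >= j) and Wald-tests equality of each slope across splits,
    using the Brant (1990) joint covariance of the stacked estimates.

    Returns a dict with ``statistic``, ``df``, ``p`` (global test) and a
    ``per_variable`` list of (name, statistic, df, p).
    """
    y = np.asarray(y_ord, dtype=int)
    X = np.asarray(X, dtype=float)
    J = int(y.max()) + 1
    if J < 3:
        raise ValueError("Brant test undefined for fewer than 3 ordered levels")
    n, p = X.shape
    Xi = np.column_stack([np.ones(n), X])
    fits, pis = [], []
    for j in range(1, J):
        z = (y >= j).astype(float)
        f = fit_logistic(Xi, z)
        fits.append(f)
        pis.append(1.0 / (1.0 + np.exp(-(Xi @ f.coefficients))))

    M = J - 1
    q = p + 1
    # joint covariance of stacked (intercept+slope) estimates
    V = np.zeros((M * q, M * q))
    invinfo = []
    for j in range(M):
        wj = pis[j] * (1 - pis[j])
        invinfo.append(np.linalg.inv((Xi.T * wj) @ Xi))
    for j in range(M):
        for k in range(j, M):
            # cov(1{y>=j+1}, 1{y>=k+1}) = pi_k (1 - pi_j) for j <= k
            wjk = pis[k] * (1 - pis[j])
            mid = (Xi.T * wjk) @ Xi
            blk = invinfo[j] @ mid @ invinfo[k]
            V[j * q:(j + 1) * q, k * q:(k + 1) * q] = blk
            V[k * q:(k + 1) * q, j * q:(j + 1) * q] = blk.T

    beta = np.concatenate([f.coefficients for f in fits])  # (M*q,)
    # contrasts: slope_m(j) - slope_m(j+1) for each variable m, split j
    rows = []
    var_rows: list[list[int]] = [[] for _ in range(p)]
    for m in range(p):
        for j in range(M - 1):
            r = np.zeros(M * q)
            r[j * q + 1 + m] = 1.0
            r[(j + 1) * q + 1 + m] = -1.0
            var_rows[m].append(len(rows))
            rows.append(r)
    D = np.array(rows)
    d = D @ beta
    Vd = D @ V @ D.T
    stat = float(d @ np.linalg.solve(Vd, d))
    df = (J - 2) * p
    out = {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}
    names = column_names or [f"x{m}" for m in range(p)]
    per_var = []
    for m in range(p):
        idx = var_rows[m]
        dm = d[idx]
        Vm = Vd[np.ix_(idx, idx)]
        sm = float(dm @ np.linalg.solve(Vm, dm))
        dfm = J - 2
        per_var.append((names[m], sm, dfm, float(stats.chi2.sf(sm, dfm))))
    out["per_variable"] = per_var
    return out


def accuracy_change(score_learn: float, score_valid: float, rule: str) -> float:
    """Percent degradation of predictive accuracy from learning to validation.

    PDI is already an accuracy (higher = better): the change is the relative
    drop in PDI.  The Brier score is a loss, so it is mapped to the accuracy
    scale 1 - Brier before taking the relative drop.  Positive values mean
    the model predicts worse on validation data.
    """
    if rule == "pdi":
        return 100.0 * (score_learn - score_valid) / score_learn
    if rule == "brier":
        return 100.0 * ((1.0 - score_learn) - (1.0 - score_valid)) / (1.0 - score_learn)
    raise ValueError(f"unknown rule {rule!r}")
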