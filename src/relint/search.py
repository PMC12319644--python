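"""Candidate enumeration and bootstrap out-of-bag model selection.

The candidate space crosses the allowed functional forms of the continuous
covariates (linear or restricted cubic splines with 3-5 knots) with subsets
of pairwise interactions among the five intersectionality covariates (age,
sex, education, income, region).  Every candidate keeps the mandatory base
terms (urges to smoke, calendar time).

Selection works on repeated bootstrap samples of the learning data: the
bootstrap sample is the inner learning set, the out-of-bag observations the
inner validation set.  Each candidate is fitted on the inner learning set
and scored on the out-of-bag set (PDI for the multinomial motivation
outcome, Brier score for the binary quit attempt), scores are averaged over
the imputed datasets and over replicates, and the candidate that is best on
average wins.  Selecting on out-of-bag predictions rather than in-sample
fit is what suppresses spurious interactions: an interaction that only fits
noise does not survive averaging over many resampled versions of the data.

A winning interaction is finally confirmed with a pooled likelihood-ratio
test against the same model without the interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product as iproduct

import numpy as np
import pandas as pd

from .glm import (ModelSpec, Term, DEFAULT_REFERENCES, build_design, bic,
                  fit_logistic, fit_multinomial, fit_model, freeze_knots,
                  predict_probs_design, MTSS3_LEVELS)
from .impute import ImputationSet, pool_lr
from .scoring import brier_score, pdi

log = logging.getLogger(__name__)

__all__ = ["CandidateSpace", "SelectionResult", "enumerate_candidates",
           "bootstrap_select", "backward_eliminate", "best_subset",
           "confirm_interaction"]

INTERSECTIONALITY = ("age", "sex", "education", "income", "region")


@dataclass
class CandidateSpace:
    """Declarative candidate model space."""

    outcome: str
    base_terms: list[Term] = field(default_factory=list)
    categorical_terms: list[Term] = field(default_factory=lambda: [
        Term("sex", "categorical"), Term("education", "categorical"),
        Term("region", "categorical")])
    spline_options: dict[str, list[str]] = field(default_factory=lambda: {
        "age": ["rcs4"], "income": ["linear"]})
    interaction_pool: list[tuple[str, str]] = field(default_factory=lambda: [
        tuple(p) for p in combinations(INTERSECTIONALITY, 2)])
    max_interactions: int = 1

    def __post_init__(self):
        self.interaction_pool = [tuple(p) for p in self.interaction_pool]
        seen = set()
        for p in self.interaction_pool:
            key = frozenset(p)
            if key in seen:
                raise ValueError(f"duplicate interaction pair {p}")
            seen.add(key)
        if self.max_interactions < 0:
            raise ValueError("max_interactions must be >= 0")


def default_space(outcome: str) -> CandidateSpace:
    """Default space: mandatory urges + time, five intersection covariates."""
    time_term = Term("year", "categorical" if outcome == "mtss3" else "linear")
    return CandidateSpace(
        outcome=outcome,
        base_terms=[Term("urges", "categorical"), time_term],
    )


@dataclass
class SelectionResult:
    winner: ModelSpec
    candidates: list[ModelSpec]
    scores: np.ndarray          # (B, n_candidates), NaN = skipped replicate
    mean_scores: np.ndarray     # (n_candidates,)
    rule: str
    B: int
    winner_index: int
    lr_confirmation: dict | None = None


def enumerate_candidates(space: CandidateSpace) -> list[ModelSpec]:
    """Cartesian product of spline options x interaction subsets (hierarchy kept)."""
    cont_names = list(space.spline_options)
    form_combos = list(iproduct(*(space.spline_options[n] for n in cont_names)))
    inter_subsets = [()]
    for r in range(1, space.max_interactions + 1):
        inter_subsets.extend(combinations(space.interaction_pool, r))
    out = []
    for forms in form_combos:
        terms = (list(space.base_terms) + list(space.categorical_terms)
                 + [Term(n, f) for n, f in zip(cont_names, forms)])
        for inters in inter_subsets:
            out.append(ModelSpec(outcome=space.outcome, terms=list(terms),
                                 interactions=[tuple(p) for p in inters],
                                 reference_levels=dict(DEFAULT_REFERENCES)))
    return out


def _analysis_frame(df, outcome):
    if outcome == "mtss3":
        return df[df["smoker_status"] == "current"] if "smoker_status" in df.columns else df
    return df


def _fit_design(X, y, outcome, beta0=None):
    if outcome == "qa":
        return fit_logistic(X, y, beta0=beta0)
    return fit_multinomial(X, y, n_categories=len(MTSS3_LEVELS), beta0=beta0)


def _score_oob(fit, X_oob, y_oob, rule):
    P = predict_probs_design(fit, X_oob)
    if rule == "brier":
        return brier_score(y_oob, P).value
    return pdi(y_oob, P).value


def bootstrap_select(imputation_set: ImputationSet, candidates: list[ModelSpec],
                     B: int, rule: str, seed: int,
                     max_retries: int = 10) -> SelectionResult:
    """Select the candidate with the best mean out-of-bag score over B replicates.

    Each replicate draws ids with replacement (the inner learning set); the
    out-of-bag ids form the inner validation set.  Candidate scores are
    averaged across the imputed datasets within a replicate.  Replicates in
    which a categorical level is absent from the bootstrap sample (or the
    out-of-bag set is too small to score) are redrawn up to ``max_retries``
    times and then skipped with a log entry.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    if not candidates:
        raise ValueError("no candidates to select among")
    rule = rule.lower()
    if rule not in {"pdi", "brier"}:
        raise ValueError(f"unknown rule {rule!r}")
    outcome = candidates[0].outcome

    # freeze spline knots once, on the full learning data (first imputation)
    ref_frame = _analysis_frame(imputation_set.completed[0], outcome)
    for spec in candidates:
        freeze_knots(ref_frame, spec)

    # pre-build designs: one (X, y) per (imputation, candidate), shared rows
    designs = []
    cat_cols = sorted({t.name for c in candidates for t in c.terms
                       if t.form == "categorical"})
    for dfi in imputation_set.completed:
        sub = _analysis_frame(dfi, outcome)
        per_cand = [build_design(sub, spec) for spec in candidates]
        n0 = len(per_cand[0].index)
        if any(len(d.index) != n0 for d in per_cand):
            raise ValueError("candidates disagree on analysis rows")
        cat_levels = {}
        for c in cat_cols:
            if c in sub.columns:
                codes = pd.Categorical(
                    sub.iloc[per_cand[0].index][c].astype(str)).codes
                cat_levels[c] = (codes.astype(np.intp), int(codes.max()) + 1)
        # full-data fits warm-start the per-replicate refits
        warm = [np.asarray(_fit_design(d.X, d.y, outcome).coefficients)
                for d in per_cand]
        designs.append((per_cand, cat_levels, warm))

    n = len(designs[0][0][0].index)
    rng = np.random.default_rng(seed)
    scores = np.full((B, len(candidates)), np.nan)
    n_skipped = 0
    for b in range(B):
        ok = False
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            oob = ~inbag
            if not oob.any():
                continue
            # every categorical level present in the bootstrap sample?
            valid = True
            for _, cat_levels, _ in designs[:1]:
                for codes, n_lev in cat_levels.values():
                    if np.any(np.bincount(codes[idx], minlength=n_lev) == 0):
                        valid = False
                        break
            if not valid:
                continue
            try:
                rep = np.zeros(len(candidates))
                for per_cand, _, warm in designs:
                    for ci, d in enumerate(per_cand):
                        f = _fit_design(d.X[idx], d.y[idx], outcome,
                                        beta0=warm[ci])
                        rep[ci] += _score_oob(f, d.X[oob], d.y[oob], rule)
                scores[b] = rep / len(designs)
                ok = True
            except ValueError:
                continue
            break
        if not ok:
            n_skipped += 1
            log.warning("bootstrap replicate %d skipped after %d retries",
                        b, max_retries)
    mean_scores = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean_scores)):
        raise RuntimeError("all bootstrap replicates were skipped")
    widx = int(np.nanargmax(mean_scores) if rule == "pdi"
               else np.nanargmin(mean_scores))
    return SelectionResult(winner=candidates[widx], candidates=candidates,
                           scores=scores, mean_scores=mean_scores, rule=rule,
                           B=B, winner_index=widx)


def _pooled_bic(imputation_set, spec):
    vals = []
    for dfi in imputation_set.completed:
        sub = _analysis_frame(dfi, spec.outcome)
        vals.append(bic(fit_model(sub, spec, freeze=False)))
    return float(np.mean(vals))


def backward_eliminate(imputation_set: ImputationSet, full_spec: ModelSpec,
                       base_term_names: tuple[str, ...] = ("urges", "year"),
                       ) -> ModelSpec:
    """Backward elimination by pooled BIC, honouring model hierarchy.

    At each step the single admissible simplification that most decreases
    the mean BIC across imputations is applied: dropping an interaction,
    reducing a spline term to linear, or dropping a main effect that is not
    part of any remaining interaction.  Base terms are never dropped.
    Stops when no simplification lowers the BIC.
    """
    ref_frame = _analysis_frame(imputation_set.completed[0], full_spec.outcome)
    spec = freeze_knots(ref_frame, full_spec)
    current_bic = _pooled_bic(imputation_set, spec)
    while True:
        moves = []
        inter_members = {n for p in spec.interactions for n in p}
        for p in spec.interactions:
            moves.append(("drop_inter", p))
        for t in spec.terms:
            if t.name in base_term_names:
                continue
            if t.spline_k is not None:
                moves.append(("to_linear", t.name))
            elif t.name not in inter_members:
                moves.append(("drop_term", t.name))
        if not moves:
            break
        best = None
        for kind, target in moves:
            cand = _apply_move(spec, kind, target)
            val = _pooled_bic(imputation_set, cand)
            if best is None or val < best[0]:
                best = (val, cand)
        if best[0] < current_bic:
            current_bic, spec = best[0], best[1]
        else:
            break
    return spec


def _apply_move(spec: ModelSpec, kind: str, target) -> ModelSpec:
    if kind == "drop_inter":
        inters = [p for p in spec.interactions if p != target]
        terms = list(spec.terms)
    elif kind == "to_linear":
        inters = list(spec.interactions)
        terms = [Term(t.name, "linear") if t.name == target else t
                 for t in spec.terms]
    else:  # drop_term (never part of an interaction)
        inters = list(spec.interactions)
        terms = [t for t in spec.terms if t.name != target]
    ss = {k: v for k, v in spec.spline_specs.items()
          if any(t.name == k and t.spline_k for t in terms)}
    return ModelSpec(outcome=spec.outcome, terms=terms, interactions=inters,
                     reference_levels=dict(spec.reference_levels),
                     spline_specs=ss)


def best_subset(imputation_set: ImputationSet, space: CandidateSpace,
                rule: str, B: int = 200, seed: int = 0) -> SelectionResult:
    """Exhaustive candidate evaluation via bootstrap out-of-bag scoring.

    This is the selection path for the multinomial motivation outcome, for
    which stepwise elimination machinery is not well defined; the binary
    outcome uses it too after a BIC-based backward-elimination prefilter.
    """
    candidates = enumerate_candidates(space)
    log.info("best subset: %d candidates", len(candidates))
    return bootstrap_select(imputation_set, candidates, B=B, rule=rule, seed=seed)


def confirm_interaction(selection: SelectionResult,
                        imputation_set: ImputationSet,
                        alpha: float = 0.05) -> SelectionResult:
    """Pooled LR confirmation of the winner's interaction term(s).

    A winner without interactions passes vacuously.  Otherwise the winner is
    tested against itself minus all interactions via the Meng-Rubin pooled
    LR test; the interaction is retained iff pooled p < alpha.
    """
    winner = selection.winner
    if not winner.interactions:
        selection.lr_confirmation = {"retained": True, "p": None,
                                     "statistic": None, "df": 0}
        return selection
    reduced = winner.drop_interactions()
    if imputation_set.m >= 2:
        frames = [( _analysis_frame(dfi, winner.outcome)) for dfi in imputation_set.completed]
        sub_set = ImputationSet(completed=frames, m=imputation_set.m,
                                iterations=imputation_set.iterations,
                                seed=imputation_set.seed,
                                variables_imputed=imputation_set.variables_imputed)
        stat, k, p, dbar = pool_lr(winner, reduced, sub_set)
        selection.lr_confirmation = {"retained": bool(p < alpha), "p": p,
                                     "statistic": stat, "df": k,
                                     "mean_lr": dbar}
    else:
        from .glm import lr_test
        sub = _analysis_frame(imputation_set.completed[0], winner.outcome)
        ff = fit_model(sub, winner, freeze=False)
        fr = fit_model(sub, reduced, freeze=False)
        stat, df, p = lr_test(ff, fr)
        selection.lr_confirmation = {"retained": bool(p < alpha), "p": p,
                                     "statistic": stat, "df": df}
    return selection
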