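"""End-to-end orchestration: synthesise/load -> recode -> split -> impute ->
diagnose -> select -> confirm -> pool -> validate, with a JSON report.

The three analysis steps mirror the study design: (1) a 70/30 random split
into learning and validation data; (2) bootstrap out-of-bag model selection
within the learning data (PDI for the 3-category motivation outcome, Brier
score for the binary quit attempt), with a pooled likelihood-ratio
confirmation of any winning interaction; (3) external evaluation of the
selected model's predictive accuracy on the validation data.  Imputation is
run separately for learning (m = 10) and validation (m = 20) data to avoid
optimism in the accuracy comparison.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .effects import external_validate, marginal_probabilities, pooled_or_table
from .glm import ModelSpec, Term, build_design, fit_model
from .impute import ImputationSet, chained_imputation, _complete_set
from .scoring import brant_test
from .search import (CandidateSpace, backward_eliminate, bootstrap_select,
                     confirm_interaction, default_space, enumerate_candidates,
                     _analysis_frame)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, with study-scale defaults."""

    generator: synthetic.GeneratorConfig | None = None
    input_csv: str | None = None
    outcomes: tuple[str, ...] = ("mtss3", "qa")
    split_fraction: float = 0.7
    year_keep: tuple[int, int] = (2016, 2020)
    m_learn: int = 10
    m_valid: int = 20
    imputation_iterations: int = 10
    B: int = 200
    m_score: int = 2   # imputations used inside bootstrap scoring (see docs)
    max_interactions: int = 1
    interaction_pool: list | None = None  # None = all 10 intersection pairs
    spline_options: dict = field(default_factory=lambda: {
        "age": ["rcs4"], "income": ["linear"]})
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None
    marginal_grids: bool = True

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")
        for oc in self.outcomes:
            if oc not in {"mtss3", "qa"}:
                raise ValueError(f"unknown outcome {oc!r}")

    def rule_for(self, outcome: str) -> str:
        return "pdi" if outcome == "mtss3" else "brier"


def _load_or_generate(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv:
        return pd.read_csv(config.input_csv)
    gen = config.generator or synthetic.GeneratorConfig(seed=config.seed)
    return synthetic.generate_table(gen)


def _impute(table, m, iterations, seed):
    has_missing = table[["education", "region", "urges", "income", "age",
                         "qa"]].isna().any().any() or \
        table.loc[table.get("smoker_status", "current") == "current", "mtss3"].isna().any()
    if not has_missing or m == 1:
        return _complete_set(table, m, seed)
    return chained_imputation(table, m=m, iterations=iterations, seed=seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report."""
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "stages": {}, "outcomes": {}}

    def stage(name):
        report["stages"][name] = round(time.time() - t0, 2)
        log.info("stage %s done at %.1fs", name, time.time() - t0)

    try:
        df = _load_or_generate(config)
        df = df[(df["year"] >= config.year_keep[0])
                & (df["year"] <= config.year_keep[1])].reset_index(drop=True)
        df = synthetic.recode_outcomes(df)
        stage("data")

        learn, valid = synthetic.split_learning_validation(
            df, config.split_fraction, seed=config.seed + 1)
        report["n_learning"] = int(len(learn))
        report["n_validation"] = int(len(valid))
        stage("split")

        learn_set = _impute(learn, config.m_learn, config.imputation_iterations,
                            seed=config.seed + 11)
        valid_set = _impute(valid, config.m_valid, config.imputation_iterations,
                            seed=config.seed + 17)
        stage("imputation")

        # proportional-odds diagnostic on the collapsed motivation outcome
        if "mtss3" in config.outcomes:
            sub = _analysis_frame(learn_set.completed[0], "mtss3")
            diag_spec = ModelSpec(outcome="mtss3", terms=[
                Term("urges", "categorical"), Term("year", "categorical"),
                Term("sex", "categorical"), Term("education", "categorical"),
                Term("region", "categorical"), Term("age", "linear"),
                Term("income", "linear")])
            d = build_design(sub, diag_spec)
            br = brant_test(d.y, d.X[:, 1:], column_names=d.column_names[1:])
            report["brant"] = {"statistic": br["statistic"], "df": br["df"],
                               "p": br["p"]}
            stage("brant")

        for outcome in config.outcomes:
            rule = config.rule_for(outcome)
            space = default_space(outcome)
            space.spline_options = {k: list(v) for k, v in
                                    config.spline_options.items()}
            space.max_interactions = config.max_interactions
            if config.interaction_pool is not None:
                space.interaction_pool = [tuple(p) for p in
                                          config.interaction_pool]
            candidates = enumerate_candidates(space)
            if outcome == "qa":
                # BE+BIC prefilter: start from the richest candidate forms
                full = ModelSpec(outcome="qa",
                                 terms=candidates[-1].terms,
                                 interactions=list(space.interaction_pool),
                                 reference_levels=dict(candidates[-1].reference_levels))
                pre = backward_eliminate(learn_set, full)
                if pre.to_json() not in {c.to_json() for c in candidates}:
                    candidates = candidates + [pre]
            ms = max(1, min(config.m_score, learn_set.m))
            score_set = ImputationSet(
                completed=learn_set.completed[:ms], m=ms,
                iterations=learn_set.iterations, seed=learn_set.seed,
                variables_imputed=learn_set.variables_imputed)
            sel = bootstrap_select(score_set, candidates, B=config.B,
                                   rule=rule, seed=config.seed + 23)
            sel = confirm_interaction(sel, learn_set, alpha=config.alpha)
            winner = sel.winner
            if sel.lr_confirmation and not sel.lr_confirmation["retained"]:
                winner = winner.drop_interactions()

            frames = [_analysis_frame(dfi, outcome) for dfi in learn_set.completed]
            fits = [fit_model(f, winner, freeze=False) for f in frames]
            or_table = pooled_or_table(fits)
            vrep = external_validate(winner, learn_set, valid_set, rule)

            oc_rep = {
                "rule": rule,
                "winner": winner.to_dict(),
                "winner_interactions": [list(p) for p in winner.interactions],
                "n_candidates": len(sel.candidates),
                "mean_scores": [round(float(s), 6) for s in sel.mean_scores],
                "lr_confirmation": sel.lr_confirmation,
                "score_learn": vrep.score_learn,
                "score_valid": vrep.score_valid,
                "accuracy_change_pct": vrep.accuracy_change_pct,
            }
            if outdir:
                or_table.to_csv(outdir / f"or_table_{outcome}.csv", index=False)
                pd.DataFrame({"candidate": range(sel.scores.shape[1])}).join(
                    pd.DataFrame(sel.scores.T)).to_csv(
                        outdir / f"bootstrap_scores_{outcome}.csv", index=False)
            if config.marginal_grids:
                axes = ({"age": list(np.arange(20, 81, 5.0)),
                         "income": [0.5, 1.5, 2.5]} if outcome == "mtss3" else
                        {"age": list(np.arange(20, 81, 5.0)),
                         "sex": ["male", "female"],
                         "education": ["low", "middle", "high"]})
                grid = marginal_probabilities(fits, frames, axes)
                if outdir:
                    grid.to_csv(outdir / f"marginal_grid_{outcome}.csv",
                                index=False)
                if outcome == "mtss3":
                    low = grid[(grid.income == 0.5)
                               & (grid.category == "motivation")]
                    oc_rep["motivation_peak_age_low_income"] = float(
                        low.loc[low.probability.idxmax(), "age"])
            report["outcomes"][outcome] = oc_rep
            stage(f"model_{outcome}")
    except Exception as exc:
        report["error"] = {"stage": _last_stage(report), "message": str(exc)}
        if outdir:
            (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                           default=_json_default))
        raise

    report["elapsed_s"] = round(time.time() - t0, 2)
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=_json_default))
    return report


def _last_stage(report):
    stages = list(report.get("stages", {}))
    return stages[-1] if stages else "init"


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)
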