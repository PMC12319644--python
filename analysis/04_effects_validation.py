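"""Pooled OR tables, marginal probability surfaces, external validation.

Refits each winning model on the learning imputations, pools coefficients
by Rubin's rules into OR tables, computes average-marginal-prediction
surfaces for the interaction of interest (age x income for motivation,
age x sex x education for quit attempts, drawn as heatmaps), and evaluates
the predictive-accuracy change on the separately imputed validation data.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from relint.effects import (external_validate, marginal_probabilities,
                            pooled_or_table)
from relint.glm import ModelSpec, fit_model
from relint.search import _analysis_frame

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "select_models", Path(__file__).with_name("03_select_models.py"))
_sm = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sm)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def heatmap(grid, value_col, x, y, category, path, title):
    sub = grid[grid.category == category] if "category" in grid else grid
    piv = sub.pivot_table(index=y, columns=x, values=value_col)
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.pcolormesh(piv.columns, piv.index, piv.values, cmap="viridis")
    fig.colorbar(im, ax=ax, label="probability")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main():
    ap = argparse.ArgumentParser()
    ap.parse_args()

    learn_set = _sm.load_imputations("learning")
    valid_set = _sm.load_imputations("validation")

    for outcome, rule in (("mtss3", "pdi"), ("qa", "brier")):
        winner = ModelSpec.from_json(
            (RESULTS / f"winner_{outcome}.json").read_text())
        frames = [_analysis_frame(c, outcome) for c in learn_set.completed]
        fits = [fit_model(f, winner, freeze=False) for f in frames]

        or_tab = pooled_or_table(fits)
        or_tab.to_csv(RESULTS / f"or_table_{outcome}.csv", index=False)

        if outcome == "mtss3":
            axes = {"age": list(np.arange(20.0, 81.0, 2.0)),
                    "income": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]}
        else:
            axes = {"age": list(np.arange(20.0, 81.0, 2.0)),
                    "sex": ["male", "female"],
                    "education": ["low", "middle", "high"]}
        grid = marginal_probabilities(fits, frames, axes)
        grid.to_csv(RESULTS / f"marginal_grid_{outcome}.csv", index=False)
        if outcome == "mtss3":
            heatmap(grid, "probability", "age", "income", "motivation",
                    RESULTS / "fig_motivation_age_income.png",
                    "P(motivation to stop) by age and income")
            mot = grid[(grid.category == "motivation") & (grid.income == 0.5)]
            print(f"[mtss3] motivation peak age (income 0.5): "
                  f"{mot.loc[mot.probability.idxmax(), 'age']:.0f}")

        rep = external_validate(winner, learn_set, valid_set, rule)
        print(f"[{outcome}] {rule}: learning {rep.score_learn:.4f}, "
              f"validation {rep.score_valid:.4f}, "
              f"accuracy change {rep.accuracy_change_pct:+.2f}%")
        (RESULTS / f"validation_{outcome}.json").write_text(json.dumps({
            "rule": rule, "score_learn": rep.score_learn,
            "score_valid": rep.score_valid,
            "accuracy_change_pct": rep.accuracy_change_pct}, indent=2))


if __name__ == "__main__":
    main()
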