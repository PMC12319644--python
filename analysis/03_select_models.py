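"""Bootstrap out-of-bag model selection for both cessation outcomes.

For the 3-category motivation outcome the full candidate space is scored by
mean out-of-bag PDI (best-subset search); for the binary quit attempt a
BIC-based backward elimination prefilters the model, and the candidate
space is scored by mean out-of-bag Brier.  Winning interactions are
confirmed by a pooled likelihood-ratio test.  Winner specs and the
replicate-level score distributions go under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from relint import synthetic as syn
from relint.impute import ImputationSet
from relint.search import (backward_eliminate, bootstrap_select,
                           confirm_interaction, default_space,
                           enumerate_candidates)
from relint.glm import ModelSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"


def load_imputations(name):
    outdir = RESULTS / "imputed"
    manifest = json.loads((outdir / f"{name}_manifest.json").read_text())
    frames = [syn.recode_outcomes(pd.read_csv(outdir / f"{name}_{i:02d}.csv"))
              for i in range(manifest["m"])]
    return ImputationSet(completed=frames, m=manifest["m"],
                         iterations=manifest["iterations"],
                         seed=manifest["seed"],
                         variables_imputed=manifest["variables_imputed"])


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("-B", "--bootstrap", type=int, default=200)
    args = ap.parse_args()

    learn_set = load_imputations("learning")
    # bootstrap scoring runs on the first two imputations (ranking is very
    # stable across completed datasets); pooling later uses all of them
    score_set = ImputationSet(completed=learn_set.completed[:2], m=2,
                              iterations=learn_set.iterations,
                              seed=learn_set.seed,
                              variables_imputed=learn_set.variables_imputed)
    for outcome, rule in (("mtss3", "pdi"), ("qa", "brier")):
        space = default_space(outcome)
        candidates = enumerate_candidates(space)
        if outcome == "qa":
            full = ModelSpec(outcome="qa", terms=candidates[-1].terms,
                             interactions=list(space.interaction_pool))
            pre = backward_eliminate(learn_set, full)
            if pre.to_json() not in {c.to_json() for c in candidates}:
                candidates.append(pre)
            print(f"[qa] BE+BIC prefilter kept interactions: {pre.interactions}")
        sel = bootstrap_select(score_set, candidates, B=args.bootstrap,
                               rule=rule, seed=args.seed + 23)
        sel = confirm_interaction(sel, learn_set)
        winner = sel.winner
        if sel.lr_confirmation and not sel.lr_confirmation["retained"]:
            winner = winner.drop_interactions()
        (RESULTS / f"winner_{outcome}.json").write_text(winner.to_json())
        scores = pd.DataFrame(sel.scores,
                              columns=[f"cand_{i}" for i in
                                       range(len(sel.candidates))])
        scores.insert(0, "replicate", np.arange(len(scores)))
        scores.to_csv(RESULTS / f"bootstrap_scores_{outcome}.csv", index=False)
        print(f"[{outcome}] winner interactions: {winner.interactions}, "
              f"rule={rule}, mean score={sel.mean_scores[sel.winner_index]:.5f}, "
              f"LR confirmation: {sel.lr_confirmation}")


if __name__ == "__main__":
    main()
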