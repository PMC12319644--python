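"""Split the survey into learning/validation data and multiply impute each.

The 70/30 split precedes imputation, and the two halves are imputed in
fully separate runs (m=10 learning, m=20 validation) so that no information
leaks from validation into the learning-stage models.  Completed datasets
and a manifest go under results/imputed/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from relint import synthetic as syn
from relint.impute import chained_imputation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--m-learn", type=int, default=10)
    ap.add_argument("--m-valid", type=int, default=20)
    ap.add_argument("--iterations", type=int, default=10)
    args = ap.parse_args()

    src = RESULTS / "survey_synthetic.csv"
    if not src.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    table = syn.recode_outcomes(pd.read_csv(src))
    learn, valid = syn.split_learning_validation(table, 0.7, seed=args.seed + 1)
    outdir = RESULTS / "imputed"
    outdir.mkdir(parents=True, exist_ok=True)

    for name, frame, m, s in (("learning", learn, args.m_learn, args.seed + 11),
                              ("validation", valid, args.m_valid, args.seed + 17)):
        iset = chained_imputation(frame, m=m, iterations=args.iterations, seed=s)
        for i, c in enumerate(iset.completed):
            c.to_csv(outdir / f"{name}_{i:02d}.csv", index=False)
        (outdir / f"{name}_manifest.json").write_text(json.dumps({
            "m": iset.m, "iterations": iset.iterations, "seed": iset.seed,
            "n": len(frame), "variables_imputed": iset.variables_imputed},
            indent=2))
        print(f"{name}: n={len(frame)}, m={iset.m}, "
              f"imputed {iset.variables_imputed}")


if __name__ == "__main__":
    main()
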