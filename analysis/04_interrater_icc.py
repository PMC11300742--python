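#!/usr/bin/env python
"""Inter-rater reliability of the semi-quantitative score on phantoms.

Takes the per-case scores of the evaluated synthetic cohort, simulates
an independent second rater who moves one point up or down on a fraction
of cases, and computes the single-rater two-way-mixed consistency ICC —
the same reliability summary the scale was validated with. Writes the
rating matrix and ICC to results/interrater/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from segqa.cohort_stats import icc_consistency
from segqa.synthetic import simulate_rater_pair


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--scores", type=Path, default=Path("results/cohort_eval/case_scores.csv")
    )
    parser.add_argument("--seed", type=int, default=2)
    parser.add_argument("--n-review", type=int, default=30,
                        help="number of randomly selected cases re-rated")
    parser.add_argument("--out-dir", type=Path, default=Path("results/interrater"))
    args = parser.parse_args()

    scores = pd.read_csv(args.scores)
    rng = np.random.default_rng(args.seed)
    pick = rng.choice(len(scores), size=min(args.n_review, len(scores)), replace=False)
    subset = scores.iloc[sorted(pick)]
    ratings = simulate_rater_pair(subset["score"].to_numpy(), seed=args.seed)
    icc = icc_consistency(ratings)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"case_id": subset["case_id"], "rater1": ratings[:, 0], "rater2": ratings[:, 1]}
    ).to_csv(args.out_dir / "rating_matrix.csv", index=False)
    with open(args.out_dir / "icc.json", "w") as fh:
        json.dump({"icc_consistency": icc, "n_cases": len(ratings)}, fh, indent=2)
    print(f"consistency ICC(3,1) on {len(ratings)} re-rated cases: {icc:.3f}")


if __name__ == "__main__":
    main()
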