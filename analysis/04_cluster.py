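"""Majority-vote k-means stratification of the 25-feature matrix.

Reads results/features.csv (run scripts 01-02 first); writes
results/labels.csv, results/votes.json and results/criteria.csv and
prints the vote tally and deviance-ordered cluster sizes.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hippoclust.clustering import (
    cluster_metabolic_only,
    order_by_deviance,
    select_k_majority,
    standardize,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument(
        "--mode", choices=["full", "metabolic-only"], default="full",
        help="cluster on all 25 features or the 7 metabolic measures only",
    )
    args = parser.parse_args()

    features = pd.read_csv(args.out_dir / "features.csv", index_col=0)
    if args.mode == "metabolic-only":
        solution = cluster_metabolic_only(features, seed=args.seed)
    else:
        fm = standardize(features)
        solution = order_by_deviance(
            select_k_majority(fm.frame, seed=args.seed), features
        )

    pd.DataFrame(
        {"subject_id": solution.subject_ids, "cluster": solution.labels}
    ).to_csv(args.out_dir / "labels.csv", index=False)
    (args.out_dir / "votes.json").write_text(
        json.dumps({"votes": solution.votes, "tally": solution.tally,
                    "chosen_k": solution.chosen_k}, indent=2)
    )
    solution.criteria.to_csv(args.out_dir / "criteria.csv")

    print(f"mode: {args.mode}")
    print(f"vote tally: {solution.tally}  ->  chosen k = {solution.chosen_k}")
    for c in sorted(set(solution.labels)):
        sel = solution.labels == c
        print(
            f"cluster {c}: n = {sel.sum():3d}; "
            f"SSPG {features.loc[sel, 'SSPG'].mean():.1f} mg/dL, "
            f"leptin {features.loc[sel, 'leptin'].mean():.1f} ug/L"
        )
    print(f"wrote {args.out_dir / 'labels.csv'}, votes.json, criteria.csv")


if __name__ == "__main__":
    main()
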