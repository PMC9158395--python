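"""Compare the recovered clusters on metabolic, demographic, cognitive,
connectivity and head-motion variables.

Reads results/cohort.csv, results/features.csv and results/labels.csv
(run scripts 01-04 first); writes results/comparison.csv and prints the
significant rows.
"""

import argparse
from pathlib import Path

import pandas as pd

from hippoclust.comparison import compare_clusters
from hippoclust.connectivity import CONNECTIVITY_FEATURES


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = pd.read_csv(args.out_dir / "cohort.csv")
    features = pd.read_csv(args.out_dir / "features.csv", index_col=0)
    labels = pd.read_csv(args.out_dir / "labels.csv")
    complete = cohort[cohort.has_imaging & cohort.has_ist].reset_index(drop=True)

    report = compare_clusters(
        complete,
        labels["cluster"].to_numpy(),
        connectivity=features[list(CONNECTIVITY_FEATURES)],
    )
    report.to_csv(args.out_dir / "comparison.csv", index=False)

    sig = report[report.significant]
    print(f"{len(sig)} of {len(report)} variables differ at p < 0.05:")
    cols = ["variable", "cluster1", "cluster2", "test", "p"]
    print(sig[cols].to_string(index=False))
    print(f"wrote {args.out_dir / 'comparison.csv'}")


if __name__ == "__main__":
    main()
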