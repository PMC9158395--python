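"""Age/sex-adjusted Spearman association matrix over the 25 measures.

Reads results/cohort.csv and results/features.csv (run scripts 01-02
first); writes results/association_rho.csv and results/association_p.csv
and prints the metabolic block with significance markers.
"""

import argparse
from pathlib import Path

import pandas as pd

from hippoclust.association import association_matrix
from hippoclust.clustering import METABOLIC_FEATURES


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = pd.read_csv(args.out_dir / "cohort.csv")
    features = pd.read_csv(args.out_dir / "features.csv", index_col=0)
    complete = cohort[cohort.has_imaging & cohort.has_ist].set_index("subject_id")
    table = pd.concat(
        [complete[["age", "sex"]], features.loc[complete.index]], axis=1
    )

    am = association_matrix(table, adjust=True)
    am.rho.to_csv(args.out_dir / "association_rho.csv")
    am.p.to_csv(args.out_dir / "association_p.csv")

    block = list(METABOLIC_FEATURES)
    print("age/sex-adjusted Spearman rho, metabolic block:")
    print(am.rho.loc[block, block].round(2).to_string())
    sig = am.significant().loc[block, block].sum().sum() // 2
    print(f"significant metabolic pairs at p < 0.05: {sig} of 21")
    print(f"wrote {args.out_dir / 'association_rho.csv'} and association_p.csv")


if __name__ == "__main__":
    main()
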