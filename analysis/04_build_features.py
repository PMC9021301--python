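"""Assemble the regression design: 91 network-connectivity cells (upper
triangle of each driver's 13x13 matrix, diagonal included) plus age.

Writes the drivers-by-features table to scratch/features.csv and a
small shape/provenance note to results/features_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from wayfind.pipeline import load_connectivity_dir
from wayfind.rsfc import build_feature_table

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    conn = load_connectivity_dir(STUDY / "connectivity")
    cov = pd.read_csv(STUDY / "covariates.csv", index_col="driver_id")
    table = build_feature_table(conn, cov["age"])
    table.to_csv(ROOT / "scratch" / "features.csv")
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "features_summary.json", "w") as fh:
        json.dump(
            {
                "n_drivers": int(table.shape[0]),
                "n_features": int(table.shape[1]),
                "first_features": list(table.columns[:5]),
                "last_feature": table.columns[-1],
            },
            fh, indent=1,
        )
    print(f"feature table: {table.shape[0]} drivers x {table.shape[1]} features")


if __name__ == "__main__":
    main()
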