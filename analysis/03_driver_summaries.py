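"""Compress each driver's trip history into the one-row-per-driver
summary panel (medians of the route metrics, means of the event rates,
radius of gyration, destination uniqueness).

Writes results/driver_summaries.csv and a cohort table
(results/cohort_table.csv) with mean/SD/median/min/max per measure —
the format a study demographics table uses.
"""

from pathlib import Path

import pandas as pd

from wayfind.pipeline import driver_summary_table, load_breadcrumbs, trip_metrics_table
from wayfind.roads import load_network_csv

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    net = load_network_csv(STUDY / "network.csv")
    trips = load_breadcrumbs(STUDY / "breadcrumbs.csv")
    cov = pd.read_csv(STUDY / "covariates.csv", index_col="driver_id")
    _, per_driver = trip_metrics_table(trips, net)
    summaries = driver_summary_table(trips, per_driver, cov["enrollment_years"])
    summaries = summaries.join(cov["age"])
    RESULTS.mkdir(exist_ok=True)
    summaries.to_csv(RESULTS / "driver_summaries.csv")
    cohort = summaries.agg(["mean", "std", "median", "min", "max"]).T.round(4)
    cohort.to_csv(RESULTS / "cohort_table.csv")
    print(f"{len(summaries)} drivers summarized")
    print(cohort)


if __name__ == "__main__":
    main()
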