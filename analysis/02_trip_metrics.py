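"""Compute the per-trip metric panel for every trip in the study.

Reads scratch/study/, computes route straightness, the actual-optimal
distance and time ratios, and the driving-event counts for all 12,800
trips, and writes the long table to scratch/trip_metrics.csv with a
cohort-level distribution summary in results/trip_metrics_summary.csv.
"""

from pathlib import Path

from wayfind.pipeline import load_breadcrumbs, trip_metrics_table
from wayfind.roads import load_network_csv

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

METRICS = [
    "distance_mi", "straightness", "actual_optimal_distance_ratio",
    "actual_optimal_time_ratio", "hard_brake_count", "hard_accel_count",
    "overspeed_event_count", "overspeed_time_fraction",
]


def main() -> None:
    net = load_network_csv(STUDY / "network.csv")
    trips = load_breadcrumbs(STUDY / "breadcrumbs.csv")
    table, _ = trip_metrics_table(trips, net)
    table.to_csv(ROOT / "scratch" / "trip_metrics.csv", index=False)
    summary = table[METRICS].describe().T.round(4)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "trip_metrics_summary.csv")
    print(f"{len(table)} trips from {table['driver_id'].nunique()} drivers")
    print(summary[["mean", "50%", "min", "max"]])


if __name__ == "__main__":
    main()
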