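"""Descriptive cohort summary of the detection results.

Aggregates the per-synapse reports from 02 into group-level medians, means,
standard errors and empirical CDFs (no hypothesis testing; the tidy tables
are the export surface for external statistics tools).
"""

from pathlib import Path

import pandas as pd

from calyxnano.pipeline import empirical_cdfs, summarize_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = ROOT / "cluster_reports.csv"
    if not path.exists():
        raise SystemExit("run analysis/02_detect_nanoclusters.py first")
    reports = pd.read_csv(path)
    summary = summarize_cohort(reports)
    summary.to_csv(ROOT / "cohort_summary.csv", index=False)
    empirical_cdfs(reports).to_csv(ROOT / "cohort_cdfs.csv", index=False)
    show = summary[summary.metric.isin(["n_nanoclusters", "volume_nm3", "nc_mean_volume_nm3", "fraction_locs_in_nc"])]
    print(show.round(3).to_string(index=False))
    print(f"\nwrote {ROOT/'cohort_summary.csv'} and cohort_cdfs.csv")


if __name__ == "__main__":
    main()
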