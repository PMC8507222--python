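#!/usr/bin/env python
"""Organoid-level summaries, z-scores, and healthy-vs-disease statistics.

Averages every channel metric over the active channels of each organoid,
assembles the cohort table, standardises it, and compares the disease group
against the healthy reference by rank-based tests with Holm correction.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from organoid_mea import summary as sm

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

KEY_METRICS = ["spike_rate", "burst_rate", "isi_cv", "pct_connected",
               "weight", "relpow_delta", "relpow_low_gamma", "lfp_peak_amp",
               "mi_delta_upper_gamma", "mi_theta_upper_gamma"]


def main() -> None:
    spikes = pd.read_csv(RESULTS / "spike_metrics.csv")
    netw = pd.read_csv(RESULTS / "network_metrics.csv")
    oscp = pd.read_csv(RESULTS / "oscillation_metrics.csv")
    pacm = pd.read_csv(RESULTS / "pac_metrics.csv")

    summaries = []
    for rid, sub in spikes.groupby("recording_id"):
        active = set(sub.loc[sub["active"], "channel_id"])
        tidy = []
        for frame, cols in (
                (sub, ["spike_rate", "burst_rate", "isi_cv"]),
                (oscp[oscp.recording_id == rid],
                 [c for c in oscp.columns
                  if c.startswith("relpow_") or c == "lfp_peak_amp"])):
            for _, r in frame.iterrows():
                for c in cols:
                    tidy.append({"channel_id": r["channel_id"],
                                 "metric_name": c, "value": r[c]})
        for _, r in pacm[pacm.recording_id == rid].iterrows():
            tidy.append({"channel_id": r["channel_id"],
                         "metric_name": r["metric_name"],
                         "value": r["value"]})
        nrow = netw[netw.recording_id == rid].iloc[0]
        for c in ("pct_connected", "weight", "period_autocorrelation_s"):
            if np.isfinite(nrow.get(c, np.nan)):
                tidy.append({"channel_id": "ALL", "metric_name": c,
                             "value": nrow[c]})
        s = sm.summarize(pd.DataFrame(tidy), active, rid,
                         group=rid[:-2])
        summaries.append(s)

    table = sm.cohort_table(summaries)
    table.to_csv(RESULTS / "organoid_summary.csv", index=False)
    z = sm.zscore_matrix(table)
    z.to_csv(RESULTS / "organoid_zscores.csv", index=False)

    tests = []
    for metric in KEY_METRICS:
        if metric in table.columns and table[metric].notna().all():
            tests.append(sm.group_compare(table, metric, "healthy"))
    tests_df = pd.concat(tests, ignore_index=True)
    tests_df.to_csv(RESULTS / "group_tests.csv", index=False)

    means = table.groupby("group")[
        [m for m in KEY_METRICS if m in table.columns]].mean()
    print("group means:")
    print(means.round(4).T)
    print("\nrank tests vs healthy (Holm-adjusted):")
    print(tests_df[["metric", "group", "p_adj", "reject"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
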