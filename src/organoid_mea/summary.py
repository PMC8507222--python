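"""Organoid-level aggregation, cohort tables, and group comparisons.

Each per-channel metric is averaged over the active channels to represent
the organoid.  Cohorts are compared per metric by a Kruskal-Wallis omnibus
plus reference-vs-group Mann-Whitney tests with Holm correction — a
rank-based many-to-one scheme standing in for figure-style "ANOVA on ranks
with Dunnett's correction", which has no exact nonparametric analogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrganoidSummary",
    "summarize",
    "cohort_table",
    "zscore_matrix",
    "group_compare",
]


@dataclass
class OrganoidSummary:
    recording_id: str
    group: str
    values: dict[str, float] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)
    n_active_channels: int = 0


def summarize(
    metrics: pd.DataFrame,
    active_ids: set[str] | list[str],
    recording_id: str,
    group: str = "",
    expected_metrics: list[str] | None = None,
) -> OrganoidSummary:
    """Mean over active channels per metric; network-level rows pass through.

    ``metrics`` is tidy (channel_id, metric_name, value); rows with
    channel_id == "ALL" are recording-level and are taken as-is.  Metrics in
    ``expected_metrics`` that produce no value are flagged missing, never
    silently zero.
    """
    active = set(active_ids)
    values: dict[str, float] = {}
    for name, sub in metrics.groupby("metric_name"):
        rec_level = sub[sub["channel_id"] == "ALL"]
        if len(rec_level):
            v = rec_level["value"].iloc[0]
            if np.isfinite(v):
                values[name] = float(v)
            continue
        chan = sub[sub["channel_id"].isin(active)]
        vals = chan["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            values[name] = float(vals.mean())
    missing = [m for m in (expected_metrics or []) if m not in values]
    return OrganoidSummary(recording_id, group, values, missing,
                           n_active_channels=len(active))


def cohort_table(summaries: list[OrganoidSummary]) -> pd.DataFrame:
    """Wide table: one row per organoid, one column per metric."""
    rows = []
    for s in summaries:
        row = {"recording_id": s.recording_id, "group": s.group}
        row.update(s.values)
        rows.append(row)
    return pd.DataFrame(rows)


def zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metric z-scores across organoids (sample SD, ddof=1).

    Input is the wide cohort table; metric columns are standardised, zero-
    variance metrics yield a flagged all-zero row (column here).
    """
    meta = [c for c in ("recording_id", "group") if c in table.columns]
    metrics = [c for c in table.columns if c not in meta]
    if len(table) < 2:
        raise ValueError("need at least 2 organoids")
    out = table[meta].copy()
    flagged = []
    for m in metrics:
        x = table[m].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            out[m] = 0.0
            flagged.append(m)
        else:
            out[m] = (x - np.nanmean(x)) / sd
    out.attrs["zero_variance_metrics"] = flagged
    return out


def group_compare(
    table: pd.DataFrame,
    metric: str,
    reference_group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based many-to-one comparisons against a reference group.

    Kruskal-Wallis across all groups, then two-sided Mann-Whitney U of the
    reference versus each other group, Holm-adjusted.  Returns one row per
    comparison with the omnibus statistics repeated; empty frame when there
    is nothing to compare.
    """
    groups = {g: sub[metric].dropna().to_numpy(dtype=float)
              for g, sub in table.groupby("group")}
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    others = [g for g in groups if g != reference_group]
    if not others:
        return pd.DataFrame(
            columns=["metric", "group", "reference", "u_stat", "p_raw",
                     "p_adj", "reject", "kw_stat", "kw_p"])
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")
    kw_stat, kw_p = stats.kruskal(*groups.values())
    rows = []
    pvals = []
    for g in others:
        u, p = stats.mannwhitneyu(groups[reference_group], groups[g],
                                  alternative="two-sided")
        rows.append({"metric": metric, "group": g,
                     "reference": reference_group,
                     "u_stat": float(u), "p_raw": float(p)})
        pvals.append(p)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    for row, pa, rj in zip(rows, p_adj, reject):
        row["p_adj"] = float(pa)
        row["reject"] = bool(rj)
        row["kw_stat"] = float(kw_stat)
        row["kw_p"] = float(kw_p)
    return pd.DataFrame(rows)
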