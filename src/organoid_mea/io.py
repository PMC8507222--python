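"""Containers and file formats for MEA recordings and derived tables.

A recording lives in an HDF5 container: dataset ``data`` (channels x samples),
attributes ``fs_hz``, ``channel_ids``, ``t0_s``.  Derived objects (spike
tables, burst tables, connectivity edge lists, tidy metric tables) are plain
CSV so they stay diffable and text-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_spike_table",
    "write_spike_table",
    "read_burst_table",
    "write_burst_table",
    "read_graph",
    "write_graph",
    "read_metrics",
    "write_metrics",
    "METRIC_VOCABULARY",
    "validate_metric_name",
]

# Registered metric vocabulary.  relpow_<band> and mi_<phase>_<amp> are
# pattern-matched against the canonical band names.
_BAND_NAMES = ("delta", "theta", "alpha", "beta", "low_gamma", "upper_gamma")
METRIC_VOCABULARY = frozenset(
    {
        "spike_rate",
        "burst_rate",
        "isi_cv",
        "pct_connected",
        "weight",
        "period_s",
        "lfp_peak_amp",
    }
    | {f"relpow_{b}" for b in _BAND_NAMES}
    | {
        f"mi_{p}_{a}"
        for p in _BAND_NAMES
        for a in _BAND_NAMES
        if p != a
    }
)

_FLOAT_FMT = "%.12g"  # round trips comfortably beyond 9 significant digits


def validate_metric_name(name: str) -> None:
    if name not in METRIC_VOCABULARY:
        raise ValueError(f"unregistered metric name: {name!r}")


@dataclass
class Recording:
    """Multichannel extracellular voltage trace.

    data : (n_channels, n_samples) array, volts
    fs_hz : sampling rate, samples/second
    channel_ids : unique labels, one per row
    t0_s : recording start offset in seconds
    """

    data: np.ndarray
    fs_hz: float
    channel_ids: list[str] = field(default_factory=list)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError(
                f"channel_ids length {len(self.channel_ids)} does not match "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        """Sample times in seconds (t0-referenced)."""
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, data: np.ndarray, fs_hz: float | None = None,
                  t0_s: float | None = None) -> "Recording":
        return Recording(
            data=data,
            fs_hz=self.fs_hz if fs_hz is None else fs_hz,
            channel_ids=list(self.channel_ids),
            t0_s=self.t0_s if t0_s is None else t0_s,
        )


def write_recording(rec: Recording, path) -> None:
    """Write a recording to the HDF5 container (chunked along samples)."""
    chunk_cols = int(min(rec.n_samples, 65536)) or 1
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "data",
            data=rec.data,
            chunks=(rec.n_channels, chunk_cols),
        )
        f.attrs["fs_hz"] = float(rec.fs_hz)
        f.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
        f.attrs["t0_s"] = float(rec.t0_s)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: missing dataset 'data'")
        for attr in ("fs_hz", "channel_ids", "t0_s"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        data = f["data"][...]
        fs_hz = float(f.attrs["fs_hz"])
        channel_ids = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["channel_ids"]
        ]
        t0_s = float(f.attrs["t0_s"])
    return Recording(data=data, fs_hz=fs_hz, channel_ids=channel_ids, t0_s=t0_s)


def _stable_sort(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return df.sort_values(by, kind="mergesort").reset_index(drop=True)


def write_spike_table(spikes: pd.DataFrame, path) -> None:
    """Write rows of (channel_id, spike_time_s), sorted by channel then time."""
    df = spikes.loc[:, ["channel_id", "spike_time_s"]].copy()
    df = _stable_sort(df, ["channel_id", "spike_time_s"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spike_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"channel_id": str})
    if list(df.columns) != ["channel_id", "spike_time_s"]:
        raise ValueError(f"{path}: expected columns channel_id,spike_time_s")
    return df


def write_burst_table(bursts: pd.DataFrame, path) -> None:
    """Rows of (channel_id, start_s, end_s, n_spikes)."""
    df = bursts.loc[:, ["channel_id", "start_s", "end_s", "n_spikes"]].copy()
    df = _stable_sort(df, ["channel_id", "start_s"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_burst_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"channel_id": str})


def _check_unique_pairs(df: pd.DataFrame) -> None:
    pairs = [tuple(sorted((a, b))) for a, b in zip(df["channel_a"], df["channel_b"])]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicate unordered channel pair(s) in graph: {dupes}")


def write_graph(edges: pd.DataFrame, path) -> None:
    """Edge list (channel_a, channel_b, weight); one row per unordered pair."""
    df = edges.loc[:, ["channel_a", "channel_b", "weight"]].copy()
    # canonical orientation: channel_a <= channel_b lexicographically
    flip = df["channel_a"] > df["channel_b"]
    df.loc[flip, ["channel_a", "channel_b"]] = df.loc[
        flip, ["channel_b", "channel_a"]
    ].to_numpy()
    _check_unique_pairs(df)
    df = _stable_sort(df, ["channel_a", "channel_b"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_graph(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"channel_a": str, "channel_b": str})
    _check_unique_pairs(df)
    return df


def write_metrics(metrics: pd.DataFrame, path, validate: bool = True) -> None:
    """Tidy metric table: (recording_id, channel_id, metric_name, value)."""
    cols = ["recording_id", "channel_id", "metric_name", "value"]
    df = metrics.loc[:, cols].copy()
    if validate:
        for name in df["metric_name"].unique():
            validate_metric_name(name)
    df = _stable_sort(df, ["recording_id", "channel_id", "metric_name"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"recording_id": str, "channel_id": str})
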