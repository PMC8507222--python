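"""Spike detection, activity filtering, burst detection, firing statistics.

Detection operates on the spike-band-filtered trace: each channel's baseline
mean and SD come from the first 30 s, and events are local extrema whose
absolute deviation from the baseline mean exceeds 4 SD (both polarities
trigger; extracellular spikes are predominantly negative but the rule is
symmetric).  Channels at or below 12 spikes per minute are inactive.  A
burst is any run of spikes where some 100 ms window holds at least 4 of
them; overlapping qualifying windows merge into one burst spanning first to
last member spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "SpikeTrain",
    "BurstSet",
    "ChannelStats",
    "detect_spikes",
    "classify_active",
    "detect_bursts",
    "channel_stats",
]

INACTIVE_MAX_SPIKES_PER_MIN = 12  # "<= 12 spikes per minute" is inactive


@dataclass
class SpikeTrain:
    channel_id: str
    times_s: np.ndarray
    threshold_v: float
    baseline_sd_v: float
    baseline_mean_v: float
    degenerate_baseline: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times_s.size


@dataclass
class BurstSet:
    channel_id: str
    intervals: list[tuple[float, float]] = field(default_factory=list)
    spike_counts: list[int] = field(default_factory=list)

    @property
    def n_bursts(self) -> int:
        return len(self.intervals)


@dataclass
class ChannelStats:
    channel_id: str
    spike_rate_hz: float
    burst_rate_per_min: float
    isi_cv: float          # NaN when undefined (< 3 spikes)
    active: bool
    isi_cv_defined: bool = True


def detect_spikes(
    rec: Recording,
    sd_multiplier: float = 4.0,
    baseline_window_s: float = 30.0,
    refractory_ms: float = 1.0,
) -> list[SpikeTrain]:
    """Threshold-crossing events on a spike-band-filtered recording.

    Per channel: baseline mean/SD over the first ``baseline_window_s``;
    events are local maxima of |x - mean| exceeding ``sd_multiplier`` * SD,
    separated by at least ``refractory_ms``.  A constant (zero-SD) channel
    yields an empty train flagged ``degenerate_baseline``.
    """
    nb = int(round(min(baseline_window_s, rec.duration_s) * rec.fs_hz))
    nb = max(nb, 2)
    dist = max(1, int(round(refractory_ms / 1000.0 * rec.fs_hz)))
    trains = []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        m = float(np.mean(x[:nb]))
        sd = float(np.std(x[:nb]))
        if sd == 0.0:
            trains.append(
                SpikeTrain(rec.channel_ids[ch], np.empty(0), threshold_v=m,
                           baseline_sd_v=0.0, baseline_mean_v=m,
                           degenerate_baseline=True)
            )
            continue
        dev = np.abs(x - m)
        thr = sd_multiplier * sd
        peaks, _ = signal.find_peaks(dev, height=thr, distance=dist)
        times = rec.t0_s + peaks / rec.fs_hz
        trains.append(
            SpikeTrain(rec.channel_ids[ch], times, threshold_v=m + thr,
                       baseline_sd_v=sd, baseline_mean_v=m)
        )
    return trains


def classify_active(train: SpikeTrain, duration_s: float) -> bool:
    """Active iff strictly more than 12 spikes per minute."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    per_min = train.n_spikes / duration_s * 60.0
    return per_min > INACTIVE_MAX_SPIKES_PER_MIN


def detect_bursts(train: SpikeTrain, min_spikes: int = 4,
                  window_ms: float = 100.0) -> BurstSet:
    """Bursts: >= ``min_spikes`` spikes within any ``window_ms`` window.

    Every window starting at a spike is examined (a qualifying window can
    always be slid left onto a spike without losing members); overlapping
    qualifying windows are merged, and each burst's interval spans its first
    to last member spike.
    """
    t = train.times_s
    w = window_ms / 1000.0
    qual: list[tuple[float, float]] = []
    j = 0
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + w, side="right"))
        if j - i >= min_spikes:
            qual.append((t[i], t[i] + w))
    merged: list[list[float]] = []
    for s, e in qual:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    intervals = []
    counts = []
    for s, e in merged:
        lo = int(np.searchsorted(t, s, side="left"))
        hi = int(np.searchsorted(t, e, side="right"))
        member = t[lo:hi]
        intervals.append((float(member[0]), float(member[-1])))
        counts.append(int(member.size))
    return BurstSet(train.channel_id, intervals, counts)


def channel_stats(train: SpikeTrain, bursts: BurstSet,
                  duration_s: float) -> ChannelStats:
    """Per-channel firing statistics: rate, burst rate, ISI CV, activity."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rate = train.n_spikes / duration_s
    brate = bursts.n_bursts / duration_s * 60.0
    if train.n_spikes >= 3:
        isis = np.diff(train.times_s)
        mu = isis.mean()
        cv = float(isis.std(ddof=1) / mu) if mu > 0 else np.nan
        defined = np.isfinite(cv)
    else:
        cv, defined = np.nan, False
    return ChannelStats(
        channel_id=train.channel_id,
        spike_rate_hz=float(rate),
        burst_rate_per_min=float(brate),
        isi_cv=cv,
        active=classify_active(train, duration_s),
        isi_cv_defined=defined,
    )
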