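"""Network communication: connectivity graphs and network-event periodicity.

Connectivity follows the spike-correlation convention: Pearson correlation
of 50 ms binned spike counts within a randomly selected one-minute window;
two channels are connected when r exceeds 0.5 strictly.  Periodicity of the
network spiking percentage is assessed by normalized autocorrelation and by
Welch's periodogram; a candidate peak is reported only when it exceeds the
mean + 1 SD of the statistic over the search band (0.5-30 s lags,
0.033-2 Hz).  That detection rule is kept as stated even though it is an
intentionally liberal criterion (see the methods note on its specificity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal

from .io import Recording
from .spikes import BurstSet, SpikeTrain

__all__ = [
    "ConnectivityGraph",
    "PeriodicityResult",
    "select_analysis_window",
    "slice_train",
    "spike_correlation_matrix",
    "connectivity_graph",
    "overlapping_burst_connectivity",
    "network_spiking_percentage",
    "periodicity",
]


@dataclass
class ConnectivityGraph:
    graph: nx.Graph                 # nodes: channel ids; edge attr: weight
    threshold: float
    basis: str                      # spike_correlation | overlapping_bursts | band_power
    percent_connected: float = 0.0  # % of nodes having >= 1 edge
    mean_weight: float = float("nan")

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]


@dataclass
class PeriodicityResult:
    method: str                       # autocorrelation | welch
    period_s: float | None
    peak_value: float
    detection_threshold: float
    degenerate: bool = False          # constant / zero-variance series


def select_analysis_window(rec: Recording, window_s: float = 60.0,
                           seed: int | np.random.Generator = 0) -> Recording:
    """Contiguous ``window_s`` slice with a uniformly random start."""
    if rec.duration_s < window_s - 1e-9:
        raise ValueError(
            f"recording ({rec.duration_s:.1f} s) shorter than window {window_s} s"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    max_start = rec.duration_s - window_s
    start = float(rng.uniform(0.0, max_start)) if max_start > 0 else 0.0
    i0 = int(round(start * rec.fs_hz))
    i1 = i0 + int(round(window_s * rec.fs_hz))
    return rec.copy_with(rec.data[:, i0:i1].copy(), t0_s=rec.t0_s + i0 / rec.fs_hz)


def slice_train(train: SpikeTrain, t_start: float, t_stop: float) -> SpikeTrain:
    """Restrict a spike train to [t_start, t_stop)."""
    m = (train.times_s >= t_start) & (train.times_s < t_stop)
    return SpikeTrain(train.channel_id, train.times_s[m], train.threshold_v,
                      train.baseline_sd_v, train.baseline_mean_v,
                      train.degenerate_baseline)


def spike_correlation_matrix(
    trains: list[SpikeTrain],
    t_start: float,
    t_stop: float,
    bin_ms: float = 50.0,
) -> tuple[np.ndarray, list[str]]:
    """Pearson correlation of binned spike counts.

    Returns (matrix, channel_ids); zero-variance channels yield NaN rows and
    columns (excluded from any downstream edge).
    """
    ids = [tr.channel_id for tr in trains]
    nbins = int(np.ceil((t_stop - t_start) / (bin_ms / 1000.0)))
    if nbins < 2 or len(trains) < 2:
        return np.full((len(trains), len(trains)), np.nan), ids
    edges = t_start + np.arange(nbins + 1) * (bin_ms / 1000.0)
    counts = np.vstack([
        np.histogram(tr.times_s, bins=edges)[0] for tr in trains
    ]).astype(float)
    sd = counts.std(axis=1)
    mat = np.full((len(trains), len(trains)), np.nan)
    good = sd > 0
    if good.sum() >= 2:
        sub = np.corrcoef(counts[good])
        mat[np.ix_(good, good)] = sub
    mat[np.arange(len(trains)), np.arange(len(trains))] = np.where(good, 1.0, np.nan)
    return mat, ids


def connectivity_graph(corr: np.ndarray, channel_ids: list[str],
                       threshold: float = 0.5,
                       basis: str = "spike_correlation") -> ConnectivityGraph:
    """Edges where correlation strictly exceeds ``threshold``.

    percent_connected is the percentage of supplied channels that have at
    least one edge; mean_weight averages the included edge coefficients.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1] or corr.shape[0] != len(channel_ids):
        raise ValueError("correlation matrix / channel id shape mismatch")
    finite = np.isfinite(corr)
    if not np.allclose(corr[finite & finite.T & ~np.eye(len(channel_ids), dtype=bool)],
                       corr.T[finite & finite.T & ~np.eye(len(channel_ids), dtype=bool)],
                       atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(channel_ids)
    n = len(channel_ids)
    weights = []
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isfinite(r) and r > threshold:
                g.add_edge(channel_ids[i], channel_ids[j], weight=float(r))
                weights.append(float(r))
    connected = sum(1 for node in g.nodes if g.degree(node) > 0)
    pct = 100.0 * connected / n if n else 0.0
    return ConnectivityGraph(
        graph=g, threshold=threshold, basis=basis,
        percent_connected=pct,
        mean_weight=float(np.mean(weights)) if weights else float("nan"),
    )


def _burst_overlap_fraction(a: list[tuple[float, float]],
                            b: list[tuple[float, float]]) -> float:
    """Fraction of intervals in ``a`` intersecting any interval in ``b``."""
    if not a:
        return 0.0
    hits = 0
    for s, e in a:
        if any(s <= e2 and s2 <= e for s2, e2 in b):
            hits += 1
    return hits / len(a)


def overlapping_burst_connectivity(
    bursts: list[BurstSet], min_overlap_fraction: float = 0.25
) -> ConnectivityGraph:
    """Channels connected when either one's burst-overlap fraction exceeds
    ``min_overlap_fraction``; edge weight is the larger fraction."""
    ids = [b.channel_id for b in bursts]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(bursts)):
        for j in range(i + 1, len(bursts)):
            fa = _burst_overlap_fraction(bursts[i].intervals, bursts[j].intervals)
            fb = _burst_overlap_fraction(bursts[j].intervals, bursts[i].intervals)
            w = max(fa, fb)
            if w > min_overlap_fraction:
                g.add_edge(ids[i], ids[j], weight=float(w))
    connected = sum(1 for node in g.nodes if g.degree(node) > 0)
    pct = 100.0 * connected / len(ids) if ids else 0.0
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    return ConnectivityGraph(
        graph=g, threshold=min_overlap_fraction, basis="overlapping_bursts",
        percent_connected=pct,
        mean_weight=float(np.mean(weights)) if weights else float("nan"),
    )


def network_spiking_percentage(
    trains: list[SpikeTrain],
    t_start: float,
    t_stop: float,
    bin_ms: float = 100.0,
) -> tuple[np.ndarray, float]:
    """Fraction of supplied channels firing in each bin; returns (series, fs)."""
    if not trains:
        raise ValueError("need at least one train")
    width = bin_ms / 1000.0
    nbins = int(np.ceil((t_stop - t_start) / width))
    edges = t_start + np.arange(nbins + 1) * width
    hits = np.zeros(nbins)
    for tr in trains:
        c, _ = np.histogram(tr.times_s, bins=edges)
        hits += (c > 0)
    return hits / len(trains), 1.0 / width


def periodicity(
    series: np.ndarray,
    fs_series: float,
    method: str = "autocorrelation",
    min_period_s: float = 0.5,
    max_period_s: float = 30.0,
    z_thresh: float = 1.0,
) -> PeriodicityResult:
    """Dominant period of a network-event series, or None.

    autocorrelation: lag-0-normalized autocorrelation; candidate = highest
    local maximum at lags in [min_period_s, max_period_s].  welch: highest
    spectral peak in the reciprocal frequency band (zero-padded for peak
    localisation).  Either way the peak is reported only when it exceeds
    mean + ``z_thresh`` * SD of the statistic over the search band.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series must have at least 10 bins")
    # constant up to float rounding counts as zero variance
    if np.ptp(x) == 0 or np.std(x) <= 1e-9 * np.abs(x).max():
        return PeriodicityResult(method, None, 0.0, 0.0, degenerate=True)
    if method == "autocorrelation":
        xc = x - x.mean()
        ac = signal.correlate(xc, xc, mode="full")[x.size - 1:]
        ac = ac / ac[0]
        lags = np.arange(x.size) / fs_series
        band = (lags >= min_period_s) & (lags <= max_period_s)
        vals = ac[band]
        if vals.size < 3:
            return PeriodicityResult(method, None, 0.0, 0.0, degenerate=True)
        thr = float(vals.mean() + z_thresh * vals.std())
        peaks, _ = signal.find_peaks(vals)
        if peaks.size == 0:
            return PeriodicityResult(method, None, float(vals.max()), thr)
        best = peaks[np.argmax(vals[peaks])]
        peak_val = float(vals[best])
        period = float(lags[band][best])
    elif method == "welch":
        seg = max(10, x.size // 2)
        f, p = signal.welch(x, fs=fs_series, nperseg=seg, noverlap=seg // 2,
                            nfft=16 * seg, detrend="constant")
        band = (f >= 1.0 / max_period_s) & (f <= 1.0 / min_period_s)
        vals = p[band]
        fb = f[band]
        if vals.size < 3:
            return PeriodicityResult(method, None, 0.0, 0.0, degenerate=True)
        thr = float(vals.mean() + z_thresh * vals.std())
        peaks, _ = signal.find_peaks(vals)
        supra = peaks[vals[peaks] > thr]
        if supra.size == 0:
            top = float(vals[peaks].max()) if peaks.size else float(vals.max())
            return PeriodicityResult(method, None, top, thr)
        # a periodic pulse process puts comparable power at every harmonic,
        # so the fundamental is the LOWEST suprathreshold peak; parabolic
        # interpolation on log power refines the peak frequency
        best = int(supra[0])
        peak_val = float(vals[best])
        f_peak = float(fb[best])
        if 0 < best < vals.size - 1 and np.all(vals[best - 1:best + 2] > 0):
            y0, y1, y2 = np.log(vals[best - 1:best + 2])
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                f_peak += 0.5 * (y0 - y2) / denom * (fb[1] - fb[0])
        period = float(1.0 / f_peak)
    else:
        raise ValueError(f"unknown method {method!r}")
    if peak_val > thr:
        return PeriodicityResult(method, period, peak_val, thr)
    return PeriodicityResult(method, None, peak_val, thr)
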