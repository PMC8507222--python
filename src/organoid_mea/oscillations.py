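"""Narrow-band oscillatory power and band-power connectivity.

The 1000 Hz LFP is decomposed into six canonical bands — delta (0.5-4 Hz),
theta (5-8), alpha (9-13), beta (14-32), low gamma (33-80), upper gamma
(100-200) — by the synchrosqueezed wavelet transform; per-band power is the
Welch estimate (2000 ms windows, 1000 ms overlap) integrated over the band's
edges and normalized across the six bands.  The inter-band gaps are left
unassigned, so the six relative fractions sum to one.

Band-power connectivity correlates per-channel relative-power time courses
computed in consecutive 5 s windows; channels whose Pearson coefficient
exceeds the median + 1 SD of the coefficient distribution are connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording
from .network import ConnectivityGraph, connectivity_graph
from .sst import sst_band_signals

__all__ = [
    "BANDS",
    "BAND_NAMES",
    "BandPowerResult",
    "sst_band_decompose",
    "relative_band_power",
    "band_powers_welch",
    "lfp_peak_amplitude",
    "power_connectivity",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (9.0, 13.0),
    "beta": (14.0, 32.0),
    "low_gamma": (33.0, 80.0),
    "upper_gamma": (100.0, 200.0),
}
BAND_NAMES = tuple(BANDS)

WELCH_WINDOW_MS = 2000.0
WELCH_OVERLAP_MS = 1000.0


@dataclass
class BandPowerResult:
    channel_ids: list[str]
    relative: dict[str, np.ndarray]      # band -> per-channel fraction
    absolute: dict[str, np.ndarray]      # band -> per-channel power (V^2)
    undefined: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def relative_matrix(self) -> np.ndarray:
        """(n_channels, n_bands) array in BAND_NAMES order."""
        return np.column_stack([self.relative[b] for b in BAND_NAMES])


def sst_band_decompose(
    rec: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    voices: int = 32,
) -> dict[str, np.ndarray]:
    """Per-band reconstructed signals, each (n_channels, n_samples)."""
    bands = BANDS if bands is None else bands
    out = {name: np.zeros_like(rec.data, dtype=float) for name in bands}
    for ch in range(rec.n_channels):
        sigs = sst_band_signals(rec.data[ch], rec.fs_hz, bands, voices=voices)
        for name, s in sigs.items():
            out[name][ch] = s
    return out


def _welch_band_power(x: np.ndarray, fs: float, lo: float, hi: float,
                      nperseg: int | None = None) -> float:
    """Welch power integrated over [lo, hi] (V^2)."""
    if nperseg is None:
        nperseg = int(round(WELCH_WINDOW_MS / 1000.0 * fs))
    nperseg = min(nperseg, x.size)
    noverlap = nperseg // 2
    f, p = signal.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap,
                        detrend="constant")
    m = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else 0.0


def relative_band_power(
    band_signals: dict[str, np.ndarray],
    fs_hz: float,
    channel_ids: list[str] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPowerResult:
    """Relative power per band from band-decomposed signals.

    Per band: Welch power of that band's reconstruction integrated over the
    band's edges; fractions normalize over the six bands.  All-zero channels
    are flagged undefined (NaN fractions).
    """
    bands = BANDS if bands is None else bands
    names = list(bands)
    nch = next(iter(band_signals.values())).shape[0]
    ids = channel_ids or [f"ch{i:02d}" for i in range(nch)]
    absolute = {b: np.zeros(nch) for b in names}
    for b in names:
        lo, hi = bands[b]
        for ch in range(nch):
            absolute[b][ch] = _welch_band_power(band_signals[b][ch], fs_hz, lo, hi)
    total = np.sum([absolute[b] for b in names], axis=0)
    undefined = total <= 0
    relative = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in names:
            relative[b] = np.where(undefined, np.nan, absolute[b] / total)
    return BandPowerResult(ids, relative, absolute, undefined)


def band_powers_welch(x: np.ndarray, fs: float,
                      bands: dict[str, tuple[float, float]] | None = None,
                      nperseg: int | None = None) -> dict[str, float]:
    """Band powers straight from the raw PSD (no decomposition)."""
    bands = BANDS if bands is None else bands
    return {b: _welch_band_power(x, fs, lo, hi, nperseg)
            for b, (lo, hi) in bands.items()}


def lfp_peak_amplitude(rec: Recording) -> np.ndarray:
    """Per-channel maximum absolute amplitude (volts)."""
    return np.max(np.abs(rec.data), axis=1)


def power_connectivity(
    rec: Recording,
    band: str,
    window_s: float = 5.0,
    threshold: float | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> tuple[ConnectivityGraph, np.ndarray]:
    """Connectivity from correlated relative band-power time courses.

    Each channel yields one relative-power value of ``band`` per consecutive
    ``window_s`` window (PSD integration over band edges within the window).
    Pairwise Pearson coefficients above the median + 1 SD of the coefficient
    distribution become edges; pass ``threshold`` to override.
    Returns (graph, correlation matrix).
    """
    bands = BANDS if bands is None else bands
    if band not in bands:
        raise ValueError(f"unknown band {band!r}")
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if rec.duration_s < 2 * window_s:
        raise ValueError("duration must cover at least two windows")
    wlen = int(round(window_s * rec.fs_hz))
    nwin = rec.n_samples // wlen
    names = list(bands)
    series = np.zeros((rec.n_channels, nwin))
    for ch in range(rec.n_channels):
        for w in range(nwin):
            seg = rec.data[ch, w * wlen:(w + 1) * wlen]
            powers = {b: _welch_band_power(seg, rec.fs_hz, *bands[b])
                      for b in names}
            tot = sum(powers.values())
            series[ch, w] = powers[band] / tot if tot > 0 else np.nan
    # zero-variance / undefined channels flagged and excluded pairwise
    valid = np.array([
        np.isfinite(series[ch]).all() and series[ch].std() > 0
        for ch in range(rec.n_channels)
    ])
    corr = np.full((rec.n_channels, rec.n_channels), np.nan)
    if valid.sum() >= 2:
        corr[np.ix_(valid, valid)] = np.corrcoef(series[valid])
    if threshold is None:
        iu = np.triu_indices(rec.n_channels, k=1)
        coefs = corr[iu]
        coefs = coefs[np.isfinite(coefs)]
        threshold = float(np.median(coefs) + coefs.std()) if coefs.size else np.inf
    g = connectivity_graph(corr, rec.channel_ids, threshold=threshold,
                           basis="band_power")
    return g, corr
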