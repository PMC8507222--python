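"""Phase-amplitude coupling via the Kullback-Leibler modulation index.

The slow band's instantaneous phase and the fast band's amplitude envelope
come from the analytic signal of zero-phase FIR band-passed traces.  Phases
are binned into 18 bins of 20 degrees; the mean envelope per bin, normalized
to a probability distribution P, gives

    MI = (log N - H(P)) / log N,    H(P) = -sum p log p,

which is 0 for a phase-uniform envelope and 1 when all envelope mass sits in
one bin.  The standard panel couples delta/theta phase with lower/upper
gamma amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io import Recording
from .oscillations import BANDS
from .preprocess import design_bandpass, zero_phase_fir

__all__ = [
    "PACResult",
    "band_pass_signal",
    "extract_phase",
    "extract_amplitude",
    "modulation_index",
    "pac_panel",
]


@dataclass
class PACResult:
    phase_band: str
    amp_band: str
    n_bins: int
    bin_amplitude_distribution: np.ndarray = field(
        default_factory=lambda: np.empty(0))
    mi: float = float("nan")
    undefined: bool = False
    empty_bins: int = 0


def band_pass_signal(x: np.ndarray, fs_hz: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase FIR band-pass used for phase/amplitude extraction."""
    x = np.asarray(x, dtype=float)
    # ~3 cycles of the low edge, capped at a third of the trace
    numtaps = int(round(3 * fs_hz / lo))
    numtaps = max(31, min(numtaps, max(31, x.shape[-1] // 3)))
    taps = design_bandpass(fs_hz, lo, hi, transition_hz=3.3 * fs_hz / numtaps)
    return zero_phase_fir(x, taps)[0]


def extract_phase(band_signal: np.ndarray) -> tuple[np.ndarray, bool]:
    """Instantaneous phase in [-pi, pi); flagged undefined for zero input."""
    x = np.asarray(band_signal, dtype=float)
    if not np.any(x):
        return np.full(x.shape, np.nan), False
    return np.angle(hilbert(x)), True


def extract_amplitude(band_signal: np.ndarray) -> np.ndarray:
    """Analytic-signal envelope (>= 0)."""
    x = np.asarray(band_signal, dtype=float)
    if not np.any(x):
        return np.zeros_like(x)
    return np.abs(hilbert(x))


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = 18,
                     phase_band: str = "", amp_band: str = "") -> PACResult:
    """KL-normalized modulation index of the phase-binned envelope."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ok = np.isfinite(phase) & np.isfinite(amplitude)
    if not ok.any() or not np.any(amplitude[ok]):
        return PACResult(phase_band, amp_band, n_bins, undefined=True)
    phase, amplitude = phase[ok], amplitude[ok]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=amplitude, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    means = np.zeros(n_bins)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    total = means.sum()
    if total <= 0:
        return PACResult(phase_band, amp_band, n_bins, undefined=True)
    p = means / total
    pos = p > 0
    entropy = float(-np.sum(p[pos] * np.log(p[pos])))
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    return PACResult(phase_band, amp_band, n_bins,
                     bin_amplitude_distribution=p, mi=float(mi),
                     empty_bins=int((~nz).sum()))


def pac_panel(
    rec: Recording,
    phase_bands: tuple[str, ...] = ("delta", "theta"),
    amp_bands: tuple[str, ...] = ("low_gamma", "upper_gamma"),
    n_bins: int = 18,
) -> pd.DataFrame:
    """MI for each (phase, amplitude) band pair, per channel.

    Returns a tidy frame (channel_id, metric_name, value, undefined) with
    metric names like ``mi_delta_upper_gamma``.  Expects the 1000 Hz LFP.
    """
    rows = []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        phases = {}
        for pb in phase_bands:
            sig = band_pass_signal(x, rec.fs_hz, *BANDS[pb])
            phases[pb], _ = extract_phase(sig)
        amps = {}
        for ab in amp_bands:
            sig = band_pass_signal(x, rec.fs_hz, *BANDS[ab])
            amps[ab] = extract_amplitude(sig)
        for pb in phase_bands:
            for ab in amp_bands:
                res = modulation_index(phases[pb], amps[ab], n_bins, pb, ab)
                rows.append({
                    "channel_id": rec.channel_ids[ch],
                    "metric_name": f"mi_{pb}_{ab}",
                    "value": res.mi,
                    "undefined": res.undefined,
                })
    return pd.DataFrame(rows)
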