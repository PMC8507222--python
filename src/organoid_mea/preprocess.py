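"""Signal conditioning applied before any analysis.

Three stages: Savitzky-Golay smoothing of the raw trace, a zero-phase FIR
band-pass (300-2500 Hz) isolating multi-unit spikes, and an anti-aliased
decimation to 1000 Hz for the local-field-potential analyses.

All FIR filters are odd-length symmetric windows applied by centred
convolution, which is exactly zero-phase: spike timing and the phase used for
phase-amplitude coupling are never shifted.
"""

from __future__ import annotations

from math import ceil, gcd

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "savgol_smooth",
    "spike_band_filter",
    "lfp_downsample",
    "zero_phase_fir",
    "design_bandpass",
    "design_lowpass",
]

# Hamming-window FIR: transition width ~ 3.3/N * fs, stopband ~ 53 dB.
_HAMMING_TRANSITION = 3.3


def _odd(n: int) -> int:
    n = int(n)
    return n + 1 if n % 2 == 0 else n


def zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an odd-length linear-phase FIR with zero net delay.

    Centred 'same' convolution of a symmetric kernel has exactly zero phase;
    edges see an implicit zero extension.
    """
    if taps.size % 2 != 1:
        raise ValueError("taps must have odd length for zero-phase application")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = signal.oaconvolve(x, taps[None, :], mode="same", axes=1)
    return out


def design_bandpass(fs_hz: float, low_hz: float, high_hz: float,
                    transition_hz: float | None = None) -> np.ndarray:
    """Linear-phase band-pass with -6 dB points at (low_hz, high_hz)."""
    if not 0 < low_hz < high_hz:
        raise ValueError(f"invalid band ordering: ({low_hz}, {high_hz})")
    if high_hz >= fs_hz / 2:
        raise ValueError(
            f"high edge {high_hz} Hz must lie below Nyquist {fs_hz / 2} Hz"
        )
    if transition_hz is None:
        transition_hz = low_hz / 2.0  # reach full attenuation by 0.5x low edge
    numtaps = _odd(ceil(_HAMMING_TRANSITION * fs_hz / transition_hz))
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs_hz)


def design_lowpass(fs_hz: float, passband_hz: float, stopband_hz: float) -> np.ndarray:
    """Linear-phase low-pass: flat to passband_hz, stopped by stopband_hz."""
    if not 0 < passband_hz < stopband_hz < fs_hz / 2:
        raise ValueError(
            f"need 0 < passband ({passband_hz}) < stopband ({stopband_hz}) "
            f"< Nyquist ({fs_hz / 2})"
        )
    width = stopband_hz - passband_hz
    numtaps = _odd(ceil(_HAMMING_TRANSITION * fs_hz / width))
    cutoff = 0.5 * (passband_hz + stopband_hz)
    return signal.firwin(numtaps, cutoff, fs=fs_hz)


def savgol_smooth(rec: Recording, order: int = 2, window_points: int = 9) -> Recording:
    """Savitzky-Golay smoothing along time (default: order 2, 9-point window).

    Reproduces polynomials up to ``order`` exactly in the interior; reduces
    broadband noise variance by the squared norm of the kernel.
    """
    if window_points % 2 != 1:
        raise ValueError("window_points must be odd")
    if window_points <= order:
        raise ValueError("window_points must exceed the polynomial order")
    out = signal.savgol_filter(rec.data, window_points, order, axis=1)
    return rec.copy_with(out)


def spike_band_filter(rec: Recording, low_hz: float = 300.0,
                      high_hz: float = 2500.0) -> Recording:
    """Zero-phase 300-2500 Hz band-pass isolating the multi-unit spike band."""
    taps = design_bandpass(rec.fs_hz, low_hz, high_hz)
    return rec.copy_with(zero_phase_fir(rec.data, taps))


def lfp_downsample(rec: Recording, cutoff_hz: float = 400.0,
                   target_fs_hz: float = 1000.0) -> Recording:
    """Anti-aliased decimation to the LFP rate (default 1000 Hz).

    ``cutoff_hz`` is the preserved passband edge; the stopband starts at the
    target Nyquist so that folded energy is suppressed (Hamming design,
    >50 dB).  Integer decimation keeps sample t0 alignment; non-integer
    ratios go through polyphase resampling with the same filter.
    """
    if cutoff_hz > target_fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz exceeds target Nyquist {target_fs_hz / 2} Hz"
        )
    if target_fs_hz > rec.fs_hz:
        raise ValueError("target rate exceeds input rate")
    if target_fs_hz == rec.fs_hz:
        return rec.copy_with(rec.data.copy())
    taps = design_lowpass(rec.fs_hz, cutoff_hz, target_fs_hz / 2)
    ratio = rec.fs_hz / target_fs_hz
    if abs(ratio - round(ratio)) < 1e-9:
        filtered = zero_phase_fir(rec.data, taps)
        out = filtered[:, :: int(round(ratio))]
    else:
        # rational resampling; filter at the upsampled rate
        num = int(round(target_fs_hz * 1000))
        den = int(round(rec.fs_hz * 1000))
        g = gcd(num, den)
        up, down = num // g, den // g
        taps_up = design_lowpass(rec.fs_hz * up, cutoff_hz, target_fs_hz / 2) * up
        out = signal.resample_poly(rec.data, up, down, axis=1, window=taps_up)
    return rec.copy_with(np.ascontiguousarray(out), fs_hz=target_fs_hz)
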