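"""Synchrosqueezed continuous wavelet transform and band-limited inversion.

The oscillation analyses decompose the 1000 Hz LFP into narrow bands by
synchrosqueezing: an analytic-Morlet CWT is reassigned in frequency using the
phase transform (the instantaneous frequency of each coefficient), which
collapses the wavelet's spectral smear onto sharp ridges.  A band-limited
signal is then recovered by the one-sided Morlet inversion restricted to the
reassigned frequencies falling inside the band.

Construction (Daubechies-Maes):

  W(a, b)   = CWT with a^(-1/2) normalisation, analytic Morlet
              psi_hat(xi) = exp(-(xi - mu)^2 / 2), xi > 0
  omega(a,b)= Im[ d/db W(a,b) / W(a,b) ] / (2 pi)      (phase transform, Hz)
  x(b)      = (2 / C_psi) * Re integral W(a, b) a^(-3/2) da
  C_psi     = integral_0^inf psi_hat(xi) dxi / xi

(the analytic wavelet sees only positive frequencies, which carry half of a
real signal, hence the factor 2).

Restricting the a-integral to coefficients whose omega(a,b) lies inside a
band yields that band's analytic component; its real part is the band signal.
On a log-spaced scale grid the integral is a^(-1/2) * dln(a)-weighted sum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.integrate import quad

__all__ = ["sst_band_signals", "synchrosqueeze", "morlet_admissibility"]

_DEFAULT_MU = 6.0


@lru_cache(maxsize=8)
def morlet_admissibility(mu: float = _DEFAULT_MU) -> float:
    """C_psi = int_0^inf exp(-(xi-mu)^2/2) dxi/xi for the analytic Morlet."""
    val, _ = quad(lambda x: np.exp(-0.5 * (x - mu) ** 2) / x, 1e-8, mu + 12.0)
    return val


def _scale_grid(fs_hz: float, fmin_hz: float, fmax_hz: float, voices: int,
                mu: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-spaced centre frequencies (ascending) and scales in samples."""
    n_octaves = np.log2(fmax_hz / fmin_hz)
    n_scales = int(np.ceil(n_octaves * voices)) + 1
    freqs = fmin_hz * 2.0 ** (np.arange(n_scales) / voices)
    freqs = freqs[freqs <= fmax_hz * (1 + 1e-12)]
    scales = mu * fs_hz / (2 * np.pi * freqs)  # peak response at freqs
    dlog = np.log(2.0) / voices
    return freqs, scales, dlog


def _padded_fft(x: np.ndarray, pad: int) -> tuple[np.ndarray, int, int]:
    n = x.size
    pad = min(pad, n)
    target = next_fast_len(n + 2 * pad)
    extra = target - (n + 2 * pad)
    left = pad
    xp = np.pad(x, (pad, pad + extra), mode="reflect")
    return fft(xp), left, target


def sst_band_signals(
    x: np.ndarray,
    fs_hz: float,
    bands: dict[str, tuple[float, float]],
    fmin_hz: float = 0.5,
    fmax_hz: float | None = None,
    voices: int = 32,
    mu: float = _DEFAULT_MU,
    block: int = 32,
) -> dict[str, np.ndarray]:
    """Band-limited reconstructions of ``x`` via synchrosqueezing.

    Coefficients are assigned to a band when their reassigned (instantaneous)
    frequency falls inside the band's edges; the band signal is the Morlet
    inverse over those coefficients.  Bands above Nyquist raise.

    Scales are processed in blocks so memory stays O(block * n).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    nyq = fs_hz / 2
    for name, (lo, hi) in bands.items():
        if not 0 < lo < hi:
            raise ValueError(f"band {name}: invalid edges ({lo}, {hi})")
        if hi >= nyq:
            raise ValueError(f"band {name}: upper edge {hi} Hz >= Nyquist {nyq} Hz")
    if fmax_hz is None:
        fmax_hz = min(0.9 * nyq, 450.0)
    out = {name: np.zeros(n) for name in bands}
    if n == 0 or not np.any(x):
        return out

    freqs, scales, dlog = _scale_grid(fs_hz, fmin_hz, fmax_hz, voices, mu)
    # pad by ~4 time-stds of the largest-scale wavelet
    pad = int(np.ceil(4 * scales[0]))
    X, left, ntot = _padded_fft(x, pad)
    xi = 2 * np.pi * np.arange(ntot) / ntot  # rad/sample, [0, 2pi)
    half = ntot // 2 + 1

    cpsi = morlet_admissibility(mu)
    tiny = 1e-10 * np.sqrt(np.mean(x**2))

    acc = {name: np.zeros(n, dtype=complex) for name in bands}
    for s0 in range(0, scales.size, block):
        sl = slice(s0, min(s0 + block, scales.size))
        a = scales[sl][:, None]  # (k, 1)
        psi = np.zeros((a.size, ntot))
        arg = a * xi[None, :half]
        psi[:, :half] = np.exp(-0.5 * (arg - mu) ** 2)
        psi[:, 0] = 0.0
        base = np.sqrt(a) * psi
        W = ifft(X[None, :] * base, axis=1)[:, left:left + n]
        dW = ifft(X[None, :] * base * (1j * xi[None, :] * fs_hz), axis=1)[
            :, left:left + n
        ]
        mag = np.abs(W)
        ok = mag > tiny
        with np.errstate(divide="ignore", invalid="ignore"):
            finst = np.where(ok, (dW / np.where(ok, W, 1)).imag / (2 * np.pi), -1.0)
        weight = (a ** -0.5) * dlog  # a^{-3/2} da on the log grid
        for name, (lo, hi) in bands.items():
            sel = ok & (finst >= lo) & (finst <= hi)
            acc[name] += np.sum(np.where(sel, W, 0) * weight, axis=0)
    for name in bands:
        out[name] = (2.0 * acc[name] / cpsi).real
    return out


def synchrosqueeze(
    x: np.ndarray,
    fs_hz: float,
    fmin_hz: float = 0.5,
    fmax_hz: float | None = None,
    voices: int = 32,
    mu: float = _DEFAULT_MU,
) -> tuple[np.ndarray, np.ndarray]:
    """Full synchrosqueezed transform ``(Tx, freqs)``.

    Tx has shape (n_freqs, n_samples); summing rows over a frequency range
    and taking ``(2 * sum / C_psi).real`` reconstructs that range's signal.
    Intended for inspection and tests on short signals (dense output).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if fmax_hz is None:
        fmax_hz = min(0.9 * fs_hz / 2, 450.0)
    freqs, scales, dlog = _scale_grid(fs_hz, fmin_hz, fmax_hz, voices, mu)
    pad = int(np.ceil(4 * scales[0]))
    X, left, ntot = _padded_fft(x, pad)
    xi = 2 * np.pi * np.arange(ntot) / ntot
    half = ntot // 2 + 1
    tiny = 1e-10 * np.sqrt(np.mean(x**2)) if np.any(x) else np.inf

    Tx = np.zeros((freqs.size, n), dtype=complex)
    log_f0 = np.log2(freqs[0])
    for k, a in enumerate(scales):
        psi = np.zeros(ntot)
        psi[:half] = np.exp(-0.5 * (a * xi[:half] - mu) ** 2)
        psi[0] = 0.0
        base = np.sqrt(a) * psi
        W = ifft(X * base)[left:left + n]
        dW = ifft(X * base * (1j * xi * fs_hz))[left:left + n]
        ok = np.abs(W) > tiny
        finst = np.full(n, -1.0)
        finst[ok] = (dW[ok] / W[ok]).imag / (2 * np.pi)
        rows = np.round((np.log2(np.where(finst > 0, finst, freqs[0])) - log_f0)
                        * voices).astype(int)
        valid = ok & (finst > 0) & (rows >= 0) & (rows < freqs.size)
        contrib = W * (a ** -0.5) * dlog
        np.add.at(Tx, (rows[valid], np.nonzero(valid)[0]), contrib[valid])
    return Tx, freqs
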