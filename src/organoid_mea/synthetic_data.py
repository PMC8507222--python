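"""Synthetic MEA recordings with exact ground truth.

Emulates what an organoid sitting on a 60-electrode array produces: Gaussian
background noise, extracellular spike waveforms at Poisson/bursty times,
periodic network events that recruit a subset of channels, additive
narrow-band oscillations (delta through upper gamma) with slow amplitude
drift, and phase-amplitude coupling of a fast band's envelope to a slow
band's phase.  Every downstream metric (spike times, burst intervals,
connected pairs, band-power fractions, coupling depth) has a known answer,
so the whole pipeline is verifiable without lab data.

Two phenotype presets are provided.  ``healthy`` fires and bursts briskly
with near-full network recruitment; ``mutant`` mirrors a degenerating
network: fewer bursts, weaker recruitment, enhanced delta power and stronger
delta-phase -> upper-gamma-amplitude coupling.  The preset magnitudes are
this package's choices for a clearly separated cohort; they are not measured
values from any particular tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import Recording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "simulate_cohort",
    "spike_template",
    "healthy_config",
    "mutant_config",
    "PRESETS",
    "save_ground_truth",
    "load_ground_truth",
]

BAND_CENTERS_HZ = {
    "delta": 2.25,
    "theta": 6.5,
    "alpha": 11.0,
    "beta": 23.0,
    "low_gamma": 56.5,
    "upper_gamma": 150.0,
}
BAND_EDGES_HZ = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (9.0, 13.0),
    "beta": (14.0, 32.0),
    "low_gamma": (33.0, 80.0),
    "upper_gamma": (100.0, 200.0),
}

_REFRACTORY_S = 0.002  # absolute refractory enforced on each channel's train


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults give a plausible active network."""

    n_channels: int = 8
    duration_s: float = 60.0
    fs_hz: float = 5000.0
    noise_sd: float = 5e-6            # volts
    spike_amplitude: float = 50e-6    # volts, magnitude of the negative peak
    tonic_rate_hz: float = 1.0        # Poisson background firing per channel
    burst_rate_per_min: float = 12.0  # Poisson burst onsets per channel
    spikes_per_burst: int = 6
    intra_burst_isi_ms: float = 15.0
    network_event_period_s: float | None = 5.0
    network_participation: float = 0.9
    band_amplitudes: dict[str, float] = field(default_factory=dict)
    pac_phase_band: str = "delta"
    pac_amp_band: str = "upper_gamma"
    pac_depth: float = 0.0            # m in (1 + m cos phi) / (1 + m)
    shared_oscillation_drift: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")
        for name, amp in self.band_amplitudes.items():
            if name not in BAND_EDGES_HZ:
                raise ValueError(f"unknown band {name!r}")
            if amp < 0:
                raise ValueError(f"band amplitude for {name} must be >= 0")
            if amp > 0 and self.fs_hz <= 2 * BAND_EDGES_HZ[name][1]:
                raise ValueError(
                    f"fs_hz {self.fs_hz} violates Nyquist for band {name} "
                    f"(upper edge {BAND_EDGES_HZ[name][1]} Hz)"
                )
        for attr in ("noise_sd", "spike_amplitude", "tonic_rate_hz",
                     "burst_rate_per_min", "intra_burst_isi_ms"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")
        if not 0 <= self.network_participation <= 1:
            raise ValueError("network_participation must lie in [0, 1]")
        if not 0 <= self.pac_depth <= 1:
            raise ValueError("pac_depth must lie in [0, 1]")
        if self.network_event_period_s is not None and self.network_event_period_s <= 0:
            raise ValueError("network_event_period_s must be positive or None")
        for b in (self.pac_phase_band, self.pac_amp_band):
            if b not in BAND_EDGES_HZ:
                raise ValueError(f"unknown band {b!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as f:
            return cls(**json.load(f))


@dataclass
class GroundTruth:
    """Exact answers for every downstream metric."""

    spike_times: list[list[float]]                  # per channel, sorted
    burst_intervals: list[list[tuple[float, float]]]
    connected_pairs: set[tuple[int, int]]           # network-subset channel pairs
    true_band_power: dict[str, float]               # realised relative fractions
    true_pac_depth: float
    network_event_times: list[float] = field(default_factory=list)
    network_subset: list[int] = field(default_factory=list)


def spike_template(fs_hz: float, amplitude: float) -> np.ndarray:
    """Biphasic extracellular waveform, ~2 ms, negative-dominant.

    Peak (most negative) sample has magnitude ``amplitude``; the index of
    that sample within the template is the ground-truth spike time.
    """
    t = np.arange(-0.001, 0.001, 1.0 / fs_hz)
    w = -np.exp(-0.5 * (t / 2.5e-4) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - 4.5e-4) / 3.5e-4) ** 2
    )
    return amplitude * w / np.abs(w).max()


def _slow_drift(rng: np.random.Generator, n: int, fs_hz: float,
                sd: float = 0.2, tau_s: float = 2.0) -> np.ndarray:
    """Positive slow multiplicative envelope, mean ~1, SD ~``sd``."""
    raw = rng.normal(size=n)
    f = np.fft.rfftfreq(n, 1 / fs_hz)
    smooth = np.fft.irfft(np.fft.rfft(raw) * np.exp(-0.5 * (f * tau_s * 2 * np.pi) ** 2),
                          n)
    s = smooth.std()
    if s > 0:
        smooth = smooth / s * sd
    return np.clip(1.0 + smooth, 0.05, None)


def _thin_refractory(times: np.ndarray, labels: np.ndarray,
                     refractory_s: float) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(times, kind="mergesort")
    times, labels = times[order], labels[order]
    keep = np.ones(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if t - last < refractory_s:
            keep[i] = False
        else:
            last = t
    return times[keep], labels[keep]


def simulate_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its exact ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.  Components are additive: noise + injected spike waveforms +
    per-band oscillations.  With coupling depth m, the amplitude band's
    envelope is multiplied by (1 + m cos phi) / (1 + m), phi being the phase
    of the phase band's carrier.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    C = config.n_channels
    fs = config.fs_hz
    dur = config.duration_s

    data = rng.normal(0.0, config.noise_sd, size=(C, n)) if config.noise_sd > 0 \
        else np.zeros((C, n))

    # --- network-event schedule and recruited subset (fixed per recording)
    event_times: list[float] = []
    subset: list[int] = []
    if config.network_event_period_s is not None and config.network_participation > 0:
        T = config.network_event_period_s
        event_times = list(np.arange(T / 2, dur - 0.1, T))
        k = int(np.ceil(config.network_participation * C))
        subset = sorted(rng.choice(C, size=k, replace=False).tolist())

    # --- spike times per channel: tonic Poisson + Poisson burst clusters
    #     + network-event clusters; 2 ms refractory on the merged train
    template = spike_template(fs, config.spike_amplitude)
    peak_idx = int(np.argmin(template))
    spike_times: list[list[float]] = []
    burst_intervals: list[list[tuple[float, float]]] = []
    burst_isi = config.intra_burst_isi_ms / 1000.0
    for ch in range(C):
        times = []
        labels = []  # -1 tonic, >=0 cluster id
        cluster = 0
        if config.tonic_rate_hz > 0:
            n_tonic = rng.poisson(config.tonic_rate_hz * dur)
            times.append(rng.uniform(0, dur, size=n_tonic))
            labels.append(np.full(n_tonic, -1))
        if config.burst_rate_per_min > 0:
            n_b = rng.poisson(config.burst_rate_per_min / 60.0 * dur)
            onsets = rng.uniform(0, dur, size=n_b)
            for o in onsets:
                ts = o + np.arange(config.spikes_per_burst) * burst_isi
                times.append(ts)
                labels.append(np.full(ts.size, cluster))
                cluster += 1
        if ch in subset:
            for ev in event_times:
                jit = rng.uniform(-0.01, 0.01)
                ts = ev + jit + np.arange(config.spikes_per_burst) * burst_isi
                times.append(ts)
                labels.append(np.full(ts.size, cluster))
                cluster += 1
        if times:
            t_all = np.concatenate(times)
            l_all = np.concatenate(labels)
            inside = (t_all >= 0) & (t_all < dur - 0.002)
            t_all, l_all = t_all[inside], l_all[inside]
            t_all, l_all = _thin_refractory(t_all, l_all, _REFRACTORY_S)
        else:
            t_all = np.empty(0)
            l_all = np.empty(0)

        # snap to samples and inject
        idx = np.round(t_all * fs).astype(int)
        snapped = idx / fs
        for i in idx:
            lo = i - peak_idx
            hi = lo + template.size
            a = max(lo, 0)
            b = min(hi, n)
            if a < b:
                data[ch, a:b] += template[a - lo:b - lo]
        spike_times.append(snapped.tolist())

        ivals = []
        for cid in np.unique(l_all[l_all >= 0]):
            member = snapped[l_all == cid]
            if member.size:
                ivals.append((float(member.min()), float(member.max())))
        ivals.sort()
        # ground-truth intervals: merge any that overlap after refractory thinning
        merged: list[tuple[float, float]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        burst_intervals.append(merged)

    # --- oscillations: band-centre sinusoids with slow amplitude drift
    t = np.arange(n) / fs
    comp_power = {b: 0.0 for b in BAND_EDGES_HZ}
    shared_drifts: dict[str, np.ndarray] = {}
    shared_phases: dict[str, float] = {}
    if config.shared_oscillation_drift:
        for band, amp in config.band_amplitudes.items():
            if amp > 0:
                shared_drifts[band] = _slow_drift(rng, n, fs)
                shared_phases[band] = rng.uniform(0, 2 * np.pi)
    # process the coupling phase band first so its carrier phase exists when
    # the amplitude band is modulated
    band_order = sorted(
        config.band_amplitudes,
        key=lambda b: (b != config.pac_phase_band, list(BAND_EDGES_HZ).index(b)),
    )
    for ch in range(C):
        share = config.shared_oscillation_drift and (not subset or ch in subset)
        phase_carrier = None
        for band in band_order:
            amp = config.band_amplitudes[band]
            if amp <= 0:
                continue
            fc = BAND_CENTERS_HZ[band]
            if share and band in shared_drifts:
                env = shared_drifts[band]
                th0 = shared_phases[band]
            else:
                env = _slow_drift(rng, n, fs)
                th0 = rng.uniform(0, 2 * np.pi)
            phi = 2 * np.pi * fc * t + th0
            if band == config.pac_phase_band:
                phase_carrier = phi
            comp = amp * env * np.cos(phi)
            if band == config.pac_amp_band and config.pac_depth > 0:
                if phase_carrier is None:
                    # phase band carries no amplitude: use its nominal phase
                    phase_carrier = 2 * np.pi * BAND_CENTERS_HZ[
                        config.pac_phase_band] * t
                m = config.pac_depth
                comp = comp * (1 + m * np.cos(phase_carrier)) / (1 + m)
            data[ch] += comp
            comp_power[band] += float(np.mean(comp**2))
    total = sum(comp_power.values())
    true_band_power = {
        b: (p / total if total > 0 else 0.0) for b, p in comp_power.items()
    }

    pairs = {
        (a, b) for i, a in enumerate(subset) for b in subset[i + 1:]
    } if len(subset) >= 2 else set()

    rec = Recording(data=data, fs_hz=fs,
                    channel_ids=[f"ch{i:02d}" for i in range(C)])
    gt = GroundTruth(
        spike_times=spike_times,
        burst_intervals=burst_intervals,
        connected_pairs=pairs,
        true_band_power=true_band_power,
        true_pac_depth=config.pac_depth,
        network_event_times=[float(e) for e in event_times],
        network_subset=subset,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# phenotype presets

def healthy_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        seed=seed,
        burst_rate_per_min=4.0,
        network_participation=0.9,
        band_amplitudes={
            "delta": 5e-6,
            "theta": 4e-6,
            "alpha": 3e-6,
            "beta": 3e-6,
            "low_gamma": 4e-6,
            "upper_gamma": 4e-6,
        },
        pac_depth=0.2,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def mutant_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Disease phenotype: fewer bursts, weaker recruitment, enhanced delta
    power and stronger delta->upper-gamma coupling."""
    cfg = SimulationConfig(
        seed=seed,
        burst_rate_per_min=2.0,
        network_participation=0.5,
        band_amplitudes={
            "delta": 12e-6,
            "theta": 4e-6,
            "alpha": 3e-6,
            "beta": 3e-6,
            "low_gamma": 4e-6,
            "upper_gamma": 4e-6,
        },
        pac_depth=0.7,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


PRESETS = {"healthy": healthy_config, "mutant": mutant_config}


def simulate_cohort(preset: str, n_organoids: int, seed: int = 0,
                    **overrides) -> list[tuple[Recording, GroundTruth]]:
    """Simulate ``n_organoids`` recordings; organoid i uses seed ``seed + i``."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_organoids < 1:
        raise ValueError("n_organoids must be >= 1")
    out = []
    for i in range(n_organoids):
        cfg = PRESETS[preset](seed=seed + i, **overrides)
        out.append(simulate_recording(cfg))
    return out


# ---------------------------------------------------------------------------
# ground-truth sidecar (JSON)

def save_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "spike_times": gt.spike_times,
        "burst_intervals": [[list(iv) for iv in ch] for ch in gt.burst_intervals],
        "connected_pairs": sorted([list(p) for p in gt.connected_pairs]),
        "true_band_power": gt.true_band_power,
        "true_pac_depth": gt.true_pac_depth,
        "network_event_times": gt.network_event_times,
        "network_subset": gt.network_subset,
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as f:
        d = json.load(f)
    return GroundTruth(
        spike_times=d["spike_times"],
        burst_intervals=[[tuple(iv) for iv in ch] for ch in d["burst_intervals"]],
        connected_pairs={tuple(p) for p in d["connected_pairs"]},
        true_band_power=d["true_band_power"],
        true_pac_depth=d["true_pac_depth"],
        network_event_times=d.get("network_event_times", []),
        network_subset=d.get("network_subset", []),
    )
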