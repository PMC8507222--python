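"""Detection, activity rule, burst logic (vs brute force), firing stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organoid_mea import preprocess as pp
from organoid_mea import spikes as sp
from organoid_mea import synthetic_data as sd
from organoid_mea.io import Recording


def _train(times, ch="ch00"):
    return sp.SpikeTrain(ch, np.asarray(times, dtype=float), 0.0, 1.0, 0.0)


def brute_force_bursts(times, min_spikes=4, window_s=0.1):
    """Independent O(n^2) oracle: enumerate every spike-anchored window,
    merge overlapping qualifying windows, report member spans."""
    times = np.asarray(times, dtype=float)
    windows = []
    for i, t0 in enumerate(times):
        members = [j for j, t in enumerate(times) if t0 <= t <= t0 + window_s]
        if len(members) >= min_spikes:
            windows.append((t0, t0 + window_s))
    merged = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        member = [t for t in times if s <= t <= e]
        out.append(((member[0], member[-1]), len(member)))
    return out


class TestDetect:
    def test_constant_channel_flagged_not_crash(self):
        rec = Recording(np.zeros((1, 200_000)), 5000.0)
        (tr,) = sp.detect_spikes(rec)
        assert tr.n_spikes == 0 and tr.degenerate_baseline

    def test_injected_spikes_recovered(self):
        cfg = sd.SimulationConfig(n_channels=2, duration_s=40, fs_hz=5000,
                                  tonic_rate_hz=2.5, burst_rate_per_min=0,
                                  network_event_period_s=None, seed=11)
        rec, gt = sd.simulate_recording(cfg)  # amplitude = 10x noise SD
        fb = pp.spike_band_filter(rec, 300, 2250)
        trains = sp.detect_spikes(fb, baseline_window_s=30, refractory_ms=2)
        hit = tot = 0
        for ch, tr in enumerate(trains):
            for t in gt.spike_times[ch]:
                tot += 1
                if tr.n_spikes and np.min(np.abs(tr.times_s - t)) <= 1e-3:
                    hit += 1
        assert hit / tot >= 0.99

    def test_false_event_rate_matches_crossing_oracle(self):
        """On pure filtered noise the detector's event count equals the
        refractory-merged threshold-upcrossing count of |x - mean|."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = Recording(rng.normal(0, 5e-6, (1, 5000 * 40)), 5000.0)
            fb = pp.spike_band_filter(rec, 300, 2250)
            (tr,) = sp.detect_spikes(fb, baseline_window_s=30)
            d = np.abs(fb.data[0] - tr.baseline_mean_v)
            thr = 4 * tr.baseline_sd_v
            ups = np.nonzero((d[1:] > thr) & (d[:-1] <= thr))[0]
            refr = int(1e-3 * 5000)
            n_oracle = (1 + np.sum(np.diff(ups) > refr)) if ups.size else 0
            assert abs(tr.n_spikes - n_oracle) <= max(2, 0.05 * n_oracle)

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        rec = Recording(rng.normal(0, 1e-5, (1, 5000 * 35)), 5000.0)
        counts = [sp.detect_spikes(rec, sd_multiplier=k)[0].n_spikes
                  for k in (3, 4, 5, 6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestActiveRule:
    @pytest.mark.parametrize("n_spikes,expected", [
        (0, False), (12, False), (13, True),
    ])
    def test_boundary_at_12_per_minute(self, n_spikes, expected):
        tr = _train(np.linspace(0.1, 59.9, n_spikes) if n_spikes else [])
        assert sp.classify_active(tr, 60.0) is expected

    def test_rate_scaled_by_duration(self):
        tr = _train(np.linspace(0.1, 29.9, 7))  # 14/min over 30 s
        assert sp.classify_active(tr, 30.0)


class TestBursts:
    def test_four_spikes_in_100ms_is_one_burst(self):
        bs = sp.detect_bursts(_train([0.0, 0.030, 0.060, 0.090]))
        assert bs.n_bursts == 1
        assert bs.spike_counts == [4]
        assert bs.intervals[0] == (0.0, 0.090)

    def test_three_spikes_is_none(self):
        assert sp.detect_bursts(_train([0.0, 0.040, 0.080])).n_bursts == 0

    def test_sparse_spikes_never_burst(self):
        assert sp.detect_bursts(_train(np.arange(50) * 0.2)).n_bursts == 0

    def test_matches_brute_force_on_random_trains(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 120)
            times = np.sort(rng.uniform(0, 10, size=n))
            times = times[np.concatenate(([True], np.diff(times) > 1e-4))]
            got = sp.detect_bursts(_train(times))
            want = brute_force_bursts(times)
            assert [(iv, c) for iv, c in
                    zip(got.intervals, got.spike_counts)] == [
                ((pytest.approx(iv[0]), pytest.approx(iv[1])), c)
                for iv, c in want]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 10.0, allow_nan=False), min_size=0,
                    max_size=60),
           st.integers(2, 6),
           st.floats(0.02, 0.3))
    def test_burst_oracle_property(self, raw_times, min_spikes, window_s):
        times = np.unique(np.asarray(raw_times, dtype=float))
        got = sp.detect_bursts(_train(times), min_spikes=min_spikes,
                               window_ms=window_s * 1000.0)
        want = brute_force_bursts(times, min_spikes=min_spikes,
                                  window_s=window_s)
        assert [(iv, c) for iv, c in
                zip(got.intervals, got.spike_counts)] == [
            ((pytest.approx(iv[0]), pytest.approx(iv[1])), c)
            for iv, c in want]

    def test_burst_membership_monotonicity(self):
        # merging can fuse bursts, so the monotone quantity is the number
        # of spikes belonging to any burst, not the burst count
        rng = np.random.default_rng(7)
        times = np.sort(rng.uniform(0, 10, size=300))
        tr = _train(times)
        by_min = [sum(sp.detect_bursts(tr, min_spikes=k).spike_counts)
                  for k in (3, 4, 5, 6)]
        assert all(a >= b for a, b in zip(by_min, by_min[1:]))
        n_by_window = [
            sum(sp.detect_bursts(tr, window_ms=w).spike_counts)
            for w in (50, 100, 200)]
        assert all(a <= b for a, b in zip(n_by_window, n_by_window[1:]))

    def test_burst_spikes_are_detected_spikes(self):
        cfg = sd.healthy_config(seed=13, duration_s=40)
        rec, _ = sd.simulate_recording(cfg)
        fb = pp.spike_band_filter(rec, 300, 2250)
        for tr in sp.detect_spikes(fb, baseline_window_s=30, refractory_ms=2):
            bs = sp.detect_bursts(tr)
            for (s, e), c in zip(bs.intervals, bs.spike_counts):
                inside = (tr.times_s >= s) & (tr.times_s <= e)
                assert inside.sum() == c
                assert 0 <= s <= e <= 40.0
                assert c >= 4


class TestChannelStats:
    def test_periodic_train_cv_zero(self):
        tr = _train(np.arange(100) * 0.5)
        st = sp.channel_stats(tr, sp.detect_bursts(tr), 50.0)
        assert st.isi_cv == pytest.approx(0.0, abs=1e-12)

    def test_rate_arithmetic(self):
        tr = _train(np.linspace(0.25, 59.75, 120))
        st = sp.channel_stats(tr, sp.detect_bursts(tr), 60.0)
        assert st.spike_rate_hz == pytest.approx(2.0)
        assert st.active

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(5)
        isis = rng.exponential(0.02, size=5000)
        tr = _train(np.cumsum(isis))
        st = sp.channel_stats(tr, sp.BurstSet("ch00"), float(tr.times_s[-1]))
        assert abs(st.isi_cv - 1.0) < 0.06  # ~3 SD of the CV estimator

    def test_short_train_flagged(self):
        tr = _train([1.0, 2.0])
        st = sp.channel_stats(tr, sp.BurstSet("ch00"), 10.0)
        assert not st.isi_cv_defined and np.isnan(st.isi_cv)


def test_burst_rate_recovery_on_simulator():
    """Detected burst rate within 15% of the configured Poisson rate
    (healthy preset without the extra periodic network bursts), 5 seeds."""
    rates = []
    for seed in range(5):
        cfg = sd.healthy_config(seed=seed, network_event_period_s=None)
        rec, _ = sd.simulate_recording(cfg)
        fb = pp.spike_band_filter(pp.savgol_smooth(rec), 300, 2250)
        trains = sp.detect_spikes(fb, baseline_window_s=30, refractory_ms=2)
        per_ch = [sp.detect_bursts(t).n_bursts / cfg.duration_s * 60
                  for t in trains]
        rates.append(np.mean(per_ch))
    assert np.mean(rates) == pytest.approx(4.0, rel=0.15)
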