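"""Connectivity graphs, window selection, and periodicity detection."""

import numpy as np
import pytest
from scipy import stats

from organoid_mea import network as nw
from organoid_mea import preprocess as pp
from organoid_mea import spikes as sp
from organoid_mea import synthetic_data as sd
from organoid_mea.io import Recording


def _train(times, ch="ch00"):
    return sp.SpikeTrain(ch, np.asarray(times, dtype=float), 0.0, 1.0, 0.0)


class TestWindow:
    def test_deterministic_under_seed(self):
        rec = Recording(np.random.default_rng(0).normal(size=(1, 3000)), 10.0)
        w1 = nw.select_analysis_window(rec, 60.0, seed=9)
        w2 = nw.select_analysis_window(rec, 60.0, seed=9)
        assert w1.t0_s == w2.t0_s
        np.testing.assert_array_equal(w1.data, w2.data)

    def test_exact_length_recording_returned_whole(self):
        rec = Recording(np.zeros((1, 600)), 10.0)
        w = nw.select_analysis_window(rec, 60.0, seed=0)
        assert w.t0_s == 0.0 and w.n_samples == 600

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nw.select_analysis_window(Recording(np.zeros((1, 100)), 10.0), 60.0)

    def test_start_times_uniform(self):
        rec = Recording(np.zeros((1, 3000)), 10.0)  # 300 s at 10 Hz
        rng = np.random.default_rng(123)
        starts = np.array([
            nw.select_analysis_window(rec, 60.0, rng).t0_s
            for _ in range(2000)])
        ks = stats.kstest(starts / 240.0, "uniform")
        assert ks.pvalue > 0.01


class TestSpikeCorrelation:
    def test_identical_trains_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 60, 300))
        corr, _ = nw.spike_correlation_matrix(
            [_train(t, "a"), _train(t.copy(), "b")], 0, 60)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_independent_poisson_below_threshold(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(300):
            a = np.sort(rng.uniform(0, 60, 300))
            b = np.sort(rng.uniform(0, 60, 300))
            corr, _ = nw.spike_correlation_matrix(
                [_train(a, "a"), _train(b, "b")], 0, 60)
            worst = max(worst, abs(corr[0, 1]))
        assert worst < 0.5

    def test_shared_network_bursts_exceed_threshold(self):
        # channels sharing every network-event burst, with modest
        # independent activity on top
        cfg = sd.healthy_config(seed=21, n_channels=2,
                                network_participation=1.0,
                                tonic_rate_hz=0.5, burst_rate_per_min=1.0)
        rec, gt = sd.simulate_recording(cfg)
        assert gt.connected_pairs == {(0, 1)}
        fb = pp.spike_band_filter(pp.savgol_smooth(rec), 300, 2250)
        trains = sp.detect_spikes(fb, baseline_window_s=30, refractory_ms=2)
        corr, ids = nw.spike_correlation_matrix(trains, 0, 60)
        assert corr[0, 1] > 0.5

    def test_graph_recovers_ground_truth_pairs(self):
        """At strong coupling the thresholded graph matches the simulator's
        connected pairs (Jaccard >= 0.9 over 3 seeds)."""
        for seed in (50, 51, 52):
            cfg = sd.healthy_config(seed=seed, network_participation=0.75,
                                    tonic_rate_hz=0.5, burst_rate_per_min=1.0)
            rec, gt = sd.simulate_recording(cfg)
            fb = pp.spike_band_filter(pp.savgol_smooth(rec), 300, 2250)
            trains = sp.detect_spikes(fb, baseline_window_s=30,
                                      refractory_ms=2)
            corr, ids = nw.spike_correlation_matrix(trains, 0, 60)
            g = nw.connectivity_graph(corr, ids)
            got = {tuple(sorted((ids.index(a), ids.index(b))))
                   for a, b, _ in g.edges}
            want = gt.connected_pairs
            jacc = len(got & want) / len(got | want)
            assert jacc >= 0.9, f"seed {seed}: Jaccard {jacc:.2f}"

    def test_zero_variance_channel_flagged(self):
        t = np.sort(np.random.default_rng(3).uniform(0, 60, 100))
        corr, _ = nw.spike_correlation_matrix(
            [_train(t, "a"), _train([], "b"), _train(t + 0.001, "c")], 0, 60)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[1, 2])
        assert np.isfinite(corr[0, 2])


class TestGraph:
    def test_strictly_above_half(self):
        # scan r = 0.00..1.00; the largest non-connecting value is 0.50
        largest_non = -1.0
        for r in np.round(np.arange(0, 1.01, 0.01), 2):
            m = np.array([[1.0, r], [r, 1.0]])
            g = nw.connectivity_graph(m, ["a", "b"])
            if g.graph.number_of_edges() == 0:
                largest_non = max(largest_non, r)
        assert largest_non == pytest.approx(0.50)

    def test_all_below_threshold_gives_empty(self):
        m = np.full((4, 4), 0.4)
        np.fill_diagonal(m, 1.0)
        g = nw.connectivity_graph(m, list("abcd"))
        assert g.graph.number_of_edges() == 0
        assert g.percent_connected == 0.0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 200))
        m = np.corrcoef(x)
        ids = [f"c{i}" for i in range(6)]
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7):
            edges = {frozenset(e[:2]) for e in
                     nw.connectivity_graph(m, ids, thr).edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_percent_connected_label_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 50))
        m = np.corrcoef(x)
        g1 = nw.connectivity_graph(m, list("abcdef"))
        perm = [3, 1, 4, 0, 5, 2]
        g2 = nw.connectivity_graph(m[np.ix_(perm, perm)],
                                   [list("abcdef")[i] for i in perm])
        assert g1.percent_connected == g2.percent_connected

    def test_asymmetric_rejected(self):
        m = np.array([[1.0, 0.2], [0.6, 1.0]])
        with pytest.raises(ValueError):
            nw.connectivity_graph(m, ["a", "b"])


class TestOverlappingBursts:
    def test_identical_sets_fully_connected(self):
        b = sp.BurstSet("a", [(0.0, 0.1), (1.0, 1.2)], [4, 5])
        b2 = sp.BurstSet("b", [(0.0, 0.1), (1.0, 1.2)], [4, 5])
        g = nw.overlapping_burst_connectivity([b, b2])
        assert g.graph.has_edge("a", "b")
        assert g.graph["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_disjoint_not_connected(self):
        b = sp.BurstSet("a", [(0.0, 0.1)], [4])
        b2 = sp.BurstSet("b", [(5.0, 5.1)], [4])
        assert nw.overlapping_burst_connectivity(
            [b, b2]).graph.number_of_edges() == 0

    def test_matches_interval_tree_oracle(self):
        from intervaltree import IntervalTree
        rng = np.random.default_rng(6)
        for _ in range(50):
            sets = []
            for ch in range(4):
                starts = np.sort(rng.uniform(0, 30, rng.integers(1, 15)))
                ivals = [(s, s + rng.uniform(0.05, 0.5)) for s in starts]
                merged = []
                for s, e in ivals:
                    if merged and s <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                    else:
                        merged.append((s, e))
                sets.append(sp.BurstSet(f"c{ch}", merged,
                                        [4] * len(merged)))
            g = nw.overlapping_burst_connectivity(sets, 0.25)
            trees = {b.channel_id: IntervalTree.from_tuples(
                [(s, e + 1e-12) for s, e in b.intervals]) for b in sets}
            for i in range(4):
                for j in range(i + 1, 4):
                    bi, bj = sets[i], sets[j]
                    fi = np.mean([bool(trees[bj.channel_id].overlap(s, e + 1e-12))
                                  for s, e in bi.intervals])
                    fj = np.mean([bool(trees[bi.channel_id].overlap(s, e + 1e-12))
                                  for s, e in bj.intervals])
                    expect = max(fi, fj) > 0.25
                    assert g.graph.has_edge(bi.channel_id,
                                            bj.channel_id) == expect


class TestSpikingPercentage:
    def test_full_and_empty(self):
        dense = [_train(np.arange(0.05, 10, 0.05), f"c{i}") for i in range(3)]
        series, fs = nw.network_spiking_percentage(dense, 0, 10)
        assert fs == 10.0
        np.testing.assert_allclose(series, 1.0)
        silent = [_train([], f"c{i}") for i in range(3)]
        series, _ = nw.network_spiking_percentage(silent, 0, 10)
        np.testing.assert_allclose(series, 0.0)

    def test_simulator_events_make_peaks(self):
        cfg = sd.healthy_config(seed=30, tonic_rate_hz=0.3,
                                burst_rate_per_min=1.0)
        rec, gt = sd.simulate_recording(cfg)
        fb = pp.spike_band_filter(pp.savgol_smooth(rec), 300, 2250)
        trains = sp.detect_spikes(fb, baseline_window_s=30, refractory_ms=2)
        series, fs = nw.network_spiking_percentage(trains, 0, 60)
        for ev in gt.network_event_times:
            b = int(ev * fs)
            assert series[max(0, b - 1):b + 2].max() >= 0.8


class TestPeriodicity:
    def test_square_wave_period_recovered_by_both(self):
        t = np.arange(0, 60, 0.1)
        series = (np.sin(2 * np.pi * 0.2 * t) > 0).astype(float)
        for method in ("autocorrelation", "welch"):
            res = nw.periodicity(series, 10.0, method)
            assert res.period_s == pytest.approx(5.0, abs=0.1), method

    def test_constant_series_flagged_absent(self):
        res = nw.periodicity(np.full(600, 0.3), 10.0)
        assert res.period_s is None and res.degenerate

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            nw.periodicity(np.zeros(5), 10.0)

    def test_simulator_period_recovered(self):
        for seed in (40, 41):
            cfg = sd.healthy_config(seed=seed)
            rec, _ = sd.simulate_recording(cfg)
            fb = pp.spike_band_filter(pp.savgol_smooth(rec), 300, 2250)
            trains = sp.detect_spikes(fb, baseline_window_s=30,
                                      refractory_ms=2)
            series, fs = nw.network_spiking_percentage(trains, 0, 60)
            for method in ("autocorrelation", "welch"):
                res = nw.periodicity(series, fs, method)
                assert res.period_s == pytest.approx(5.0, abs=0.1)
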