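"""End-to-end analysis of one recording: raw trace -> tidy metric table.

Chains the stages in the order the analyses expect them: Savitzky-Golay
smoothing of the raw signal; spike-band filtering, spike/burst detection and
firing statistics; spike-correlation connectivity and network-event
periodicity inside a randomly placed one-minute window; LFP decimation to
1000 Hz followed by synchrosqueezed band power, LFP peak amplitude,
band-power connectivity and the phase-amplitude-coupling panel.

Per-channel metrics are emitted per channel; network-level quantities
(percent connected, weight, period) appear once per recording under
channel_id "ALL".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import network, oscillations, pac, preprocess, spikes
from .io import Recording
from .summary import OrganoidSummary, summarize

__all__ = ["analyze_recording", "ORGANOID_METRICS"]

ORGANOID_METRICS = [
    "spike_rate", "burst_rate", "isi_cv", "pct_connected", "weight",
    "period_s", "lfp_peak_amp",
    *[f"relpow_{b}" for b in oscillations.BAND_NAMES],
    "mi_delta_low_gamma", "mi_delta_upper_gamma",
    "mi_theta_low_gamma", "mi_theta_upper_gamma",
]


def analyze_recording(
    rec: Recording,
    recording_id: str,
    seed: int = 0,
    window_s: float | None = 60.0,
    sst_voices: int = 16,
    corr_threshold: float = 0.5,
) -> tuple[pd.DataFrame, OrganoidSummary]:
    """Run the full pipeline; returns (tidy metric table, organoid summary).

    ``window_s`` is the analysis window randomly placed in the recording
    (clipped to the recording length).  ``sst_voices`` controls the
    synchrosqueezing grid density used for band power.
    """
    rng = np.random.default_rng(seed)
    if window_s is None or window_s >= rec.duration_s:
        window = rec
    else:
        window = network.select_analysis_window(rec, window_s, rng)
    dur = window.duration_s
    t0, t1 = window.t0_s, window.t0_s + dur

    # --- spike stage
    smoothed = preprocess.savgol_smooth(window)
    high = min(2500.0, 0.45 * rec.fs_hz)  # clamp below Nyquist at reduced fs
    spike_band = preprocess.spike_band_filter(smoothed, 300.0, high)
    # 2 ms dead-time: the FIR band edges ring for ~2 ms around each
    # waveform, and multi-unit events closer than that are not separable
    trains = spikes.detect_spikes(spike_band,
                                  baseline_window_s=min(30.0, dur),
                                  refractory_ms=2.0)
    rows: list[dict] = []
    active_ids: list[str] = []
    active_trains = []
    for tr in trains:
        bursts = spikes.detect_bursts(tr)
        st = spikes.channel_stats(tr, bursts, dur)
        if st.active:
            active_ids.append(tr.channel_id)
            active_trains.append(tr)
        rows.extend([
            {"channel_id": tr.channel_id, "metric_name": "spike_rate",
             "value": st.spike_rate_hz},
            {"channel_id": tr.channel_id, "metric_name": "burst_rate",
             "value": st.burst_rate_per_min},
            {"channel_id": tr.channel_id, "metric_name": "isi_cv",
             "value": st.isi_cv},
        ])

    # --- network stage (active channels only)
    if len(active_trains) >= 2:
        corr, ids = network.spike_correlation_matrix(active_trains, t0, t1)
        graph = network.connectivity_graph(corr, ids, threshold=corr_threshold)
        rows.append({"channel_id": "ALL", "metric_name": "pct_connected",
                     "value": graph.percent_connected})
        rows.append({"channel_id": "ALL", "metric_name": "weight",
                     "value": graph.mean_weight})
    if active_trains:
        series, fs_series = network.network_spiking_percentage(
            active_trains, t0, t1)
        per = network.periodicity(series, fs_series, method="autocorrelation")
        if per.period_s is not None:
            rows.append({"channel_id": "ALL", "metric_name": "period_s",
                         "value": per.period_s})

    # --- LFP stage
    lfp = preprocess.lfp_downsample(smoothed)
    band_sigs = oscillations.sst_band_decompose(lfp, voices=sst_voices)
    bp = oscillations.relative_band_power(band_sigs, lfp.fs_hz,
                                          channel_ids=lfp.channel_ids)
    for b in oscillations.BAND_NAMES:
        for ch, cid in enumerate(lfp.channel_ids):
            rows.append({"channel_id": cid, "metric_name": f"relpow_{b}",
                         "value": float(bp.relative[b][ch])})
    peaks = oscillations.lfp_peak_amplitude(lfp)
    for ch, cid in enumerate(lfp.channel_ids):
        rows.append({"channel_id": cid, "metric_name": "lfp_peak_amp",
                     "value": float(peaks[ch])})
    pac_df = pac.pac_panel(lfp)
    for _, r in pac_df.iterrows():
        rows.append({"channel_id": r["channel_id"],
                     "metric_name": r["metric_name"],
                     "value": r["value"]})

    table = pd.DataFrame(rows)
    table.insert(0, "recording_id", recording_id)
    summary = summarize(table, active_ids, recording_id,
                        expected_metrics=ORGANOID_METRICS)
    return table, summary
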