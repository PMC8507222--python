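#!/usr/bin/env python
"""Narrow-band oscillatory power, LFP peaks, and band-power connectivity.

Decimates each recording to the 1000 Hz LFP, decomposes it into the six
canonical bands by the synchrosqueezed wavelet transform, and estimates
relative power by Welch (2 s window, 1 s overlap).  Band-power connectivity
uses 5 s windows with the median + 1 SD coefficient threshold.
"""

from pathlib import Path

import pandas as pd

from organoid_mea import io as oio
from organoid_mea import oscillations as osc
from organoid_mea import preprocess as pp

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"
RESULTS = ROOT / "results"


def main() -> None:
    rows, conn_rows = [], []
    paths = sorted(REC_DIR.glob("*.h5"))
    if not paths:
        raise SystemExit("no recordings found; run 01_simulate_cohorts.py")
    for path in paths:
        rid = path.stem
        rec = oio.read_recording(path)
        lfp = pp.lfp_downsample(pp.savgol_smooth(rec))
        sigs = osc.sst_band_decompose(lfp, voices=16)
        bp = osc.relative_band_power(sigs, lfp.fs_hz, lfp.channel_ids)
        peaks = osc.lfp_peak_amplitude(lfp)
        for ch, cid in enumerate(lfp.channel_ids):
            row = {"recording_id": rid, "channel_id": cid,
                   "lfp_peak_amp": float(peaks[ch])}
            for b in osc.BAND_NAMES:
                row[f"relpow_{b}"] = float(bp.relative[b][ch])
            rows.append(row)
        g, _ = osc.power_connectivity(lfp, "upper_gamma")
        conn_rows.append({
            "recording_id": rid, "band": "upper_gamma",
            "pct_connected": g.percent_connected,
            "weight": g.mean_weight,
            "threshold": g.threshold,
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "oscillation_metrics.csv", index=False)
    pd.DataFrame(conn_rows).to_csv(RESULTS / "power_connectivity.csv",
                                   index=False)
    print(df.groupby(df.recording_id.str[:-2])[
        [f"relpow_{b}" for b in osc.BAND_NAMES]].mean().round(3))


if __name__ == "__main__":
    main()
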