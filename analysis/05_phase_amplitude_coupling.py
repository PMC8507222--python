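#!/usr/bin/env python
"""Phase-amplitude coupling panel per channel.

KL modulation index (18 phase bins) of delta/theta phase against
lower/upper gamma amplitude on the 1000 Hz LFP.
"""

from pathlib import Path

import pandas as pd

from organoid_mea import io as oio
from organoid_mea import pac
from organoid_mea import preprocess as pp

ROOT = Path(__file__).resolve().parents[1]
REC_DIR = ROOT / "scratch" / "recordings"
RESULTS = ROOT / "results"


def main() -> None:
    frames = []
    paths = sorted(REC_DIR.glob("*.h5"))
    if not paths:
        raise SystemExit("no recordings found; run 01_simulate_cohorts.py")
    for path in paths:
        rid = path.stem
        rec = oio.read_recording(path)
        lfp = pp.lfp_downsample(pp.savgol_smooth(rec))
        panel = pac.pac_panel(lfp)
        panel.insert(0, "recording_id", rid)
        frames.append(panel)
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(RESULTS / "pac_metrics.csv", index=False)
    wide = df.pivot_table(index="recording_id", columns="metric_name",
                          values="value")
    print(wide.groupby(wide.index.str[:-2]).mean().round(4))


if __name__ == "__main__":
    main()
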