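#!/usr/bin/env python
"""Per-channel SNR and response latency on the demo checkerboard session,
compared against the planted values.

Requires 01_simulate_sessions.py.  Writes results/evoked_quality.csv.
"""
from pathlib import Path

import pandas as pd

from arrayqc.alignment import align_session
from arrayqc.io import read_session
from arrayqc.pipeline import PipelineConfig, snr_stage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    session, lut = read_session(ROOT / "scratch" / "sessions" / "snr")
    aligned, _ = align_session(session)
    summary = snr_stage(aligned, lut, PipelineConfig())
    planted = pd.read_csv(ROOT / "results" / "planted_ground_truth.csv")
    planted = planted[planted.session == "snr"][["global_id", "snr"]]
    merged = summary.merge(planted.rename(columns={"global_id": "channel",
                                                   "snr": "planted_snr"}),
                           on="channel")
    merged.to_csv(ROOT / "results" / "evoked_quality.csv", index=False)
    n_good = int(summary.good.sum())
    n_expected = int((planted.snr >= 2).sum())
    print(f"{n_good} good channels (SNR >= 2) of {len(summary)}; "
          f"planted split predicts {n_expected}")
    ok = merged[merged.planted_snr >= 2]
    print(f"median |SNR error| on responsive channels: "
          f"{(ok.snr - ok.planted_snr).abs().median():.2f}")


if __name__ == "__main__":
    main()
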