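#!/usr/bin/env python
"""Receptive-field estimates from the demo moving-bar session, with the
recovery error against the planted centres.

Requires 01_simulate_sessions.py.  Writes results/rf_map.csv.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from arrayqc.alignment import align_session
from arrayqc.io import read_session
from arrayqc.pipeline import PipelineConfig, rf_stage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    sess_dir = ROOT / "scratch" / "sessions" / "rf"
    session, lut = read_session(sess_dir)
    stimulus = json.loads((sess_dir / "stimulus.json").read_text())
    aligned, _ = align_session(session)
    rf_map = rf_stage(aligned, lut, PipelineConfig(), stimulus)

    planted = pd.read_csv(ROOT / "results" / "planted_ground_truth.csv")
    planted = planted[planted.session == "rf"].copy()
    planted["centre"] = planted.rf_centre.str.strip("()")
    cx = planted.centre.str.split(",", expand=True).astype(float)
    planted["planted_x"], planted["planted_y"] = cx[0], cx[1]
    merged = rf_map.merge(
        planted[["global_id", "planted_x", "planted_y"]].rename(
            columns={"global_id": "channel"}), on="channel")
    merged["centre_error_dva"] = np.hypot(merged.centre_x - merged.planted_x,
                                          merged.centre_y - merged.planted_y)
    merged.to_csv(ROOT / "results" / "rf_map.csv", index=False)
    print(f"mapped {len(rf_map)} / {len(planted)} channels; "
          f"max centre error {merged.centre_error_dva.max():.3f} dva, "
          f"median {merged.centre_error_dva.median():.3f} dva")


if __name__ == "__main__":
    main()
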