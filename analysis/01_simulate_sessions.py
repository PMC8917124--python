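#!/usr/bin/env python
"""Generate one small demo session of each kind (resting, checkerboard,
moving-bar) with planted ground truth.

Raw session directories are written under scratch/sessions/ (large, binary);
the planted per-channel properties go to results/planted_ground_truth.csv.
"""
from pathlib import Path

import json
import numpy as np
import pandas as pd

from arrayqc import build_lut
from arrayqc.io import write_session
from arrayqc.synthetic import (SessionSpec, SynchrofactGroup,
                               default_rf_centres, generate_session)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"

SPECS = {
    "resting": SessionSpec(
        task_kind="resting", duration=40.0, n_arrays=4, electrodes_per_array=8,
        seed=101, closure_schedule=((10.0, 22.0),),
        # the planted group spans both reference groups and is sparse within
        # each: cross-talk dense within one reference wire would be largely
        # absorbed by the PC-removal step
        synchrofact_groups=(SynchrofactGroup(members=(3, 4, 5, 19, 20, 21),
                                             rate_hz=1.0),)),
    "snr": SessionSpec(
        task_kind="snr", duration=60.0, n_arrays=2, electrodes_per_array=8,
        seed=102, per_channel_snr=np.repeat([0.5, 2.0, 4.0, 8.0], 4),
        per_channel_latency_ms=50.0),
    "rf": SessionSpec(
        task_kind="rf", duration=52.0, n_arrays=2, electrodes_per_array=8,
        seed=103, per_channel_snr=8.0,
        rf_centres=default_rf_centres(16, seed=103)),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, spec in SPECS.items():
        session, gt = generate_session(spec)
        out = SCRATCH / name
        write_session(session, out,
                      lut=build_lut(spec.n_arrays, spec.electrodes_per_array))
        stim = {"task_kind": spec.task_kind}
        if spec.task_kind == "rf":
            t0 = gt.trials.drop_duplicates("direction")
            stim.update(bar_speed=float(spec.bar_speed),
                        sweep_duration_s=float(gt.trials.sweep_duration.iloc[0]),
                        start_positions={r.direction: float(r.start_position)
                                         for r in t0.itertuples(index=False)})
        (out / "stimulus.json").write_text(json.dumps(stim, indent=1))
        for gid in range(1, spec.n_channels + 1):
            rows.append({"session": name, **gt.channel(gid)})
        print(f"{name}: {session.n_files} file(s), lengths {session.lengths()}, "
              f"{len(gt.events)} events -> {out}")
    pd.DataFrame(rows).to_csv(RESULTS / "planted_ground_truth.csv", index=False)
    print(f"planted ground truth for {len(rows)} channels -> "
          f"{RESULTS / 'planted_ground_truth.csv'}")


if __name__ == "__main__":
    main()
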