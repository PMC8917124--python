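"""Session-directory I/O.

A session directory holds one HDF5 raw file plus one CSV event file per NSP,
the channel LUT, and optional per-channel impedance metadata:

    nsp1_raw.h5 ... nspK_raw.h5     (datasets: signals; attrs: rate, labels)
    nsp1_events.csv ...             (columns: sample_index, code)
    lut.csv                         (seven LUT columns, header mandatory)
    impedance.csv                   (optional; passed through verbatim)

Derived signals are written one file per array, 64 channels each, with the
rate, filter provenance and global channel IDs stored as dataset attributes:
muae_array1.h5 ... / lfp_array1.h5 ...
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .channel_map import LUT, read_lut, write_lut
from .errors import ConfigurationError
from .session import DerivedSignal, EventStream, NSPFile, RawSessionSet


def write_events(stream: EventStream, path: str | Path) -> None:
    pd.DataFrame({"sample_index": stream.samples,
                  "code": stream.codes}).to_csv(path, index=False)


def read_events(path: str | Path) -> EventStream:
    df = pd.read_csv(path)
    return EventStream(df.sample_index.to_numpy(), df.code.to_numpy())


def write_session(session: RawSessionSet, directory: str | Path,
                  lut: LUT | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for f in session.files:
        with h5py.File(d / f"nsp{f.nsp_id}_raw.h5", "w") as h5:
            ds = h5.create_dataset("signals", data=f.signals.astype(np.float32))
            ds.attrs["rate_hz"] = f.rate
            ds.attrs["channel_labels"] = f.channel_labels
            ds.attrs["nsp_id"] = f.nsp_id
            ds.attrs["aligned"] = session.aligned
        write_events(f.events, d / f"nsp{f.nsp_id}_events.csv")
    if lut is not None:
        write_lut(lut, d / "lut.csv")
    return d


def read_session(directory: str | Path) -> tuple[RawSessionSet, LUT | None]:
    d = Path(directory)
    paths = sorted(d.glob("nsp*_raw.h5"),
                   key=lambda p: int(p.stem.split("_")[0][3:]))
    if not paths:
        raise ConfigurationError(f"no nsp*_raw.h5 files in {d}")
    files = []
    aligned = True
    for p in paths:
        nsp_id = int(p.stem.split("_")[0][3:])
        with h5py.File(p, "r") as h5:
            ds = h5["signals"]
            signals = ds[()]
            rate = float(ds.attrs["rate_hz"])
            labels = np.asarray(ds.attrs["channel_labels"])
            aligned = aligned and bool(ds.attrs.get("aligned", False))
        events = read_events(d / f"nsp{nsp_id}_events.csv")
        files.append(NSPFile(nsp_id=nsp_id, signals=signals,
                             channel_labels=labels, events=events, rate=rate))
    lut_path = d / "lut.csv"
    lut = read_lut(lut_path) if lut_path.exists() else None
    return RawSessionSet(files=files, rate=files[0].rate, aligned=aligned), lut


def write_derived(sig: DerivedSignal, array_id: int, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / f"{sig.kind.lower()}_array{array_id}.h5"
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("data", data=np.atleast_2d(sig.data)
                               .astype(np.float32))
        ds.attrs["kind"] = sig.kind
        ds.attrs["rate_hz"] = sig.rate
        if sig.channel_ids is not None:
            ds.attrs["channel_ids"] = np.asarray(sig.channel_ids)
        ds.attrs["provenance"] = json.dumps(sig.provenance)
    return path


def read_derived(path: str | Path) -> DerivedSignal:
    with h5py.File(path, "r") as h5:
        ds = h5["data"]
        return DerivedSignal(
            kind=str(ds.attrs["kind"]), rate=float(ds.attrs["rate_hz"]),
            data=ds[()],
            channel_ids=np.asarray(ds.attrs["channel_ids"])
            if "channel_ids" in ds.attrs else None,
            provenance=json.loads(ds.attrs["provenance"]))


def read_impedance(directory: str | Path) -> pd.DataFrame | None:
    p = Path(directory) / "impedance.csv"
    return pd.read_csv(p) if p.exists() else None
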