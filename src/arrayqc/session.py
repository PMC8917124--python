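"""In-memory containers for a multi-NSP recording session.

A session is acquired by several neural signal processors (NSPs), each writing
one raw file of up to 128 neural channels sampled at 30 kHz plus a digital
event stream.  NSP 1 additionally carries four analog eye channels (X/Y gaze
position on labels 129/130, X/Y pupil diameter on 131/132).  Before temporal
alignment the per-NSP files have unequal lengths because recording onset was
staggered across NSPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SignalError

RAW_RATE = 30_000.0
MUAE_RATE = 1_000.0
LFP_RATE = 500.0

#: eye-channel labels on NSP 1 (X pos, Y pos, X pupil, Y pupil)
EYE_LABELS = (129, 130, 131, 132)


@dataclass
class EventStream:
    """Digital event codes with their 30-kHz sample indices (0-based)."""

    samples: np.ndarray  # int64, strictly increasing
    codes: np.ndarray    # int, values 1-255

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.samples.shape != self.codes.shape:
            raise SignalError("samples and codes must have equal length")
        if self.samples.size > 1 and not np.all(np.diff(self.samples) > 0):
            raise SignalError("event sample indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.samples.size)

    def shifted(self, offset: int, length: int | None = None) -> "EventStream":
        """Return a copy with ``offset`` subtracted, cropped to [0, length)."""
        s = self.samples - int(offset)
        keep = s >= 0
        if length is not None:
            keep &= s < int(length)
        return EventStream(s[keep], self.codes[keep])


@dataclass
class NSPFile:
    """One NSP's signals: (n_channels, n_samples) plus its event stream."""

    nsp_id: int
    signals: np.ndarray            # float32 (n_channels, n_samples)
    channel_labels: np.ndarray     # within-NSP labels, 1-based
    events: EventStream
    rate: float = RAW_RATE

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        self.channel_labels = np.asarray(self.channel_labels, dtype=np.int64)
        if self.signals.shape[0] != self.channel_labels.size:
            raise SignalError(
                f"NSP {self.nsp_id}: {self.signals.shape[0]} rows but "
                f"{self.channel_labels.size} channel labels"
            )

    @property
    def n_samples(self) -> int:
        return int(self.signals.shape[1])

    def channel(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.channel_labels == label)
        if idx.size != 1:
            raise SignalError(f"NSP {self.nsp_id}: no unique channel label {label}")
        return self.signals[idx[0]]


@dataclass
class RawSessionSet:
    """All per-NSP files of one session, pre- or post-alignment."""

    files: list[NSPFile]
    rate: float = RAW_RATE
    aligned: bool = False

    @property
    def n_files(self) -> int:
        return len(self.files)

    def lengths(self) -> np.ndarray:
        return np.array([f.n_samples for f in self.files])

    def copy(self) -> "RawSessionSet":
        return RawSessionSet(
            files=[
                replace(f, signals=f.signals.copy(),
                        events=EventStream(f.events.samples.copy(),
                                           f.events.codes.copy()))
                for f in self.files
            ],
            rate=self.rate,
            aligned=self.aligned,
        )


@dataclass
class DerivedSignal:
    """A derived per-channel signal (MUAe at 1 kHz or LFP at 500 Hz)."""

    kind: str                     # "MUAe" | "LFP"
    rate: float
    data: np.ndarray              # (n_channels, n_samples) or (n_samples,)
    channel_ids: np.ndarray | None = None  # global channel IDs
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = {"MUAe": MUAE_RATE, "LFP": LFP_RATE}.get(self.kind)
        if expect is not None and self.rate != expect:
            raise SignalError(f"{self.kind} rate must be {expect} Hz, got {self.rate}")

    @property
    def n_samples(self) -> int:
        return int(np.atleast_2d(self.data).shape[1])
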