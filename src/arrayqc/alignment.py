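"""Temporal alignment of per-NSP files via the shared digital event stream.

All NSPs receive the same digital codes simultaneously, but each NSP starts
and stops recording at a slightly different time, so the same event sits at a
different sample index in each file.  Offsets are recovered by exact matching
of the (code, inter-event interval) sequence — codes are discrete and the
intervals are sample-exact in this acquisition design, so cross-correlation
is unnecessary — and the files are then trimmed to the common segment.

No clock-drift correction is performed: the NSP sample clocks are treated as
rate-locked, exactly one integer offset per file.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .errors import AlignmentError
from .session import EventStream, RawSessionSet

MIN_COMMON_EVENTS = 3


def _pairwise_shift(ref: EventStream, other: EventStream) -> int:
    """Sample offset d = start_other - start_ref from exact sequence matching.

    Searches every event-index lag of ``other`` against ``ref``; a lag is
    consistent when, over the whole overlap, the codes agree and the sample
    difference is one constant.  Exactly one consistent lag with at least
    MIN_COMMON_EVENTS overlapping events is required.
    """
    n, m = len(ref), len(other)
    if min(n, m) < MIN_COMMON_EVENTS:
        raise AlignmentError(
            f"need at least {MIN_COMMON_EVENTS} events per stream to align")
    solutions: list[int] = []
    for lag in range(-(m - MIN_COMMON_EVENTS), n - MIN_COMMON_EVENTS + 1):
        lo_r, lo_o = max(lag, 0), max(-lag, 0)
        count = min(n - lo_r, m - lo_o)
        if count < MIN_COMMON_EVENTS:
            continue
        rc = ref.codes[lo_r:lo_r + count]
        oc = other.codes[lo_o:lo_o + count]
        if not np.array_equal(rc, oc):
            continue
        diffs = ref.samples[lo_r:lo_r + count] - other.samples[lo_o:lo_o + count]
        if np.all(diffs == diffs[0]):
            solutions.append(int(diffs[0]))
    if not solutions:
        raise AlignmentError(
            "no consistent event correspondence between files "
            "(corrupt signals or unrelated sessions)")
    if len(set(solutions)) > 1:
        raise AlignmentError(
            f"ambiguous alignment: {len(set(solutions))} consistent offsets; "
            "event sequence too short or periodic")
    # ref sample - other sample is constant = start_other - start_ref
    return solutions[0]


def find_offsets(streams: list[EventStream]) -> np.ndarray:
    """Per-file start offsets in samples, relative to the latest-starting file.

    ``offsets[i]`` is the number of leading samples of file ``i`` that precede
    the latest-starting file's first sample; the latest starter gets 0.
    Trimming ``offsets[i]`` samples from the head of each file brings every
    common event to the same sample index in every file.
    """
    if len(streams) < 2:
        return np.zeros(len(streams), dtype=np.int64)
    # d[i] = start_i - start_0 (in master samples)
    d = np.array([0] + [_pairwise_shift(streams[0], s) for s in streams[1:]],
                 dtype=np.int64)
    offsets = d.max() - d
    return offsets


def trim_to_common(raw: RawSessionSet, offsets: np.ndarray) -> RawSessionSet:
    """Trim all files to the common aligned segment and drop non-signal channels.

    Channels above the documented range (labels > 132 on NSP 1, > 128 on the
    others) carry no data in this acquisition layout and are removed.
    """
    offsets = np.asarray(offsets, dtype=np.int64)
    if offsets.shape != (raw.n_files,):
        raise AlignmentError("one offset per file required")
    if (offsets < 0).any():
        raise AlignmentError("offsets must be nonnegative")
    usable = raw.lengths() - offsets
    length = int(usable.min())
    if length <= 0:
        raise AlignmentError("files share no common segment after offsets")

    files = []
    for f, off in zip(raw.files, offsets):
        limit = 132 if f.nsp_id == 1 else 128
        keep = f.channel_labels <= limit
        files.append(replace(
            f,
            signals=f.signals[keep, off:off + length],
            channel_labels=f.channel_labels[keep],
            events=f.events.shifted(int(off), length),
        ))
    return RawSessionSet(files=files, rate=raw.rate, aligned=True)


def align_session(raw: RawSessionSet) -> tuple[RawSessionSet, np.ndarray]:
    """Convenience wrapper: recover offsets from the event streams and trim."""
    offsets = find_offsets([f.events for f in raw.files])
    return trim_to_common(raw, offsets), offsets
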