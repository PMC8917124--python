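"""Pupil-based eye-state segmentation and its MUAe validation.

The X and Y pupil-diameter channels rest at a nonzero baseline, so each trace
is first corrected by subtracting its session minimum; the two corrected
traces are combined with the Euclidean norm.  The combined diameter is
down-sampled to 1 Hz by non-overlapping block means — which also averages
away sub-100-ms blinks — and thresholded: seconds below the threshold are
"closed", the rest "open".  Residual state segments shorter than the blink
bound inherit the surrounding state before segment statistics are computed.

The default threshold is scale-free: 10% of the 95th percentile of the 1-Hz
combined diameter.  Eye state is validated by the Pearson correlation between
the binary open indicator and the simultaneous array-mean MUAe.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SignalError
from .session import RAW_RATE

BLINK_MAX_S = 0.1  # state runs at or below this duration are blinks


def correct_and_combine(pupil_x: np.ndarray, pupil_y: np.ndarray) -> np.ndarray:
    """Subtract each trace's session minimum, then take the Euclidean norm."""
    x = np.asarray(pupil_x, dtype=float)
    y = np.asarray(pupil_y, dtype=float)
    if x.shape != y.shape:
        raise SignalError("pupil traces must have equal length")
    if x.size == 0:
        raise SignalError("empty pupil trace")
    xc = x - x.min()
    yc = y - y.min()
    return np.hypot(xc, yc)


def default_threshold(combined_1hz: np.ndarray, fraction: float = 0.10,
                      percentile: float = 95.0) -> float:
    """Scale-free closure threshold: ``fraction`` of the upper-percentile diameter."""
    return fraction * float(np.percentile(combined_1hz, percentile))


def block_average(x: np.ndarray, in_rate: float, out_rate: float = 1.0) -> np.ndarray:
    """Non-overlapping block means; trailing partial blocks are dropped."""
    block = int(round(in_rate / out_rate))
    n = x.size // block
    return np.asarray(x, dtype=float)[: n * block].reshape(n, block).mean(axis=1)


@dataclass
class EyeStateSeries:
    """1-Hz combined pupil diameter plus the open/closed segmentation."""

    rate: float
    combined_diameter: np.ndarray   # per 1-Hz bin, >= 0
    state: np.ndarray               # "open" / "closed" per bin
    segments: pd.DataFrame          # columns: state, start_s, duration_s
    threshold: float

    def open_fraction(self) -> float:
        return float(np.mean(self.state == "open"))

    def closed_seconds(self) -> float:
        closed = self.segments[self.segments.state == "closed"]
        return float(closed.duration_s.sum())

    def open_indicator(self) -> np.ndarray:
        return (self.state == "open").astype(float)


def _merge_blinks(closed: np.ndarray, max_blink_bins: int) -> np.ndarray:
    """Runs no longer than ``max_blink_bins`` inherit the surrounding state."""
    if closed.size == 0 or max_blink_bins <= 0:
        return closed
    out = closed.copy()
    n = out.size
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        run = j - i
        if run <= max_blink_bins and (i > 0 or j < n):
            # neighbouring state (prefer the preceding one)
            fill = out[i - 1] if i > 0 else out[j]
            out[i:j] = fill
        i = j
    return out


def _segments(state: np.ndarray, rate: float) -> pd.DataFrame:
    rows = []
    i = 0
    n = state.size
    while i < n:
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        rows.append({"state": "closed" if state[i] else "open",
                     "start_s": i / rate, "duration_s": (j - i) / rate})
        i = j
    return pd.DataFrame(rows, columns=["state", "start_s", "duration_s"])


def downsample_and_threshold(combined: np.ndarray, threshold: float | None = None,
                             in_rate: float = RAW_RATE, out_rate: float = 1.0,
                             blink_max_s: float = BLINK_MAX_S) -> EyeStateSeries:
    """Segment the session into eyes-open / eyes-closed epochs at 1 Hz."""
    diam = block_average(combined, in_rate, out_rate)
    if threshold is None:
        threshold = default_threshold(diam)
    if threshold <= 0:
        raise SignalError("closure threshold must be positive")
    closed = diam < threshold
    closed = _merge_blinks(closed, int(np.floor(blink_max_s * out_rate)))
    state = np.where(closed, "closed", "open")
    return EyeStateSeries(rate=out_rate, combined_diameter=diam, state=state,
                          segments=_segments(closed, out_rate),
                          threshold=float(threshold))


def correlate_state_with_muae(series: EyeStateSeries,
                              array_mean_muae_1hz: np.ndarray) -> float:
    """Pearson r between the open indicator (open = 1) and array-mean MUAe.

    Returns NaN when either series has zero variance (correlation undefined).
    """
    ind = series.open_indicator()
    mu = np.asarray(array_mean_muae_1hz, dtype=float)
    if ind.size != mu.size:
        raise SignalError("eye-state and MUAe series must have equal length")
    if ind.size < 3:
        raise SignalError("need at least 3 samples to correlate")
    if np.std(ind) == 0 or np.std(mu) == 0:
        return float("nan")
    r, _ = stats.pearsonr(ind, mu)
    return float(r)
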