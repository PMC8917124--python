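"""Receptive-field estimation from moving-bar responses.

For each sweep direction the trial-averaged 1-kHz MUAe is fitted with a
Gaussian ``offset + amplitude * exp(-(t - mu)^2 / (2 sigma^2))``.  Response
onset/offset times are ``mu -/+ 1.65 sigma``; mapping times to bar positions
along the motion axis turns each opposing direction pair into one spatial
boundary: e.g. the left RF boundary is the mean of the bar position at the
onset of the rightward sweep response and the position at the offset of the
leftward sweep response (this opposing-direction average cancels the
response latency).  The RF centre is the midpoint of the horizontal and
vertical boundaries, and the diameter is

    D = sqrt((r - l)^2 + (t - b)^2).

Coordinates: x positive rightward, y positive upward, fixation at the
origin.  The bar position refers to the centre of its leading edge.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, SignalError
from .session import MUAE_RATE

ONSET_SD_FACTOR = 1.65
AMPLITUDE_GATE_SD = 2.0   # fit accepted only if amplitude > gate x baseline SD
MIN_SIGMA_MS = 5.0        # narrower "responses" are single-bin noise spikes

HORIZONTAL = ("rightward", "leftward")
VERTICAL = ("upward", "downward")
OPPOSITE = {"rightward": "leftward", "leftward": "rightward",
            "upward": "downward", "downward": "upward"}
_SIGN = {"rightward": 1.0, "upward": 1.0, "leftward": -1.0, "downward": -1.0}


@dataclass(frozen=True)
class SweepGeometry:
    """Geometry of one bar-sweep condition."""
    direction: str              # rightward | upward | leftward | downward
    speed: float                # dva/s, > 0
    start_position: float       # dva along the motion axis at sweep onset
    sweep_onset_ms: float = 0.0
    bar_length: float = 4.0     # dva (metadata)
    bar_thickness: float = 0.04

    def __post_init__(self):
        if self.direction not in _SIGN:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.speed <= 0:
            raise ConfigurationError("bar speed must be positive")

    @property
    def sign(self) -> float:
        return _SIGN[self.direction]


@dataclass
class GaussianFit:
    mu_ms: float
    sigma_ms: float
    amplitude: float
    offset: float
    residual: float
    ok: bool
    reason: str = ""


@dataclass
class RFEstimate:
    """RF boundaries (dva), centre, and diameter for one channel."""
    channel: int
    left: float
    right: float
    bottom: float
    top: float
    centre: tuple[float, float]
    diameter: float
    partial: bool = False        # True when an opposing pair was missing
    fits: dict | None = None


def _gauss(t, offset, amplitude, mu, sigma):
    return offset + amplitude * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def fit_response_gaussian(trial_avg: np.ndarray, window_ms: tuple[float, float],
                          rate: float = MUAE_RATE,
                          baseline_sd: float | None = None,
                          amplitude_gate_sd: float = AMPLITUDE_GATE_SD,
                          min_sigma_ms: float = MIN_SIGMA_MS) -> GaussianFit:
    """Least-squares Gaussian fit to a trial-averaged MUAe trace.

    ``trial_avg`` covers ``window_ms`` (relative to sweep onset).  The fit is
    initialised at the trace argmax with sigma from the half-maximum width.
    Channels whose fitted amplitude does not exceed the noise gate, or whose
    fit fails to converge or lands outside the window, are marked unmappable.
    """
    y = np.asarray(trial_avg, dtype=float)
    if y.size < 8:
        raise SignalError("trace too short for a Gaussian fit")
    t = window_ms[0] + np.arange(y.size) * 1000.0 / rate
    if baseline_sd is None:
        # early samples double as a noise reference
        head = y[: max(int(0.1 * y.size), 4)]
        baseline_sd = float(head.std(ddof=1))

    off0 = float(np.percentile(y, 10))
    amp0 = float(y.max() - off0)
    if amp0 <= 0:
        return GaussianFit(math.nan, math.nan, 0.0, off0, math.nan, False,
                           "flat trace")
    mu0 = float(t[np.argmax(y)])
    above_half = y - off0 > amp0 / 2
    sigma0 = max(above_half.sum() * (1000.0 / rate) / 2.355, 2.0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, t, y, p0=[off0, amp0, mu0, sigma0],
            bounds=([-np.inf, 0.0, t[0], 1e-6],
                    [np.inf, np.inf, t[-1], (t[-1] - t[0])]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return GaussianFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                           False, f"no convergence: {exc}")
    offset, amplitude, mu, sigma = (float(v) for v in popt)
    residual = float(np.sqrt(np.mean((_gauss(t, *popt) - y) ** 2)))
    if amplitude <= amplitude_gate_sd * baseline_sd:
        return GaussianFit(mu, sigma, amplitude, offset, residual, False,
                           "amplitude below noise gate")
    if sigma < min_sigma_ms:
        return GaussianFit(mu, sigma, amplitude, offset, residual, False,
                           "implausibly narrow response")
    return GaussianFit(mu, sigma, amplitude, offset, residual, True)


def onset_offset_times(mu_ms: float, sigma_ms: float) -> tuple[float, float]:
    """Response onset/offset: the Gaussian midpoint -/+ 1.65 standard deviations."""
    if sigma_ms < 0:
        raise SignalError("sigma must be nonnegative")
    return mu_ms - ONSET_SD_FACTOR * sigma_ms, mu_ms + ONSET_SD_FACTOR * sigma_ms


def time_to_position(time_ms: float, geometry: SweepGeometry) -> float:
    """Bar position (dva along the motion axis) at ``time_ms``."""
    if time_ms < geometry.sweep_onset_ms:
        raise SignalError(
            f"time {time_ms} ms precedes sweep onset {geometry.sweep_onset_ms} ms")
    dt = (time_ms - geometry.sweep_onset_ms) / 1000.0
    return geometry.start_position + geometry.sign * geometry.speed * dt


def _boundary(fit_fwd: GaussianFit, geom_fwd: SweepGeometry,
              fit_bwd: GaussianFit, geom_bwd: SweepGeometry) -> tuple[float, float]:
    """(near, far) boundaries along one axis from an opposing direction pair.

    ``fwd`` moves toward positive axis values.  The near (lower-coordinate)
    boundary averages the forward response onset with the backward response
    offset; the far boundary the converse.
    """
    on_f, off_f = onset_offset_times(fit_fwd.mu_ms, fit_fwd.sigma_ms)
    on_b, off_b = onset_offset_times(fit_bwd.mu_ms, fit_bwd.sigma_ms)
    near = 0.5 * (time_to_position(on_f, geom_fwd) + time_to_position(off_b, geom_bwd))
    far = 0.5 * (time_to_position(off_f, geom_fwd) + time_to_position(on_b, geom_bwd))
    return near, far


def estimate_rf(fits: dict[str, GaussianFit], geometries: dict[str, SweepGeometry],
                channel: int = 0) -> RFEstimate | None:
    """Combine per-direction fits into one RF estimate.

    Requires both horizontal directions for the left/right boundaries and
    both vertical ones for bottom/top; with only one usable axis a partial
    estimate is returned (the missing axis is NaN), and with none, None.
    """
    def usable(direction: str) -> bool:
        f = fits.get(direction)
        return f is not None and f.ok

    have_h = all(usable(d) for d in HORIZONTAL)
    have_v = all(usable(d) for d in VERTICAL)
    if not (have_h or have_v):
        return None

    left = right = bottom = top = math.nan
    if have_h:
        left, right = _boundary(fits["rightward"], geometries["rightward"],
                                fits["leftward"], geometries["leftward"])
    if have_v:
        bottom, top = _boundary(fits["upward"], geometries["upward"],
                                fits["downward"], geometries["downward"])
    centre = (0.5 * (left + right), 0.5 * (bottom + top))
    diameter = math.hypot(right - left, top - bottom)
    return RFEstimate(channel=channel, left=left, right=right, bottom=bottom,
                      top=top, centre=centre, diameter=diameter,
                      partial=not (have_h and have_v), fits=fits)


def merge_maps(thin_map: dict[int, RFEstimate], thick_map: dict[int, RFEstimate],
               assignment: dict[int, str]) -> tuple[dict[int, RFEstimate], list[int]]:
    """Unified RF map: each channel keeps only its assigned stimulus set.

    ``assignment`` maps channel -> "thin" | "thick".  Channels assigned to a
    set where they are unmappable are returned in the missing list.
    """
    sources = {"thin": thin_map, "thick": thick_map}
    merged: dict[int, RFEstimate] = {}
    missing: list[int] = []
    for channel, which in assignment.items():
        if which not in sources:
            raise ConfigurationError(f"channel {channel}: unknown stimulus {which!r}")
        est = sources[which].get(channel)
        if est is None:
            missing.append(channel)
        else:
            merged[channel] = est
    return merged, missing


def rf_map_frame(estimates: dict[int, RFEstimate]) -> pd.DataFrame:
    rows = [{
        "channel": e.channel, "left": e.left, "right": e.right,
        "bottom": e.bottom, "top": e.top,
        "centre_x": e.centre[0], "centre_y": e.centre[1],
        "diameter": e.diameter, "partial": e.partial,
    } for e in estimates.values()]
    return pd.DataFrame(rows).sort_values("channel").reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["channel", "left", "right", "bottom",
                                           "top", "centre_x", "centre_y",
                                           "diameter", "partial"])
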