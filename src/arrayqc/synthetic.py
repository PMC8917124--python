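"""Synthetic multi-NSP sessions with planted ground truth.

Every property the downstream pipeline estimates is planted here explicitly
so recovery can be checked against a known answer: per-channel SNR and
response latency for the checkerboard task, receptive-field centres and sizes
for the sweeping-bar task, an eye-closure schedule for resting state, per-NSP
start/stop trims for the alignment stage, and synchronous-artifact groups for
cross-talk detection.

Signal model
------------
Each neural channel is white Gaussian background noise plus a Poisson train
of biphasic ~1-ms spike waveforms (amplitude a fixed multiple of the noise
SD), which exercises both the MUAe pathway and threshold-crossing extraction
without modelling real cortex.  Stimulus-evoked responses are an
amplitude-modulated 3-kHz carrier: the modulation envelope carries the
planted latency/timing and the carrier lies inside the MUAe band, so the
MUAe stage demodulates it.  The evoked amplitude is calibrated so that the
evoked-metrics SNR definition, applied to the expected traces, equals the
planted SNR (see ``_solve_amplitude``); the realized SNR of any one session
remains stochastic.

Setting ``noise_sd = 0`` silences both the noise and the background spikes
(whose amplitude scales with the noise SD), leaving a fully deterministic
evoked signal: trial traces are then bit-identical across trials.

Units are arbitrary "volts" throughout; only ratios matter to the pipeline.
Eye traces use a documented scale: pupil channels rest at a nonzero baseline
offset (exercising the minimum-subtraction correction) and drop toward zero
during scheduled closures and during brief random blinks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps, special

from .channel_map import LUT, build_lut
from .errors import ConfigurationError
from .session import EYE_LABELS, EventStream, NSPFile, RAW_RATE, RawSessionSet
from .signals import FILTER_ORDER, MUAE_BAND, compute_muae, _sos_bandpass

DIRECTIONS = ("rightward", "upward", "leftward", "downward")
#: digital event codes: single active bit N -> decimal code 2**N
CODE_SYNC_MAX = 8          # resting-state sync codes are uniform in 1..8
CODE_STIM_ON = 2           # bit 1
CODE_STIM_OFF = 4          # bit 2 (checkerboard task); doubles as reward in RF task
CODE_REWARD = 8            # bit 3 (checkerboard task)
CODE_RF_REWARD = 4
DIRECTION_CODES = {"rightward": 8, "upward": 16, "leftward": 32, "downward": 64}

_CALIBRATION_SEED = 0x5EED_CA1  # internal, independent of any session seed


@dataclass(frozen=True)
class SynchrofactGroup:
    """A set of electrodes receiving identical, simultaneous artifact spikes."""
    members: tuple[int, ...]
    rate_hz: float = 1.0


@dataclass
class SessionSpec:
    """Full description of a synthetic session; the seed determines all output."""

    task_kind: str                       # "resting" | "snr" | "rf"
    duration: float                      # seconds
    raw_rate: float = RAW_RATE
    n_arrays: int = 16
    electrodes_per_array: int = 64
    seed: int = 0

    # background signal model
    noise_sd: float = 1.0
    background_rate_hz: float = 3.0      # Poisson spike trains per channel
    spike_amp_factor: float = 8.0        # spike peak, in units of noise_sd
    # shared broadband noise within each reference-wire group (x noise_sd):
    # the common-mode signal that the synchrofact stage's PC removal strips
    common_reference_sd: float = 1.0
    # evoked carrier: inside the MUAe band and incommensurate with the 30-kHz
    # sample grid (200 distinct phases), so rectified means match the
    # continuous-phase average
    carrier_hz: float = 3150.0

    # evoked structure (snr / rf tasks)
    per_channel_snr: float | np.ndarray | None = None
    per_channel_latency_ms: float | np.ndarray = 50.0
    evoked_amplitude: float | np.ndarray | None = None  # used when noise_sd == 0
    rf_centres: np.ndarray | None = None  # (n_channels, 2) dva
    rf_sizes: float | np.ndarray = 1.0    # dva
    bar_speed: float = 4.0                # dva/s (thin-bar default)
    bar_length: float = 4.0               # dva, metadata
    bar_thickness: float = 0.04           # dva, metadata

    # trial timing (seconds)
    snr_trial_period: float = 1.4
    snr_pre_onset: float = 0.4
    snr_stim_duration: float = 0.4
    rf_trial_period: float = 1.6
    rf_fixation_lead: float = 0.2

    # resting-state / eye structure
    closure_schedule: tuple[tuple[float, float], ...] = ()
    blink_rate_hz: float = 0.2
    pupil_baseline: tuple[float, float] = (1.2, 0.9)  # volts, X / Y channels
    pupil_scale: float = 1.0                          # open-pupil amplitude, volts
    eye_open_boost: float = 0.5  # extra in-band amplitude (x noise_sd) when open

    # artifacts / acquisition plumbing
    synchrofact_groups: tuple[SynchrofactGroup, ...] = ()
    nsp_offsets: np.ndarray | None = None  # (n_files, 2) start/stop trims, samples
    max_random_offset: float = 0.5         # s; used when nsp_offsets is None

    # ---------------------------------------------------------------
    @property
    def n_files(self) -> int:
        return self.n_arrays // 2

    @property
    def n_channels(self) -> int:
        return self.n_arrays * self.electrodes_per_array

    @property
    def n_master(self) -> int:
        return int(round(self.duration * self.raw_rate))

    def validate(self) -> None:
        if self.task_kind not in ("resting", "snr", "rf"):
            raise ConfigurationError(f"unknown task_kind {self.task_kind!r}")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.raw_rate <= 0 or self.carrier_hz <= 0:
            raise ConfigurationError("all rates must be positive")
        if self.n_arrays % 2:
            raise ConfigurationError("n_arrays must be even (two per NSP)")
        if self.task_kind == "rf":
            if self.rf_centres is None:
                raise ConfigurationError("rf task requires rf_centres")
            if np.asarray(self.rf_centres).shape != (self.n_channels, 2):
                raise ConfigurationError(
                    f"rf_centres must have shape ({self.n_channels}, 2)")
            if self.bar_speed <= 0:
                raise ConfigurationError("bar speed must be positive")
        if self.noise_sd == 0 and self.task_kind in ("snr", "rf") \
                and self.evoked_amplitude is None:
            raise ConfigurationError(
                "noise_sd=0 requires an explicit evoked_amplitude (SNR is undefined)")
        sched = sorted(self.closure_schedule)
        for (s0, e0), (s1, _) in zip(sched, sched[1:]):
            if s1 < e0:
                raise ConfigurationError("overlapping closure intervals")
        for s, e in sched:
            if not (0 <= s < e <= self.duration):
                raise ConfigurationError("closure interval outside [0, duration]")
        for g in self.synchrofact_groups:
            bad = [m for m in g.members if not (1 <= m <= self.n_channels)]
            if bad:
                raise ConfigurationError(f"synchrofact members {bad} out of range")
        if self.nsp_offsets is not None:
            off = np.asarray(self.nsp_offsets)
            if off.shape != (self.n_files, 2):
                raise ConfigurationError(
                    f"nsp_offsets must have shape ({self.n_files}, 2)")
            if (off < 0).any():
                raise ConfigurationError("nsp offsets must be nonnegative")

    def lut(self) -> LUT:
        return build_lut(self.n_arrays, self.electrodes_per_array)


def default_rf_centres(n_channels: int, seed: int = 0,
                       x_range=(0.5, 2.5), y_range=(-2.5, -0.5)) -> np.ndarray:
    """Planted RF centres in the lower-right quadrant (x > 0, y < 0)."""
    rng = np.random.default_rng([seed, 0x4F])
    x = rng.uniform(*x_range, size=n_channels)
    y = rng.uniform(*y_range, size=n_channels)
    return np.column_stack([x, y])


@dataclass
class EyeSignals:
    """Four 30-kHz analog eye traces as recorded on NSP 1 channels 129-132."""
    x_pos: np.ndarray
    y_pos: np.ndarray
    pupil_x: np.ndarray
    pupil_y: np.ndarray
    rate: float = RAW_RATE

    def stacked(self) -> np.ndarray:
        return np.vstack([self.x_pos, self.y_pos, self.pupil_x, self.pupil_y])


@dataclass
class GroundTruth:
    """Every planted quantity, retrievable by global channel ID (1-based)."""
    spec: SessionSpec
    events: EventStream                  # master-timeline samples
    trials: pd.DataFrame                 # per-trial timing (and geometry for rf)
    snr: np.ndarray                      # (n_channels,) planted SNR (nan if n/a)
    latency_ms: np.ndarray
    amplitude: np.ndarray                # calibrated evoked plateau amplitude
    rf_centres: np.ndarray | None
    rf_sizes: np.ndarray | None
    closure_schedule: tuple[tuple[float, float], ...]
    blink_intervals: np.ndarray          # (n_blinks, 2) seconds
    synchrofact_times: list[np.ndarray]  # master samples, one array per group
    nsp_offsets: np.ndarray              # (n_files, 2) start/stop trims, samples
    baseline_muae_mean: float            # expected spontaneous MUAe level
    baseline_muae_sd: float              # expected per-trial baseline MUAe SD

    def channel(self, global_id: int) -> dict:
        i = int(global_id) - 1
        out = {"global_id": int(global_id), "snr": float(self.snr[i]),
               "latency_ms": float(self.latency_ms[i]),
               "amplitude": float(self.amplitude[i])}
        if self.rf_centres is not None:
            out["rf_centre"] = (float(self.rf_centres[i, 0]),
                                float(self.rf_centres[i, 1]))
            out["rf_size"] = float(self.rf_sizes[i])
        return out

    def synchrofact_counts(self) -> list[int]:
        return [len(t) for t in self.synchrofact_times]


# ----------------------------------------------------------------------
# MUAe calibration: map planted SNR -> carrier amplitude
# ----------------------------------------------------------------------

@lru_cache(maxsize=8)
def _baseline_calibration(background_rate_hz: float, spike_amp_factor: float,
                          raw_rate: float, common_reference_sd: float = 0.0,
                          window_ms: float = 300.0,
                          calib_seconds: float = 30.0) -> tuple[float, float]:
    """Expected spontaneous MUAe mean and per-window SD for unit noise SD.

    Simulates the exact background model (channel noise plus the shared
    reference-wire noise plus Poisson biphasic spikes) at sigma = 1 with a
    fixed internal seed, runs the MUAe stage, and averages the mean and SD
    over non-overlapping 300-ms windows.  By positive homogeneity of the
    MUAe pathway both constants scale linearly with the noise SD.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = int(calib_seconds * raw_rate)
    x = rng.normal(0.0, math.sqrt(1.0 + common_reference_sd ** 2), n)
    n_spk = rng.poisson(background_rate_hz * calib_seconds)
    t_spk = rng.integers(0, n - 64, size=n_spk)
    _add_waveform(x, t_spk, spike_amp_factor * _spike_waveform(raw_rate))
    mu = compute_muae(x, fs=raw_rate).data
    w = int(window_ms)  # MUAe bins are 1 ms
    # skip edge-affected first/last 50 ms
    mu = mu[50:mu.size - 50]
    n_win = mu.size // w
    wins = mu[: n_win * w].reshape(n_win, w)
    return float(wins.mean(axis=1).mean()), float(wins.std(axis=1, ddof=1).mean())


@lru_cache(maxsize=8)
def _carrier_gain(carrier_hz: float, raw_rate: float) -> float:
    """Amplitude gain of the zero-phase MUAe band-pass at the carrier."""
    sos = _sos_bandpass(*MUAE_BAND, raw_rate, FILTER_ORDER)
    _, h = sps.sosfreqz(sos, worN=[carrier_hz], fs=raw_rate)
    return float(np.abs(h[0]) ** 2)  # forward-backward pass: |H|^2


def _rectified_mean(m: np.ndarray, sigma: float) -> np.ndarray:
    """E|X| for X ~ N(m, sigma^2)."""
    if sigma == 0:
        return np.abs(m)
    z = m / sigma
    return sigma * math.sqrt(2 / math.pi) * np.exp(-0.5 * z * z) \
        + m * special.erf(z / math.sqrt(2))


def _plateau_muae(amplitude: float, sigma_eff: float) -> float:
    """Expected MUAe level with a carrier of the given amplitude present.

    The 200-Hz low-pass averages |carrier + noise| over many carrier cycles,
    so the level is E|N(A sin theta, sigma^2)| averaged over phase theta.
    """
    theta = (np.arange(256) + 0.5) * (2 * np.pi / 256)
    return float(_rectified_mean(amplitude * np.sin(theta), sigma_eff).mean())


def _solve_amplitude(snr: float, noise_sd: float, base_mean: float,
                     base_sd: float, gain: float) -> float:
    """Carrier amplitude whose expected MUAe plateau realises the planted SNR."""
    if snr <= 0:
        return 0.0
    target = base_mean + snr * base_sd
    sigma_eff = base_mean / math.sqrt(2 / math.pi)  # Gaussian-equivalent floor
    hi = (target * math.pi / 2 + 5 * sigma_eff) / gain + 1e-9
    f = lambda a: _plateau_muae(a * gain, sigma_eff) - target
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


# ----------------------------------------------------------------------
# waveforms and event helpers
# ----------------------------------------------------------------------

@lru_cache(maxsize=4)
def _spike_waveform(raw_rate: float) -> np.ndarray:
    """Biphasic ~1-ms extracellular spike, negative peak normalised to -1."""
    t = np.arange(int(0.0015 * raw_rate)) / raw_rate * 1e3  # ms
    w = -np.exp(-0.5 * ((t - 0.30) / 0.10) ** 2) \
        + 0.45 * np.exp(-0.5 * ((t - 0.70) / 0.17) ** 2)
    return w / np.abs(w.min())


def _add_waveform(x: np.ndarray, at: np.ndarray, w: np.ndarray) -> None:
    n, k = x.size, w.size
    for t in np.asarray(at, dtype=np.int64):
        stop = min(t + k, n)
        if 0 <= t < n:
            x[t:stop] += w[: stop - t]


def generate_event_stream(spec: SessionSpec) -> EventStream:
    """The shared digital event stream on the master (untrimmed) timeline."""
    spec.validate()
    fs = spec.raw_rate
    rng = np.random.default_rng([spec.seed, 1])
    if spec.task_kind == "resting":
        # one random sync code per second
        k = np.arange(int(spec.duration))
        samples = np.round((k + 0.5) * fs).astype(np.int64)
        codes = rng.integers(1, CODE_SYNC_MAX + 1, size=k.size)
        return EventStream(samples, codes)

    trials = generate_trial_table(spec)
    samples, codes = [], []
    for t in trials.itertuples(index=False):
        if spec.task_kind == "snr":
            samples += [t.onset_sample, t.offset_sample,
                        t.offset_sample + int(0.05 * fs)]
            codes += [CODE_STIM_ON, CODE_STIM_OFF, CODE_REWARD]
        else:
            samples += [t.onset_sample, t.onset_sample + int(0.02 * fs),
                        t.offset_sample + int(0.05 * fs)]
            codes += [CODE_STIM_ON, DIRECTION_CODES[t.direction], CODE_RF_REWARD]
    return EventStream(np.array(samples), np.array(codes))


def generate_trial_table(spec: SessionSpec) -> pd.DataFrame:
    """Per-trial timing (master samples); RF trials carry sweep geometry."""
    fs = spec.raw_rate
    if spec.task_kind == "snr":
        period = spec.snr_trial_period
        n_trials = int(spec.duration // period)
        start = np.arange(n_trials) * period
        onset = np.round((start + spec.snr_pre_onset) * fs).astype(np.int64)
        offset = onset + int(round(spec.snr_stim_duration * fs))
        return pd.DataFrame({
            "trial": np.arange(n_trials), "start_sample":
                np.round(start * fs).astype(np.int64),
            "onset_sample": onset, "offset_sample": offset,
        })
    if spec.task_kind == "rf":
        return generate_bar_trials(spec)
    raise ConfigurationError(f"no trials for task {spec.task_kind!r}")


def _sweep_ranges(spec: SessionSpec, pad: float = 1.0):
    c = np.asarray(spec.rf_centres, dtype=float)
    x_lo, x_hi = c[:, 0].min() - pad, c[:, 0].max() + pad
    y_lo, y_hi = c[:, 1].min() - pad, c[:, 1].max() + pad
    return (x_lo, x_hi), (y_lo, y_hi)


def generate_bar_trials(spec: SessionSpec) -> pd.DataFrame:
    """Trials for the four sweep directions, cycling rightward/upward/leftward/downward.

    The sweep span covers the planted RF region plus a 1-dva pad on each side;
    with the default centres this is 4 dva, i.e. a 1-s sweep at the thin-bar
    speed of 4 dva/s.  The reported bar position is the centre of its leading
    edge.
    """
    spec.validate()
    if spec.rf_centres is None:
        raise ConfigurationError("rf_centres must be planted for bar trials")
    if spec.bar_speed <= 0:
        raise ConfigurationError("bar speed must be positive")
    fs = spec.raw_rate
    (x_lo, x_hi), (y_lo, y_hi) = _sweep_ranges(spec)
    span = max(x_hi - x_lo, y_hi - y_lo)
    sweep_dur = span / spec.bar_speed
    period = max(spec.rf_trial_period, spec.rf_fixation_lead + sweep_dur + 0.4)
    n_trials = int(spec.duration // period)
    start_pos = {"rightward": x_lo, "leftward": x_hi,
                 "upward": y_lo, "downward": y_hi}
    sign = {"rightward": 1.0, "upward": 1.0, "leftward": -1.0, "downward": -1.0}
    rows = []
    for k in range(n_trials):
        d = DIRECTIONS[k % 4]
        t0 = k * period
        onset = int(round((t0 + spec.rf_fixation_lead) * fs))
        rows.append({
            "trial": k, "direction": d,
            "start_sample": int(round(t0 * fs)),
            "onset_sample": onset,
            "offset_sample": onset + int(round(sweep_dur * fs)),
            "speed": spec.bar_speed, "start_position": start_pos[d],
            "sign": sign[d], "sweep_duration": sweep_dur,
            "bar_length": spec.bar_length, "bar_thickness": spec.bar_thickness,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# eye signals
# ----------------------------------------------------------------------

def _smooth_wander(rng: np.random.Generator, n: int, fs: float,
                   knot_hz: float = 1.0, sd: float = 1.0) -> np.ndarray:
    """Slow random wander: linear interpolation of 1-Hz Gaussian knots."""
    n_knots = max(int(n / fs * knot_hz) + 2, 2)
    knots = rng.normal(0.0, sd, n_knots)
    t = np.arange(n) / fs * knot_hz
    return np.interp(t, np.arange(n_knots), knots)


def _closure_envelope(spec: SessionSpec, rng: np.random.Generator,
                      n: int) -> tuple[np.ndarray, np.ndarray]:
    """(envelope in [0,1], blink intervals).  0 means eyes fully closed."""
    fs = spec.raw_rate
    env = np.ones(n)
    ramp = int(0.15 * fs)
    half = np.linspace(1.0, 0.0, ramp)

    def close(i0: int, i1: int) -> None:
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            return
        env[i0:i1] = 0.0
        if i0 - ramp >= 0:
            env[i0 - ramp:i0] = np.minimum(env[i0 - ramp:i0], half)
        if i1 + ramp <= n:
            env[i1:i1 + ramp] = np.minimum(env[i1:i1 + ramp], half[::-1])

    for s, e in spec.closure_schedule:
        close(int(s * fs), int(e * fs))
    blinks = []
    if spec.blink_rate_hz > 0:
        n_blinks = rng.poisson(spec.blink_rate_hz * spec.duration)
        for t0 in np.sort(rng.uniform(0, spec.duration, n_blinks)):
            dur = rng.uniform(0.03, 0.08)  # < 100 ms: a blink, not a closure
            close(int(t0 * fs), int((t0 + dur) * fs))
            blinks.append((t0, t0 + dur))
    return env, np.array(blinks).reshape(-1, 2)


def generate_eye_signals(spec: SessionSpec) -> tuple[EyeSignals, np.ndarray]:
    """Four 30-kHz eye traces plus the realized blink intervals (seconds)."""
    spec.validate()
    n = spec.n_master
    rng = np.random.default_rng([spec.seed, 2])
    env, blinks = _closure_envelope(spec, rng, n)
    bx, by = spec.pupil_baseline
    open_diam = spec.pupil_scale * (1.0 + 0.05 * _smooth_wander(rng, n, spec.raw_rate))
    pupil_x = bx + env * open_diam + rng.normal(0, 0.004, n)
    pupil_y = by + env * 0.9 * open_diam + rng.normal(0, 0.004, n)
    x_pos = 0.3 * _smooth_wander(rng, n, spec.raw_rate) + rng.normal(0, 0.01, n)
    y_pos = 0.3 * _smooth_wander(rng, n, spec.raw_rate) + rng.normal(0, 0.01, n)
    return EyeSignals(x_pos, y_pos, pupil_x, pupil_y, spec.raw_rate), blinks


# ----------------------------------------------------------------------
# per-channel traces and full sessions
# ----------------------------------------------------------------------

def _per_channel(value, n: int, default=np.nan) -> np.ndarray:
    if value is None:
        return np.full(n, default, dtype=float)
    arr = np.asarray(value, dtype=float)
    return np.full(n, float(arr)) if arr.ndim == 0 else arr.copy()


def generate_ground_truth(spec: SessionSpec) -> GroundTruth:
    """Planted quantities shared by all channels; deterministic in the seed."""
    spec.validate()
    nch = spec.n_channels
    rng = np.random.default_rng([spec.seed, 3])

    snr = _per_channel(spec.per_channel_snr, nch)
    latency = _per_channel(spec.per_channel_latency_ms, nch, default=50.0)
    if spec.noise_sd > 0:
        base_mean_u, base_sd_u = _baseline_calibration(
            spec.background_rate_hz, spec.spike_amp_factor, spec.raw_rate,
            spec.common_reference_sd)
        base_mean = base_mean_u * spec.noise_sd
        base_sd = base_sd_u * spec.noise_sd
    else:
        base_mean = base_sd = 0.0

    if spec.evoked_amplitude is not None:
        amplitude = _per_channel(spec.evoked_amplitude, nch)
    elif spec.task_kind in ("snr", "rf") and np.isfinite(snr).any():
        gain = _carrier_gain(spec.carrier_hz, spec.raw_rate)
        amp_of = {s: _solve_amplitude(s, spec.noise_sd, base_mean, base_sd, gain)
                  for s in np.unique(snr[np.isfinite(snr)])}
        amplitude = np.array([amp_of.get(s, 0.0) if np.isfinite(s) else 0.0
                              for s in snr])
    else:
        amplitude = np.zeros(nch)

    events = generate_event_stream(spec)
    if spec.task_kind in ("snr", "rf"):
        trials = generate_trial_table(spec)
    else:
        trials = pd.DataFrame()

    _, blinks = generate_eye_signals(spec) if spec.task_kind == "resting" \
        else (None, np.empty((0, 2)))

    sf_times = []
    for gi, g in enumerate(spec.synchrofact_groups):
        g_rng = np.random.default_rng([spec.seed, 4, gi])
        n_ev = g_rng.poisson(g.rate_hz * spec.duration)
        t = np.sort(g_rng.integers(0, spec.n_master - 64, size=n_ev))
        # enforce a 2-ms separation so each insertion is one distinct event
        if t.size > 1:
            keep = np.concatenate([[True], np.diff(t) > 60])
            t = t[keep]
        sf_times.append(t)

    if spec.nsp_offsets is not None:
        offsets = np.asarray(spec.nsp_offsets, dtype=np.int64)
    else:
        max_off = int(spec.max_random_offset * spec.raw_rate)
        offsets = rng.integers(0, max_off + 1, size=(spec.n_files, 2))

    rf_sizes = _per_channel(spec.rf_sizes, nch) if spec.rf_centres is not None else None
    return GroundTruth(
        spec=spec, events=events, trials=trials, snr=snr, latency_ms=latency,
        amplitude=amplitude,
        rf_centres=None if spec.rf_centres is None
        else np.asarray(spec.rf_centres, dtype=float),
        rf_sizes=rf_sizes,
        closure_schedule=tuple(spec.closure_schedule), blink_intervals=blinks,
        synchrofact_times=sf_times, nsp_offsets=offsets,
        baseline_muae_mean=base_mean, baseline_muae_sd=base_sd,
    )


def _open_indicator(spec: SessionSpec, n: int) -> np.ndarray:
    ind = np.ones(n)
    fs = spec.raw_rate
    for s, e in spec.closure_schedule:
        ind[int(s * fs):int(e * fs)] = 0.0
    return ind


def evoked_envelope(spec: SessionSpec, gt: GroundTruth, global_id: int) -> np.ndarray:
    """The planted evoked modulation envelope on the master timeline."""
    n = spec.n_master
    fs = spec.raw_rate
    i = int(global_id) - 1
    env = np.zeros(n)
    amp = gt.amplitude[i]
    if spec.task_kind == "resting":
        # resting activity is modulated per channel (see channel_trace), not
        # through a stimulus-locked carrier
        return env
    if amp == 0 or gt.trials.empty:
        return env
    if spec.task_kind == "snr":
        lat = int(round(gt.latency_ms[i] * fs / 1000.0))
        for t in gt.trials.itertuples(index=False):
            env[t.onset_sample + lat:t.offset_sample] = amp
        return env
    # rf: Gaussian bump when the bar crosses the planted centre, delayed by latency
    x_c, y_c = gt.rf_centres[i]
    sigma_t = gt.rf_sizes[i] / (2 * 1.65 * math.sqrt(2) * spec.bar_speed)  # s
    lat_s = gt.latency_ms[i] / 1000.0
    t_axis = np.arange(n) / fs
    for t in gt.trials.itertuples(index=False):
        coord = x_c if t.direction in ("rightward", "leftward") else y_c
        t_cross = t.onset_sample / fs + (coord - t.start_position) / (t.sign * t.speed)
        t_peak = t_cross + lat_s
        lo = max(int((t_peak - 5 * sigma_t) * fs), t.onset_sample)
        hi = min(int((t_peak + 5 * sigma_t) * fs), n)
        if hi > lo:
            tt = t_axis[lo:hi]
            env[lo:hi] += amp * np.exp(-0.5 * ((tt - t_peak) / sigma_t) ** 2)
    return env


def channel_trace(spec: SessionSpec, gt: GroundTruth, global_id: int) -> np.ndarray:
    """One channel's raw 30-kHz trace on the master (untrimmed) timeline."""
    n = spec.n_master
    rng = np.random.default_rng([spec.seed, 101, int(global_id)])
    x = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)

    if spec.common_reference_sd > 0 and spec.noise_sd > 0:
        # noise shared by all channels on the same reference wire
        array_id = (int(global_id) - 1) // spec.electrodes_per_array + 1
        ref_group = (array_id + 1) // 2
        ref_rng = np.random.default_rng([spec.seed, 8, ref_group])
        x += spec.common_reference_sd * spec.noise_sd * ref_rng.normal(0.0, 1.0, n)

    w = _spike_waveform(spec.raw_rate)
    spike_amp = spec.spike_amp_factor * spec.noise_sd
    if spike_amp > 0 and spec.background_rate_hz > 0:
        n_spk = rng.poisson(spec.background_rate_hz * spec.duration)
        t_spk = rng.integers(0, max(n - w.size, 1), size=n_spk)
        if spec.task_kind == "resting" and spec.closure_schedule:
            # spiking is sparser with eyes closed
            ind = _open_indicator(spec, n)
            keep = rng.random(n_spk) < np.where(ind[t_spk] > 0, 1.0, 0.5)
            t_spk = t_spk[keep]
        _add_waveform(x, t_spk, spike_amp * w)

    if spec.task_kind == "resting" and spec.eye_open_boost > 0 \
            and spec.noise_sd > 0:
        # broadband power rises with the eyes open; independent per channel
        # (a shared deterministic component would masquerade as a
        # common-reference signal and be absorbed by PC removal downstream)
        boost = spec.eye_open_boost * spec.noise_sd * _open_indicator(spec, n)
        x += boost * rng.normal(0.0, 1.0, n)

    env = evoked_envelope(spec, gt, global_id)
    if env.any():
        t = np.arange(n) / spec.raw_rate
        x += env * np.sin(2 * np.pi * spec.carrier_hz * t)

    for g, times in zip(spec.synchrofact_groups, gt.synchrofact_times):
        if int(global_id) in g.members and spike_amp > 0:
            _add_waveform(x, times, spike_amp * w)
    return x


def channel_muae(spec: SessionSpec, gt: GroundTruth, global_ids,
                 batch: int = 8) -> np.ndarray:
    """MUAe for selected channels on the master timeline, without ever
    holding more than ``batch`` raw traces in memory."""
    global_ids = list(global_ids)
    out = None
    for b0 in range(0, len(global_ids), batch):
        gids = global_ids[b0:b0 + batch]
        raw = np.vstack([channel_trace(spec, gt, g) for g in gids])
        mu = compute_muae(raw, fs=spec.raw_rate).data
        if out is None:
            out = np.empty((len(global_ids), mu.shape[1]))
        out[b0:b0 + len(gids)] = mu
    return out


def generate_session(spec: SessionSpec) -> tuple[RawSessionSet, GroundTruth]:
    """Build the full per-NSP file set plus its ground-truth record.

    Each file holds the two arrays of one NSP (2 x electrodes_per_array
    channels); file 1 additionally carries the four eye channels.  Files are
    trimmed by their planted per-NSP start/stop offsets, so their lengths
    differ before alignment while true event times are common to all files.
    """
    spec.validate()
    gt = generate_ground_truth(spec)
    lut = spec.lut()
    n = spec.n_master
    files = []
    for f in range(1, spec.n_files + 1):
        gids = lut.globals_for_nsp(f)
        start, stop = (int(v) for v in gt.nsp_offsets[f - 1])
        traces = np.empty((len(gids), n - start - stop), dtype=np.float32)
        for row, gid in enumerate(gids):
            traces[row] = channel_trace(spec, gt, gid)[start:n - stop]
        labels = np.arange(1, len(gids) + 1)
        if f == 1:
            eye, _ = generate_eye_signals(spec)
            traces = np.vstack([traces, eye.stacked()[:, start:n - stop]
                                .astype(np.float32)])
            labels = np.concatenate([labels, np.array(EYE_LABELS)])
        events = gt.events.shifted(start, n - start - stop)
        files.append(NSPFile(nsp_id=f, signals=traces, channel_labels=labels,
                             events=events, rate=spec.raw_rate))
    return RawSessionSet(files=files, rate=spec.raw_rate, aligned=False), gt


# ----------------------------------------------------------------------
# raster-level synthesis for cross-talk studies
# ----------------------------------------------------------------------

def generate_crossing_raster(n_electrodes: int, duration: float,
                             background_rate_hz: float | np.ndarray = 3.0,
                             groups: tuple[SynchrofactGroup, ...] = (),
                             seed: int = 0, raw_rate: float = RAW_RATE,
                             lockout_ms: float = 1.0):
    """Threshold-crossing raster with planted synchrofact groups.

    Skips the raw-signal stage: background crossings are independent Poisson
    per electrode, and each group contributes exactly-simultaneous crossings
    on all members at the group rate.  Returns ``(raster, group_times)`` where
    ``raster`` is a :class:`~arrayqc.synchrofact.CrossingRaster` and
    ``group_times`` the planted event samples per group.
    """
    from .synchrofact import CrossingRaster

    rng = np.random.default_rng([seed, 5])
    n_samples = int(duration * raw_rate)
    lock = int(lockout_ms * raw_rate / 1000.0)
    for g in groups:
        bad = [m for m in g.members if not (1 <= m <= n_electrodes)]
        if bad:
            raise ConfigurationError(f"synchrofact members {bad} out of range")

    group_times = []
    for gi, g in enumerate(groups):
        g_rng = np.random.default_rng([seed, 6, gi])
        n_ev = g_rng.poisson(g.rate_hz * duration)
        t = np.sort(g_rng.integers(0, n_samples, size=n_ev))
        if t.size > 1:
            t = t[np.concatenate([[True], np.diff(t) > 2 * lock])]
        group_times.append(t)

    rates = np.broadcast_to(np.asarray(background_rate_hz, dtype=float),
                            (n_electrodes,))
    times, electrodes = [], []
    for e in range(1, n_electrodes + 1):
        t = np.sort(rng.integers(0, n_samples,
                                 size=rng.poisson(rates[e - 1] * duration)))
        for g, gt_t in zip(groups, group_times):
            if e in g.members:
                t = np.sort(np.concatenate([t, gt_t]))
        if t.size > 1:  # refractory lockout, as the extractor enforces
            keep = np.ones(t.size, dtype=bool)
            last = -10 * lock
            for i, ti in enumerate(t):
                if ti - last < lock:
                    keep[i] = False
                else:
                    last = ti
            t = t[keep]
        times.append(t)
        electrodes.append(np.full(t.size, e))

    raster = CrossingRaster(
        electrode_ids=np.arange(1, n_electrodes + 1),
        times=times, n_samples=n_samples, rate=raw_rate)
    return raster, group_times
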