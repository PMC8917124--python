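"""Cross-talk (synchrofact) detection and iterative electrode pruning.

Threshold crossings are extracted per electrode from 250-9000-Hz band-passed
traces (after removing, within each reference-wire group, the first principal
component, which roughly corresponds to the channels' common signal).  The
noise level is the Quiroga robust estimate ``median(|x|) / 0.6745`` and the
threshold is ``-5`` times that level; a 1-ms refractory lockout keeps one
crossing per excursion.

Crossings across electrodes falling in identical or adjacent 1/30-ms sampling
bins are chained (transitively) into one synchronous event whose *complexity*
is the number of distinct participating electrodes.  Whether the count of
events at each complexity exceeds chance is assessed with a one-sided Monte
Carlo test against surrogates that independently dither every crossing
uniformly within +/-5 ms; isolated crossings (complexity 1) are kept in the
histogram but not tested — they are not synchronous events.  Each electrode's
synchrofact participation is

    SP = N_aboveChance / N_total,

the fraction of all events it participates in whose complexity is flagged
above chance in its own complexity histogram (a global-histogram mode is
also available).  Electrodes with SNR < 2 or a crossing rate below 0.1/s are
excluded from the analysis.  Pruning repeatedly removes the highest-SP
electrode (ties: lowest global ID) and recomputes synchrony, chance levels
and SP on the remainder, until a configurable SP floor or removal budget is
reached.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .channel_map import LUT
from .errors import ConfigurationError, SignalError
from .session import RAW_RATE
from .signals import FILTER_ORDER

CROSSING_BAND = (250.0, 9000.0)
THRESHOLD_MULTIPLIER = 5.0
QUIROGA_FACTOR = 0.6745
LOCKOUT_MS = 1.0
DITHER_MS = 5.0
N_SURROGATES = 1000
ALPHA = 0.05
FR_MIN = 0.1          # crossings/s; below -> excluded
SNR_MIN = 2.0
SP_FLOOR = 0.1
_SURR_C_CAP = 64      # complexity cap for stored surrogate histograms


# ----------------------------------------------------------------------
# raster container
# ----------------------------------------------------------------------

@dataclass
class CrossingRaster:
    """Per-electrode sorted threshold-crossing times (samples at 30 kHz)."""

    electrode_ids: np.ndarray        # global IDs, one per electrode
    times: list[np.ndarray]          # sorted int64 sample indices
    n_samples: int
    rate: float = RAW_RATE

    def __post_init__(self):
        self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.int64)
        if len(self.times) != self.electrode_ids.size:
            raise SignalError("one crossing list per electrode required")
        self.times = [np.asarray(t, dtype=np.int64) for t in self.times]
        for eid, t in zip(self.electrode_ids, self.times):
            if t.size and (t.min() < 0 or t.max() >= self.n_samples):
                raise SignalError(f"electrode {eid}: crossing outside session")

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_ids.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.times])

    def firing_rates(self) -> np.ndarray:
        return self.counts() / self.duration_s

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, electrode_index) concatenated and time-sorted."""
        if not self.times:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        t = np.concatenate(self.times)
        e = np.concatenate([np.full(x.size, i, dtype=np.int64)
                            for i, x in enumerate(self.times)])
        order = np.argsort(t, kind="stable")
        return t[order], e[order]

    def subset(self, keep_ids: np.ndarray) -> "CrossingRaster":
        keep = np.isin(self.electrode_ids, keep_ids)
        return CrossingRaster(
            electrode_ids=self.electrode_ids[keep],
            times=[t for t, k in zip(self.times, keep) if k],
            n_samples=self.n_samples, rate=self.rate)


# ----------------------------------------------------------------------
# preprocessing and crossing extraction
# ----------------------------------------------------------------------

def preprocess_for_crossings(traces: np.ndarray, global_ids: np.ndarray,
                             lut: LUT, fs: float = RAW_RATE) -> np.ndarray:
    """Band-pass 250-9000 Hz, then remove each reference group's first PC.

    ``traces`` is (n_channels, n_samples) with rows in ``global_ids`` order.
    Groups with a single present channel are left untouched (with a warning).
    """
    x = np.asarray(traces, dtype=np.float64)
    if not np.isfinite(x).all():
        raise SignalError("non-finite samples in crossing preprocessing input")
    global_ids = np.asarray(global_ids)
    sos = sps.butter(FILTER_ORDER, CROSSING_BAND, btype="bandpass", fs=fs,
                     output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)

    group_of = np.array([lut.record(g).reference_group for g in global_ids])
    for grp in np.unique(group_of):
        rows = np.flatnonzero(group_of == grp)
        if rows.size < 2:
            warnings.warn(f"reference group {grp} has a single channel; "
                          "PC removal skipped", stacklevel=2)
            continue
        sub = x[rows]
        cov = sub @ sub.T / sub.shape[1]
        vals, vecs = np.linalg.eigh(cov)
        u = vecs[:, -1:]                      # first principal direction
        x[rows] = sub - u @ (u.T @ sub)
    return x


def extract_crossings(trace: np.ndarray, multiplier: float = THRESHOLD_MULTIPLIER,
                      fs: float = RAW_RATE,
                      lockout_ms: float = LOCKOUT_MS) -> np.ndarray:
    """Negative-threshold crossing times with a refractory lockout.

    The threshold is ``-multiplier * median(|x|) / 0.6745``; one crossing is
    registered at the first sample of each sub-threshold excursion, and
    further crossings within the lockout are discarded.
    """
    x = np.asarray(trace, dtype=np.float64)
    if not np.isfinite(x).all():
        raise SignalError("non-finite samples in trace")
    sigma = np.median(np.abs(x)) / QUIROGA_FACTOR
    if sigma == 0:
        return np.empty(0, dtype=np.int64)
    below = x < -multiplier * sigma
    if not below.any():
        return np.empty(0, dtype=np.int64)
    starts = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    lock = int(round(lockout_ms * fs / 1000.0))
    kept = []
    last = -lock - 1
    for s in starts:
        if s - last >= lock:
            kept.append(s)
            last = s
    return np.asarray(kept, dtype=np.int64)


def extract_raster(traces: np.ndarray, global_ids: np.ndarray, lut: LUT,
                   fs: float = RAW_RATE,
                   multiplier: float = THRESHOLD_MULTIPLIER) -> CrossingRaster:
    """Preprocess + extract crossings for a block of channels."""
    filt = preprocess_for_crossings(traces, global_ids, lut, fs=fs)
    times = [extract_crossings(row, multiplier=multiplier, fs=fs) for row in filt]
    return CrossingRaster(electrode_ids=np.asarray(global_ids), times=times,
                          n_samples=int(np.asarray(traces).shape[-1]), rate=fs)


# ----------------------------------------------------------------------
# synchrony counting
# ----------------------------------------------------------------------

@dataclass
class SyncCounts:
    """Synchronous-event decomposition of a raster."""
    n_events: int
    complexity: np.ndarray        # per event: number of distinct electrodes
    event_sizes: np.ndarray       # per event: number of crossings
    histogram: np.ndarray         # counts[c], c = 0..n_electrodes
    per_electrode: np.ndarray     # (n_electrodes, n_electrodes + 1)

    def total_crossings_assigned(self) -> int:
        return int(self.event_sizes.sum())


#: field-standard name for the complexity decomposition
ComplexityHistogram = SyncCounts


def _unique_int(key: np.ndarray) -> np.ndarray:
    """Sorted unique values of an integer array (np.unique minus overhead)."""
    if key.size == 0:
        return key
    sk = np.sort(key)
    mask = np.empty(sk.size, dtype=bool)
    mask[0] = True
    np.not_equal(sk[1:], sk[:-1], out=mask[1:])
    return sk[mask]


def _count_sorted(t: np.ndarray, e: np.ndarray, n_elec: int,
                  max_gap: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(event_id per crossing, complexity per event, size per event)."""
    if t.size == 0:
        z = np.empty(0, np.int64)
        return z, z, z
    new = np.empty(t.size, dtype=bool)
    new[0] = True
    np.greater(np.diff(t), max_gap, out=new[1:])
    ev = np.cumsum(new) - 1
    sizes = np.bincount(ev)
    uk = _unique_int(ev * n_elec + e)
    complexity = np.bincount(uk // n_elec, minlength=sizes.size)
    return ev, complexity, sizes


def count_synchrony(raster: CrossingRaster, max_gap: int = 1) -> SyncCounts:
    """Chain crossings in identical/adjacent sampling bins into events.

    Chaining is transitive: crossings a-b and b-c adjacent put a, b, c into
    one event.  Complexity counts distinct electrodes, so the global and
    per-electrode histograms agree with the raster's crossing totals.
    """
    t, e = raster.flatten()
    n_elec = raster.n_electrodes
    ev, complexity, sizes = _count_sorted(t, e, n_elec, max_gap)
    hist = np.bincount(complexity, minlength=n_elec + 1)[: n_elec + 1]
    per_elec = np.zeros((n_elec, n_elec + 1), dtype=np.int64)
    if t.size:
        uk = _unique_int(ev * n_elec + e)
        per_elec.ravel()[:] = np.bincount(
            (uk % n_elec) * (n_elec + 1) + complexity[uk // n_elec],
            minlength=per_elec.size)
    return SyncCounts(n_events=int(complexity.size), complexity=complexity,
                      event_sizes=sizes, histogram=hist, per_electrode=per_elec)


# ----------------------------------------------------------------------
# surrogate test
# ----------------------------------------------------------------------

@dataclass
class SynchronyFlags:
    """Above-chance decisions per complexity (and per electrode)."""
    mode: str                      # "per_electrode" | "global"
    alpha: float
    n_surrogates: int
    above_chance: np.ndarray       # bool; (n_elec, C+1) or (C+1,)
    quantiles: np.ndarray          # surrogate (1-alpha) count quantiles
    observed: np.ndarray           # matching observed counts

    def flagged_complexities(self) -> np.ndarray:
        mask = self.above_chance.any(axis=0) if self.above_chance.ndim == 2 \
            else self.above_chance
        return np.flatnonzero(mask)


def _surrogate_hists(raster: CrossingRaster, n_surrogates: int, dither: int,
                     rng: np.random.Generator, per_electrode: bool,
                     max_gap: int = 1) -> np.ndarray:
    """One surrogate complexity histogram per dithered replicate."""
    t0, e0 = raster.flatten()
    n_elec = raster.n_electrodes
    cap = min(n_elec, _SURR_C_CAP)
    shape = (n_surrogates, n_elec, cap + 1) if per_electrode \
        else (n_surrogates, cap + 1)
    out = np.zeros(shape, dtype=np.int32)
    if t0.size == 0:
        return out
    for s in range(n_surrogates):
        if dither > 0:
            t = t0 + rng.integers(-dither, dither + 1, size=t0.size)
            np.clip(t, 0, raster.n_samples - 1, out=t)
            order = np.argsort(t, kind="stable")
            t, e = t[order], e0[order]
        else:
            t, e = t0, e0
        new = np.empty(t.size, dtype=bool)
        new[0] = True
        np.greater(np.diff(t), max_gap, out=new[1:])
        ev = np.cumsum(new) - 1
        n_events = int(ev[-1]) + 1
        uk = _unique_int(ev * n_elec + e)
        ev_u = uk // n_elec
        comp = np.bincount(ev_u, minlength=n_events)   # distinct electrodes
        if per_electrode:
            c_u = np.minimum(comp[ev_u], cap)
            hist = np.bincount((uk % n_elec) * (cap + 1) + c_u,
                               minlength=n_elec * (cap + 1))
            out[s] = hist.reshape(n_elec, cap + 1)
        else:
            out[s] = np.bincount(np.minimum(comp, cap), minlength=cap + 1)
    return out


def surrogate_test(raster: CrossingRaster, counts: SyncCounts | None = None,
                   n_surrogates: int = N_SURROGATES, dither_ms: float = DITHER_MS,
                   alpha: float = ALPHA, mode: str = "per_electrode",
                   rng: np.random.Generator | int | None = None,
                   max_gap: int = 1) -> SynchronyFlags:
    """One-sided Monte Carlo test of each complexity count against dithered
    surrogates.

    A complexity c >= 2 is above chance when its observed event count exceeds
    the empirical (1 - alpha) quantile of the surrogate counts.  In
    ``per_electrode`` mode (default) the test runs on each electrode's own
    complexity histogram; ``global`` mode tests the pooled histogram.
    """
    if n_surrogates < 1:
        raise ConfigurationError("n_surrogates must be >= 1")
    if raster.counts().sum() == 0:
        raise ConfigurationError("empty raster")
    if mode not in ("per_electrode", "global"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    if counts is None:
        counts = count_synchrony(raster, max_gap)
    dither = int(round(dither_ms * raster.rate / 1000.0))
    per_elec = mode == "per_electrode"
    surr = _surrogate_hists(raster, n_surrogates, dither, rng, per_elec, max_gap)
    cap = surr.shape[-1] - 1

    observed = counts.per_electrode if per_elec else counts.histogram
    n_cols = observed.shape[-1]
    # quantiles beyond the stored cap are zero: chance events that complex
    # essentially never occur
    q = np.zeros(observed.shape, dtype=np.float64)
    q_surr = np.quantile(surr, 1.0 - alpha, axis=0, method="higher")
    q[..., : cap + 1] = q_surr
    above = observed > q
    above[..., :2] = False      # complexity 0/1: not synchronous events
    return SynchronyFlags(mode=mode, alpha=alpha, n_surrogates=n_surrogates,
                          above_chance=above, quantiles=q, observed=observed)


# ----------------------------------------------------------------------
# synchrofact participation and pruning
# ----------------------------------------------------------------------

def compute_sp(raster: CrossingRaster, flags: SynchronyFlags,
               counts: SyncCounts | None = None,
               snr: dict[int, float] | None = None,
               fr_min: float = FR_MIN, snr_min: float = SNR_MIN) -> pd.DataFrame:
    """Per-electrode synchrofact participation SP = N_aboveChance / N_total.

    ``N_total`` counts every event the electrode participates in (including
    isolated crossings) — normalising by the electrode's total event count is
    what removes the firing-rate bias; ``N_aboveChance`` counts its events
    whose complexity is flagged above chance.  Electrodes with SNR below
    ``snr_min`` (when an SNR table is supplied) or crossing rate below
    ``fr_min``, or with no events at all, are marked excluded.
    """
    if counts is None:
        counts = count_synchrony(raster)
    if flags.mode == "per_electrode":
        above_mask = flags.above_chance
    else:
        above_mask = np.broadcast_to(flags.above_chance,
                                     counts.per_electrode.shape)
    n_total = counts.per_electrode.sum(axis=1)
    n_above = np.where(above_mask[..., : counts.per_electrode.shape[1]],
                       counts.per_electrode, 0).sum(axis=1)
    fr = raster.firing_rates()
    rows = []
    for i, eid in enumerate(raster.electrode_ids):
        reason = ""
        ch_snr = None if snr is None else snr.get(int(eid))
        if n_total[i] == 0:
            reason = "no events"
        elif fr[i] < fr_min:
            reason = f"FR < {fr_min}"
        elif ch_snr is not None and ch_snr < snr_min:
            reason = f"SNR < {snr_min}"
        sp = float(n_above[i] / n_total[i]) if n_total[i] > 0 else float("nan")
        rows.append({"electrode": int(eid), "n_total": int(n_total[i]),
                     "n_above_chance": int(n_above[i]), "sp": sp,
                     "fr": float(fr[i]), "excluded": bool(reason),
                     "exclusion_reason": reason})
    return pd.DataFrame(rows)


@dataclass
class RemovalResult:
    removals: pd.DataFrame          # rank, electrode, sp_at_removal
    sp_trajectory: list[np.ndarray] # max-SP over iterations
    final_sp: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def removed_ids(self) -> np.ndarray:
        return self.removals.electrode.to_numpy()


def iterative_removal(raster: CrossingRaster, max_remove: int,
                      sp_floor: float = SP_FLOOR,
                      n_surrogates: int = N_SURROGATES,
                      dither_ms: float = DITHER_MS, alpha: float = ALPHA,
                      mode: str = "per_electrode",
                      snr: dict[int, float] | None = None,
                      fr_min: float = FR_MIN, snr_min: float = SNR_MIN,
                      rng: np.random.Generator | int | None = None) -> RemovalResult:
    """Greedy pruning: repeatedly drop the highest-SP electrode.

    Chance levels and SP are recomputed on the remaining raster after every
    removal.  Stops when ``max_remove`` electrodes are gone or no remaining
    electrode exceeds ``sp_floor``.  Excluded electrodes (low SNR / low FR)
    are dropped from the analysis up front and never pruned.
    """
    rng = np.random.default_rng(rng)
    base_sp = compute_sp(raster, surrogate_test(
        raster, n_surrogates=1, dither_ms=0, alpha=alpha, mode=mode, rng=rng),
        snr=snr, fr_min=fr_min, snr_min=snr_min)
    excluded = base_sp[base_sp.excluded]
    eligible = base_sp[~base_sp.excluded].electrode.to_numpy()
    if max_remove >= eligible.size:
        raise ConfigurationError(
            f"max_remove={max_remove} >= {eligible.size} eligible electrodes")
    active = raster.subset(eligible)

    removals: list[dict] = []
    trajectory: list[np.ndarray] = []
    sp_df = None
    while len(removals) < max_remove:
        counts = count_synchrony(active)
        flags = surrogate_test(active, counts=counts, n_surrogates=n_surrogates,
                               dither_ms=dither_ms, alpha=alpha, mode=mode,
                               rng=rng)
        sp_df = compute_sp(active, flags, counts=counts)
        trajectory.append(sp_df.sp.to_numpy())
        # argmax SP, ties -> lowest global ID (frame is ID-ordered)
        best = sp_df.loc[sp_df.sp.idxmax()]
        if not np.isfinite(best.sp) or best.sp <= sp_floor:
            break
        removals.append({"rank": len(removals) + 1,
                         "electrode": int(best.electrode),
                         "sp_at_removal": float(best.sp)})
        active = active.subset(
            active.electrode_ids[active.electrode_ids != best.electrode])

    return RemovalResult(
        removals=pd.DataFrame(removals,
                              columns=["rank", "electrode", "sp_at_removal"]),
        sp_trajectory=trajectory,
        final_sp=sp_df if sp_df is not None else pd.DataFrame(),
        excluded=excluded)
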