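"""End-to-end orchestration: align -> extract -> task metrics -> synchrofact.

``run_pipeline`` drives the stage functions over a session directory, writes
the derived-signal files and stage tables into an output directory, and
collects everything estimated per channel into a single hierarchical
metadata record (a simplified stand-in for a full electrophysiology metadata
schema) that exports losslessly to JSON.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, evoked, eye, rf, synchrofact
from .channel_map import LUT
from .errors import ConfigurationError
from .io import read_impedance, read_session, write_derived, write_events
from .session import DerivedSignal, EYE_LABELS, RawSessionSet
from .signals import compute_lfp, compute_muae
from .synthetic import CODE_STIM_ON, DIRECTION_CODES

log = logging.getLogger("arrayqc")

ALL_STAGES = ("align", "extract", "snr", "rf", "eyes", "synchrofact")


@dataclass
class PipelineConfig:
    """All stage parameters; unknown keys in a config file are rejected."""

    session_dir: str = ""
    out_dir: str = ""
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    # evoked metrics
    snr_threshold: float = evoked.SNR_THRESHOLD
    baseline_ms: float = evoked.BASELINE_MS
    stim_duration_ms: float = 400.0
    latency_min_ms: float = evoked.LATENCY_MIN_MS
    latency_max_ms: float = evoked.LATENCY_MAX_MS

    # eye state
    eye_threshold: float | None = None     # None -> scale-free default
    eye_corr_array: int = 1

    # rf mapping (geometry defaults are overridden by stimulus.json if present)
    rf_bar_speed: float = 4.0
    rf_sweep_duration_s: float = 1.0
    rf_start_positions: dict = field(default_factory=lambda: {
        "rightward": -0.5, "leftward": 3.5, "upward": -3.5, "downward": 0.5})

    # synchrofact
    crossing_multiplier: float = synchrofact.THRESHOLD_MULTIPLIER
    n_surrogates: int = synchrofact.N_SURROGATES
    dither_ms: float = synchrofact.DITHER_MS
    alpha: float = synchrofact.ALPHA
    max_remove: int = 10
    sp_floor: float = synchrofact.SP_FLOOR
    sync_mode: str = "per_electrode"

    def __post_init__(self):
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_surrogates < 1:
            raise ConfigurationError("n_surrogates must be >= 1")
        if self.eye_threshold is not None and self.eye_threshold <= 0:
            raise ConfigurationError("eye_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded)."""
        d = asdict(self)
        d.pop("session_dir", None)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------

def _jsonable(obj):
    """Recursively convert to JSON-native types; NaN becomes null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def export_metadata(meta: dict, path: str | Path, fmt: str = "json") -> Path:
    if fmt != "json":
        raise ConfigurationError(f"unknown metadata format {fmt!r}")
    path = Path(path)
    path.write_text(json.dumps(_jsonable(meta), indent=1, sort_keys=True))
    return path


def import_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------------------
# stage helpers
# ----------------------------------------------------------------------

def muae_matrix(aligned: RawSessionSet, lut: LUT) -> tuple[np.ndarray, np.ndarray]:
    """(global_ids, MUAe) over all neural channels of an aligned session."""
    ids, rows = [], []
    for f in aligned.files:
        neural = f.channel_labels[~np.isin(f.channel_labels, EYE_LABELS)]
        for label in neural:
            ids.append(lut.from_nsp(f.nsp_id, int(label)).global_id)
            rows.append(f.channel(int(label)))
    raw = np.vstack(rows)
    return np.asarray(ids), compute_muae(raw, fs=aligned.rate).data


def snr_stage(aligned: RawSessionSet, lut: LUT, cfg: PipelineConfig,
              muae: np.ndarray | None = None,
              global_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-channel evoked summary from the stimulus-onset events."""
    if muae is None or global_ids is None:
        global_ids, muae = muae_matrix(aligned, lut)
    events = aligned.files[0].events
    onsets = events.samples[events.codes == CODE_STIM_ON]
    if onsets.size == 0:
        raise ConfigurationError("snr stage: no stimulus-onset events (code 2)")
    bins_per_sample = evoked.MUAE_RATE / aligned.rate
    onset_bins = np.round(onsets * bins_per_sample).astype(np.int64)
    pre = int(cfg.baseline_ms)
    post = int(cfg.stim_duration_ms)
    ok = (onset_bins - pre >= 0) & (onset_bins + post <= muae.shape[1])
    onset_bins = onset_bins[ok]
    rows = []
    for gid, trace in zip(global_ids, muae):
        trials = evoked.extract_trials(trace, onset_bins, pre, post)
        s = evoked.compute_snr(trials, pre, cfg.stim_duration_ms,
                               channel=int(gid), baseline_ms=cfg.baseline_ms,
                               snr_threshold=cfg.snr_threshold)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def rf_stage(aligned: RawSessionSet, lut: LUT, cfg: PipelineConfig,
             stimulus: dict | None = None,
             muae: np.ndarray | None = None,
             global_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-channel RF estimates from the four sweep directions."""
    if muae is None or global_ids is None:
        global_ids, muae = muae_matrix(aligned, lut)
    stim = stimulus or {}
    speed = float(stim.get("bar_speed", cfg.rf_bar_speed))
    sweep_s = float(stim.get("sweep_duration_s", cfg.rf_sweep_duration_s))
    starts = stim.get("start_positions", cfg.rf_start_positions)

    events = aligned.files[0].events
    code_to_dir = {v: k for k, v in DIRECTION_CODES.items()}
    onsets, dirs = [], []
    samples, codes = events.samples, events.codes
    for i in np.flatnonzero(codes == CODE_STIM_ON):
        if i + 1 < codes.size and int(codes[i + 1]) in code_to_dir:
            onsets.append(samples[i])
            dirs.append(code_to_dir[int(codes[i + 1])])
    if not onsets:
        raise ConfigurationError("rf stage: no direction-tagged sweep onsets")
    onset_bins = np.round(np.array(onsets) * evoked.MUAE_RATE / aligned.rate
                          ).astype(np.int64)
    dirs = np.array(dirs)
    n_bins = int(sweep_s * evoked.MUAE_RATE)

    geometries = {d: rf.SweepGeometry(direction=d, speed=speed,
                                      start_position=float(starts[d]))
                  for d in rf.OPPOSITE}
    rows = []
    for gid, trace in zip(global_ids, muae):
        fits = {}
        for d in rf.OPPOSITE:
            sel = onset_bins[dirs == d]
            sel = sel[sel + n_bins <= trace.size]
            if sel.size == 0:
                continue
            trials = evoked.extract_trials(trace, sel, 0, n_bins)
            fits[d] = rf.fit_response_gaussian(trials.mean(axis=0),
                                               (0.0, n_bins * 1.0))
        est = rf.estimate_rf(fits, geometries, channel=int(gid))
        if est is not None:
            rows.append({"channel": est.channel, "left": est.left,
                         "right": est.right, "bottom": est.bottom,
                         "top": est.top, "centre_x": est.centre[0],
                         "centre_y": est.centre[1], "diameter": est.diameter,
                         "partial": est.partial})
    return pd.DataFrame(rows, columns=["channel", "left", "right", "bottom",
                                       "top", "centre_x", "centre_y",
                                       "diameter", "partial"])


def eye_stage(aligned: RawSessionSet, cfg: PipelineConfig, lut: LUT,
              muae: np.ndarray | None = None,
              global_ids: np.ndarray | None = None):
    """Eye-state series plus its Pearson validation against array-mean MUAe."""
    f1 = aligned.files[0]
    try:
        pupil_x, pupil_y = f1.channel(131), f1.channel(132)
    except Exception as exc:
        raise ConfigurationError("eyes stage: NSP 1 lacks pupil channels "
                                 "(labels 131/132)") from exc
    combined = eye.correct_and_combine(pupil_x, pupil_y)
    series = eye.downsample_and_threshold(combined, cfg.eye_threshold,
                                          in_rate=aligned.rate)
    r = float("nan")
    if muae is not None and global_ids is not None:
        arr_ids = lut.globals_for_array(cfg.eye_corr_array)
        sel = np.isin(global_ids, arr_ids)
        if sel.any():
            mean_muae = muae[sel].mean(axis=0)
            mu_1hz = eye.block_average(mean_muae, evoked.MUAE_RATE, 1.0)
            n = min(mu_1hz.size, series.state.size)
            trimmed = eye.EyeStateSeries(
                rate=series.rate, combined_diameter=series.combined_diameter[:n],
                state=series.state[:n], segments=series.segments,
                threshold=series.threshold)
            r = eye.correlate_state_with_muae(trimmed, mu_1hz[:n])
    return series, r


# ----------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the metadata.

    Outputs written to ``cfg.out_dir``: per-array ``muae_arrayY.h5`` /
    ``lfp_arrayY.h5``, stage tables (``evoked_summary.csv``, ``rf_map.csv``,
    ``eye_state.csv``, ``removal_list.csv``), aligned event files, and
    ``metadata.json``.  Every output carries the config hash.
    """
    t_start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session_dir = Path(cfg.session_dir)
    if not session_dir.is_dir():
        raise ConfigurationError(f"session directory {session_dir} not found")

    raw, lut = read_session(session_dir)
    if lut is None:
        raise ConfigurationError(f"align stage: {session_dir}/lut.csv missing")
    stim_path = session_dir / "stimulus.json"
    stimulus = json.loads(stim_path.read_text()) if stim_path.exists() else None

    # only task-appropriate stages apply when the session's task is known
    task = (stimulus or {}).get("task_kind")
    inapplicable = {"resting": {"snr", "rf"}, "snr": {"rf", "eyes"},
                    "rf": {"snr", "eyes"}}.get(task, set())
    stages = tuple(s for s in cfg.stages if s not in inapplicable)

    timings: dict[str, float] = {}
    meta: dict = {
        "session": {"path": str(session_dir), "config_hash": cfg.config_hash(),
                    "n_files": raw.n_files, "rate_hz": raw.rate,
                    "task": (stimulus or {}).get("task_kind")},
        "channels": {int(g): {} for g in lut.table.global_id},
    }

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s finished in %.2fs", stage, timings[stage])

    # --- align ---------------------------------------------------------
    t0 = time.time()
    if "align" in stages and not raw.aligned:
        raw, offsets = alignment.align_session(raw)
        meta["session"]["alignment_offsets"] = offsets.tolist()
        for f in raw.files:
            write_events(f.events, out / f"nsp{f.nsp_id}_aligned_events.csv")
        tick("align", t0)
    elif not raw.aligned:
        raise ConfigurationError("stages after align require an aligned session")

    muae = global_ids = None
    need_muae = {"extract", "snr", "rf", "eyes"} & set(stages)
    if need_muae:
        t0 = time.time()
        global_ids, muae = muae_matrix(raw, lut)
        if "extract" in stages:
            nsp_index = {f.nsp_id: f for f in raw.files}
            for array_id in sorted(set(lut.table.array_id)):
                arr_ids = lut.globals_for_array(array_id)
                sel = np.isin(global_ids, arr_ids)
                muae_sig = DerivedSignal(
                    kind="MUAe", rate=evoked.MUAE_RATE, data=muae[sel],
                    channel_ids=global_ids[sel],
                    provenance={"config_hash": cfg.config_hash()})
                write_derived(muae_sig, array_id, out)
                rows = [nsp_index[lut.record(g).nsp_id]
                        .channel(lut.record(g).within_nsp) for g in arr_ids]
                lfp = compute_lfp(np.vstack(rows), fs=raw.rate,
                                  channel_ids=arr_ids)
                lfp.provenance["config_hash"] = cfg.config_hash()
                write_derived(lfp, array_id, out)
        tick("extract", t0)

    # --- task metrics ----------------------------------------------------
    snr_by_channel: dict[int, float] = {}
    if "snr" in stages:
        t0 = time.time()
        summary = snr_stage(raw, lut, cfg, muae, global_ids)
        summary.to_csv(out / "evoked_summary.csv", index=False)
        for rec in summary.itertuples(index=False):
            meta["channels"][int(rec.channel)].update(
                snr=rec.snr, mean_spontaneous=rec.mean_spontaneous,
                sd_spontaneous=rec.sd_spontaneous, peak_evoked=rec.peak_evoked,
                latency_ms=rec.latency_ms, latency_flag=rec.latency_flag,
                good=bool(rec.good))
            snr_by_channel[int(rec.channel)] = float(rec.snr)
        meta["session"]["n_good_channels"] = int(summary.good.sum())
        tick("snr", t0)

    if "rf" in stages:
        t0 = time.time()
        rf_map = rf_stage(raw, lut, cfg, stimulus, muae, global_ids)
        rf_map.to_csv(out / "rf_map.csv", index=False)
        for rec in rf_map.itertuples(index=False):
            meta["channels"][int(rec.channel)].update(
                rf_centre_x=rec.centre_x, rf_centre_y=rec.centre_y,
                rf_diameter=rec.diameter)
        tick("rf", t0)

    if "eyes" in stages:
        t0 = time.time()
        series, r = eye_stage(raw, cfg, lut, muae, global_ids)
        pd.DataFrame({"second": np.arange(series.state.size),
                      "combined_diameter": series.combined_diameter,
                      "state": series.state}).to_csv(out / "eye_state.csv",
                                                     index=False)
        series.segments.to_csv(out / "eye_segments.csv", index=False)
        meta["session"]["eye"] = {
            "open_fraction": series.open_fraction(),
            "closed_seconds": series.closed_seconds(),
            "threshold": series.threshold,
            "muae_correlation": r, "correlation_array": cfg.eye_corr_array}
        tick("eyes", t0)

    if "synchrofact" in stages:
        t0 = time.time()
        ids, rows = [], []
        for f in raw.files:
            neural = f.channel_labels[~np.isin(f.channel_labels, EYE_LABELS)]
            for label in neural:
                ids.append(lut.from_nsp(f.nsp_id, int(label)).global_id)
                rows.append(f.channel(int(label)))
        raster = synchrofact.extract_raster(
            np.vstack(rows), np.array(ids), lut, fs=raw.rate,
            multiplier=cfg.crossing_multiplier)
        result = synchrofact.iterative_removal(
            raster, max_remove=cfg.max_remove, sp_floor=cfg.sp_floor,
            n_surrogates=cfg.n_surrogates, dither_ms=cfg.dither_ms,
            alpha=cfg.alpha, mode=cfg.sync_mode,
            snr=snr_by_channel or None, rng=cfg.seed)
        result.removals.to_csv(out / "removal_list.csv", index=False)
        for rec in result.removals.itertuples(index=False):
            meta["channels"][int(rec.electrode)].update(
                removal_rank=int(rec.rank), sp_at_removal=rec.sp_at_removal)
        if not result.final_sp.empty:
            for rec in result.final_sp.itertuples(index=False):
                meta["channels"][int(rec.electrode)].setdefault("sp", rec.sp)
        meta["session"]["n_removed"] = int(len(result.removals))
        tick("synchrofact", t0)

    imp = read_impedance(session_dir)
    if imp is not None:
        for rec in imp.itertuples(index=False):
            meta["channels"].setdefault(int(rec.global_id), {})[
                "impedance_kohm"] = rec.impedance_kohm

    meta["session"]["stage_timings_s"] = timings
    meta["session"]["total_runtime_s"] = round(time.time() - t_start, 3)
    export_metadata(meta, out / "metadata.json")
    return meta
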