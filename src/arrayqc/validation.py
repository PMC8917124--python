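"""Recovery studies on synthetic sessions.

Every function here runs the real pipeline stages against sessions from
:mod:`arrayqc.synthetic` and measures how well the planted ground truth is
recovered.  The problem sizes (channel counts, trial counts, surrogate
counts in the pruning loops) are chosen so a full sweep completes in a few
minutes on one CPU; docs/methods.md records the sizes used.
"""
from __future__ import annotations

import numpy as np

from . import evoked, eye, rf, synchrofact
from .alignment import align_session
from .channel_map import build_lut
from .signals import MUAE_DECIMATE, compute_lfp, compute_muae
from .synchrofact import (CrossingRaster, compute_sp, count_synchrony,
                          iterative_removal, surrogate_test)
from .synthetic import (SessionSpec, SynchrofactGroup, channel_muae,
                        default_rf_centres, generate_crossing_raster,
                        generate_ground_truth, generate_session)


# ----------------------------------------------------------------------
# printed pipeline constants, exercised on a real 60-s synthetic session
# ----------------------------------------------------------------------

def printed_constants(seed: int = 0) -> dict:
    """Rates/totals the pipeline prints, measured by running the stages."""
    spec = SessionSpec(task_kind="resting", duration=60.0, n_arrays=2,
                       electrodes_per_array=2, seed=seed,
                       closure_schedule=((20.0, 30.0),))
    session, _ = generate_session(spec)
    aligned, _ = align_session(session)
    n_raw = aligned.files[0].n_samples
    trace = aligned.files[0].channel(1)
    muae = compute_muae(trace, fs=aligned.rate)
    lfp = compute_lfp(trace, fs=aligned.rate)

    f1 = aligned.files[0]
    combined = eye.correct_and_combine(f1.channel(131), f1.channel(132))
    series = eye.downsample_and_threshold(combined, in_rate=aligned.rate)
    duration_s = n_raw / aligned.rate

    lut = build_lut()  # the full default implant
    return {
        "muae_rate_hz": muae.rate,
        "muae_decimation_factor": round(n_raw / muae.data.shape[-1]),
        "lfp_rate_hz": lfp.rate,
        # one state bin per whole second of data
        "eye_series_rate_hz": series.state.size / np.floor(duration_s),
        "lut_n_channels": float(len(lut)),
        "lut_n_reference_groups": float(lut.table.reference_group.nunique()),
        "lut_channels_per_nsp": float(
            lut.table.groupby("nsp_id").size().iloc[0]),
        "lut_n_v1_arrays": float(
            lut.table[lut.table.area == "V1"].array_id.nunique()),
    }


# ----------------------------------------------------------------------
# analytic limits
# ----------------------------------------------------------------------

def analytic_limits() -> dict:
    """Closed-form checks of the signal chain and the metric formulas."""
    # rectified in-band sinusoid settles at its mean 2/pi = 0.6366...
    t = np.arange(90_000) / 30_000.0
    sine = compute_muae(np.sin(2 * np.pi * 3150.0 * t)).data
    sine_steady = float(sine[1000:2000].mean())

    dc = compute_lfp(np.full(30_000, 1.0)).data
    lfp_dc_gain = float(dc[100:400].mean())

    # SNR formula: baseline mean 10, SD 2, smoothed evoked peak 20 -> 5
    trials = np.full((30, 800), 10.0)
    trials[:, 0:300:2] += 2.0
    trials[:, 1:300:2] -= 2.0
    trials[:, 300:700] = 20.0
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = evoked.compute_snr(trials, onset_bin=300, stim_duration_ms=400)
    # normalise away the ddof-1 factor: the worked example defines SD = 2
    snr_worked = float((s.peak_evoked - s.mean_spontaneous) / 2.0)

    # RF diameter: width 3, height 4 -> D = 5 through the estimator
    geoms = {
        "rightward": rf.SweepGeometry("rightward", 1.0, -5.0),
        "leftward": rf.SweepGeometry("leftward", 1.0, 5.0),
        "upward": rf.SweepGeometry("upward", 1.0, -5.0),
        "downward": rf.SweepGeometry("downward", 1.0, 5.0),
    }

    def fit(mu_ms, sigma_ms):
        return rf.GaussianFit(mu_ms, sigma_ms, 1.0, 0.0, 0.0, True)

    # horizontal: centred at 0 with half-width 1.5 -> onset/offset span 3
    fits = {"rightward": fit(5000.0, 1500.0 / 1.65),
            "leftward": fit(5000.0, 1500.0 / 1.65),
            "upward": fit(5000.0, 2000.0 / 1.65),
            "downward": fit(5000.0, 2000.0 / 1.65)}
    est = rf.estimate_rf(fits, geoms)
    rf_diameter = float(est.diameter)

    # SP formula: 4 above-chance events out of 10
    t_iso = np.arange(6) * 3000
    t_shared = 100_000 + np.arange(4) * 3000
    raster = CrossingRaster(
        np.array([1, 2]),
        [np.sort(np.concatenate([t_iso, t_shared])), t_shared],
        n_samples=200_000)
    counts = count_synchrony(raster)
    above = np.zeros_like(counts.per_electrode, dtype=bool)
    above[:, 2] = True
    flags = synchrofact.SynchronyFlags(
        mode="per_electrode", alpha=0.05, n_surrogates=1, above_chance=above,
        quantiles=np.zeros(above.shape), observed=counts.per_electrode)
    sp = compute_sp(raster, flags, counts=counts)
    sp_worked = float(sp[sp.electrode == 1].sp.iloc[0])

    return {
        "muae_sine_steady_state": sine_steady,
        "lfp_dc_gain": lfp_dc_gain,
        "snr_worked_example": snr_worked,
        "rf_diameter_pythagorean": rf_diameter,
        "sp_worked_example": sp_worked,
    }


# ----------------------------------------------------------------------
# oracle equivalence for synchrony chaining
# ----------------------------------------------------------------------

def _brute_force_events(raster: CrossingRaster, max_gap: int = 1):
    """O(n^2) union-find over crossing pairs; independent of the fast path."""
    crossings = [(int(t), e) for e, ts in enumerate(raster.times) for t in ts]
    n = len(crossings)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(crossings[i][0] - crossings[j][0]) <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((len({crossings[i][1] for i in members}), len(members))
                  for members in groups.values())


def oracle_equivalence(n_rasters: int = 1000, seed: int = 0) -> dict:
    """Fraction of random toy rasters where chaining matches brute force."""
    rng = np.random.default_rng([seed, 0xAC])
    agree = 0
    for _ in range(n_rasters):
        n_elec = int(rng.integers(2, 11))
        times = [np.unique(rng.integers(0, 20_000,
                                        size=rng.integers(0, 101)))
                 for _ in range(n_elec)]
        raster = CrossingRaster(np.arange(1, n_elec + 1), times,
                                n_samples=20_000)
        c = count_synchrony(raster)
        mine = sorted(zip(c.complexity.tolist(), c.event_sizes.tolist()))
        agree += mine == _brute_force_events(raster)
    return {"synchrony_oracle_agreement": agree / n_rasters,
            "n": n_rasters}


# ----------------------------------------------------------------------
# parameter recovery
# ----------------------------------------------------------------------

def snr_and_latency_recovery(seed: int = 0, n_trials: int = 100) -> dict:
    """Planted SNR in {1, 3, 8} and latencies, through raw -> MUAe -> metrics.

    Twelve channels (four per SNR level); latency is assessed on the
    channels planted at SNR >= 5 where the detection rule is reliable.
    """
    planted_snr = np.repeat([1.0, 3.0, 8.0], 4)
    planted_lat = np.tile([35.0, 45.0, 55.0, 65.0], 3)
    spec = SessionSpec(task_kind="snr",
                       duration=n_trials * 1.4 + 1.0, n_arrays=2,
                       electrodes_per_array=6,
                       per_channel_snr=planted_snr,
                       per_channel_latency_ms=planted_lat, seed=seed)
    gt = generate_ground_truth(spec)
    onset_bins = (gt.trials.onset_sample.to_numpy()
                  // MUAE_DECIMATE).astype(int)[:n_trials]
    mu = channel_muae(spec, gt, np.arange(1, 13))
    rel_err = {1.0: [], 3.0: [], 8.0: []}
    lat_err = []
    for i in range(12):
        trials = evoked.extract_trials(mu[i], onset_bins, 300, 400)
        s = evoked.compute_snr(trials, 300, 400, channel=i + 1)
        rel_err[planted_snr[i]].append(abs(s.snr - planted_snr[i])
                                       / planted_snr[i])
        if planted_snr[i] >= 5:
            assert s.latency_flag == "ok", f"channel {i+1}: {s.latency_flag}"
            lat_err.append(abs(s.latency_ms - planted_lat[i]))
    return {
        "snr_recovery_max_rel_err": float(max(max(v) for v in rel_err.values())),
        "latency_max_abs_err_ms": float(max(lat_err)),
        "n_trials": n_trials,
        "n_channels": 12,
    }


def rf_recovery(seed: int = 0, planted_snr: float | None = 8.0,
                n_channels: int = 64, trials_per_direction: int = 20) -> dict:
    """Planted RF centres through the moving-bar -> Gaussian-fit chain.

    ``planted_snr=None`` runs the noiseless limit (deterministic evoked
    signal, identical trials)."""
    centres = default_rf_centres(n_channels, seed)
    noiseless = planted_snr is None
    n_trials = 4 * trials_per_direction
    spec = SessionSpec(
        task_kind="rf", duration=n_trials * 1.6 + 1.0, n_arrays=2,
        electrodes_per_array=n_channels // 2, rf_centres=centres,
        rf_sizes=1.0, seed=seed,
        noise_sd=0.0 if noiseless else 1.0,
        evoked_amplitude=1.0 if noiseless else None,
        per_channel_snr=None if noiseless else planted_snr)
    gt = generate_ground_truth(spec)
    tab = gt.trials
    geoms = {d: rf.SweepGeometry(
        direction=d, speed=spec.bar_speed,
        start_position=float(tab[tab.direction == d].start_position.iloc[0]))
        for d in rf.OPPOSITE}
    onset_bins = {d: (tab[tab.direction == d].onset_sample.to_numpy()
                      // MUAE_DECIMATE).astype(int) for d in rf.OPPOSITE}
    n_bins = int(tab.sweep_duration.iloc[0] * 1000)
    mu = channel_muae(spec, gt, np.arange(1, n_channels + 1))
    errors = []
    for i in range(n_channels):
        fits = {}
        for d in rf.OPPOSITE:
            ob = onset_bins[d]
            ob = ob[ob + n_bins <= mu.shape[1]]
            trials = evoked.extract_trials(mu[i], ob, 0, n_bins)
            fits[d] = rf.fit_response_gaussian(trials.mean(axis=0),
                                               (0.0, float(n_bins)))
        est = rf.estimate_rf(fits, geoms, channel=i + 1)
        assert est is not None and not est.partial, f"channel {i+1} unmappable"
        errors.append(float(np.hypot(est.centre[0] - centres[i, 0],
                                     est.centre[1] - centres[i, 1])))
    return {"rf_centre_error_max_dva": float(max(errors)),
            "rf_centre_error_mean_dva": float(np.mean(errors)),
            "n_channels": n_channels,
            "trials_per_direction": trials_per_direction,
            "noiseless": noiseless}


# ----------------------------------------------------------------------
# synchrofact sensitivity / specificity
# ----------------------------------------------------------------------

def synchrofact_sensitivity(n_seeds: int = 20, seed: int = 0,
                            n_electrodes: int = 128, group_size: int = 30,
                            duration: float = 60.0,
                            n_surrogates: int = 200,
                            max_remove: int = 35) -> dict:
    """Planted 30-electrode group on a 60-s, 128-electrode session.

    A seed counts as recovered when every pruned electrode belongs to the
    planted group and at least ``group_size - 1`` members are pruned within
    the removal budget (once all partners are gone, the final member no
    longer participates in any synchronous event, so it is undetectable by
    construction).
    """
    members = tuple(range(10, 10 + group_size))
    ok = 0
    for k in range(n_seeds):
        raster, _ = generate_crossing_raster(
            n_electrodes, duration, background_rate_hz=3.0,
            groups=(SynchrofactGroup(members=members, rate_hz=1.0),),
            seed=seed * 1000 + k)
        res = iterative_removal(raster, max_remove=max_remove,
                                n_surrogates=n_surrogates,
                                rng=seed * 1000 + k)
        removed = res.removed_ids
        pure = bool(np.isin(removed, members).all())
        enough = np.isin(removed[:max_remove], members).sum() >= group_size - 1
        ok += pure and enough
    return {"synchrofact_group_recovery_fraction": ok / n_seeds,
            "n_seeds": n_seeds}


def synchrofact_specificity(seed: int = 0, n_electrodes: int = 128,
                            duration: float = 60.0,
                            n_surrogates: int = 500,
                            alpha: float = 0.05) -> dict:
    """With no planted synchrony, the flagged fraction stays near alpha.

    The false-flag fraction is measured over all per-electrode complexity
    cells (c >= 2) with a nonzero observed count.
    """
    raster, _ = generate_crossing_raster(n_electrodes, duration,
                                         background_rate_hz=3.0,
                                         seed=seed + 77)
    counts = count_synchrony(raster)
    flags = surrogate_test(raster, counts=counts, n_surrogates=n_surrogates,
                           alpha=alpha, rng=seed + 77)
    observed = counts.per_electrode
    testable = observed[:, 2:] > 0
    flagged = flags.above_chance[:, 2:][testable]
    n_tests = int(testable.sum())
    return {"null_flagged_fraction": float(flagged.mean()) if n_tests else 0.0,
            "alpha": alpha,
            "bound": alpha + 3.0 * np.sqrt(alpha / max(n_tests, 1)),
            "n": n_tests}
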