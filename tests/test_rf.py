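import math

import numpy as np
import pytest

from arrayqc import (RFEstimate, SweepGeometry, estimate_rf, fit_response_gaussian,
                     merge_maps, onset_offset_times, time_to_position)
from arrayqc.errors import ConfigurationError, SignalError
from arrayqc.evoked import extract_trials
from arrayqc.rf import GaussianFit, OPPOSITE
from arrayqc.synthetic import SessionSpec, channel_muae, generate_ground_truth


class TestOnsetOffset:
    def test_arithmetic(self):
        assert onset_offset_times(300.0, 40.0) == (234.0, 366.0)

    def test_degenerate_sigma(self):
        on, off = onset_offset_times(300.0, 0.0)
        assert on == off == 300.0

    def test_symmetry(self):
        on, off = onset_offset_times(123.0, 17.0)
        assert 123.0 - on == pytest.approx(off - 123.0)


class TestTimeToPosition:
    def test_rightward(self):
        g = SweepGeometry("rightward", speed=4.0, start_position=-10.0)
        assert time_to_position(3000.0, g) == pytest.approx(2.0)

    def test_leftward_fast_bar(self):
        g = SweepGeometry("leftward", speed=20.0, start_position=10.0)
        assert time_to_position(400.0, g) == pytest.approx(2.0)

    def test_downward_decreasing_y(self):
        g = SweepGeometry("downward", speed=4.0, start_position=1.0)
        assert time_to_position(500.0, g) < time_to_position(100.0, g)

    def test_before_onset_rejected(self):
        g = SweepGeometry("rightward", speed=4.0, start_position=0.0,
                          sweep_onset_ms=100.0)
        with pytest.raises(SignalError):
            time_to_position(50.0, g)

    def test_zero_speed_rejected(self):
        with pytest.raises(ConfigurationError):
            SweepGeometry("rightward", speed=0.0, start_position=0.0)


class TestGaussianFit:
    def test_noiseless_recovery(self):
        """An exact Gaussian trace returns its parameters to 4 significant
        figures."""
        t = np.arange(1000.0)
        y = 0.5 + 2.0 * np.exp(-0.5 * ((t - 300.0) / 40.0) ** 2)
        fit = fit_response_gaussian(y, (0.0, 1000.0))
        assert fit.ok
        assert fit.mu_ms == pytest.approx(300.0, rel=1e-4)
        assert fit.sigma_ms == pytest.approx(40.0, rel=1e-4)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-4)
        assert fit.offset == pytest.approx(0.5, rel=1e-3)

    def test_flat_trace_unmappable(self):
        fit = fit_response_gaussian(np.full(500, 1.3), (0.0, 500.0))
        assert not fit.ok

    def test_pure_noise_unmappable(self):
        rng = np.random.default_rng(0)
        fit = fit_response_gaussian(1.0 + 0.05 * rng.normal(size=600),
                                    (0.0, 600.0))
        assert not fit.ok


def _fit(mu, sigma):
    return GaussianFit(mu_ms=mu, sigma_ms=sigma, amplitude=1.0, offset=0.0,
                       residual=0.0, ok=True)


def _geoms(speed=4.0):
    return {
        "rightward": SweepGeometry("rightward", speed, -2.0),
        "leftward": SweepGeometry("leftward", speed, 2.0),
        "upward": SweepGeometry("upward", speed, -2.0),
        "downward": SweepGeometry("downward", speed, 2.0),
    }


class TestEstimateRf:
    def test_boundary_is_mean_of_opposing_pair(self):
        """Left boundary = mean(position at rightward-response onset,
        position at leftward-response offset)."""
        geoms = _geoms()
        # rightward: onset at 1000 ms -> position -2 + 4*1 = 2.0
        # leftward: offset at 1250 ms -> position 2 - 4*1.25 = -3 -> pick values
        fits = {"rightward": _fit(1100.0, 100.0 / 1.65),
                "leftward": _fit(900.0, 100.0 / 1.65),
                "upward": _fit(1000.0, 50.0 / 1.65),
                "downward": _fit(1000.0, 50.0 / 1.65)}
        est = estimate_rf(fits, geoms, channel=7)
        on_r = time_to_position(1000.0, geoms["rightward"])   # 2.0
        off_l = time_to_position(1000.0, geoms["leftward"])   # -2.0
        assert est.left == pytest.approx(0.5 * (on_r + off_l))
        assert est.channel == 7

    def test_simple_mean_example(self):
        # onset-position 2.0 and opposing offset-position 3.0 -> boundary 2.5
        geoms = {"rightward": SweepGeometry("rightward", 1.0, 0.0),
                 "leftward": SweepGeometry("leftward", 1.0, 5.0)}
        fits = {"rightward": _fit(2000.0, 0.0), "leftward": _fit(2000.0, 0.0)}
        est = estimate_rf(fits, geoms)
        # rightward onset at 2 s -> x=2; leftward offset at 2 s -> x=3
        assert est.left == pytest.approx(2.5)
        assert est.partial

    def test_pythagorean_diameter(self):
        est = RFEstimate(channel=0, left=0.0, right=3.0, bottom=0.0, top=4.0,
                         centre=(1.5, 2.0), diameter=math.hypot(3.0, 4.0))
        assert est.diameter == 5.0
        # and through the estimator itself
        geoms = _geoms(speed=1.0)
        fits = {"rightward": _fit(1500.0, 1500.0 / 1.65),
                "leftward": _fit(2500.0, 1500.0 / 1.65),
                "upward": _fit(2000.0, 2000.0 / 1.65),
                "downward": _fit(2000.0, 2000.0 / 1.65)}
        est = estimate_rf(fits, geoms)
        assert est.diameter == pytest.approx(
            math.hypot(est.right - est.left, est.top - est.bottom))

    def test_missing_pair_partial(self):
        geoms = _geoms()
        fits = {"rightward": _fit(1000.0, 50.0), "leftward": _fit(1000.0, 50.0)}
        est = estimate_rf(fits, geoms)
        assert est.partial
        assert math.isnan(est.bottom)

    def test_no_usable_axis_returns_none(self):
        assert estimate_rf({}, _geoms()) is None

    def test_onset_offset_swap_symmetry(self):
        """Each boundary is a symmetric mean over the opposing pair, so
        exchanging which member of the pair contributes onset vs offset
        (i.e. swapping the direction labels together with their mirrored
        geometries) leaves the diameter unchanged."""
        geoms = _geoms()
        fits = {"rightward": _fit(1100.0, 60.0), "leftward": _fit(950.0, 45.0),
                "upward": _fit(1000.0, 30.0), "downward": _fit(1020.0, 55.0)}
        est = estimate_rf(fits, geoms)
        # the same physical sweeps relabelled: the bar that moved rightward
        # from -2 is, in mirrored coordinates, a leftward sweep from +2
        fits_m = {"rightward": fits["leftward"], "leftward": fits["rightward"],
                  "upward": fits["downward"], "downward": fits["upward"]}
        est_m = estimate_rf(fits_m, geoms)
        assert est_m.diameter == pytest.approx(est.diameter)
        # mirrored centre: x and y flip sign
        assert est_m.centre[0] == pytest.approx(-est.centre[0])
        assert est_m.centre[1] == pytest.approx(-est.centre[1])


class TestMergeMaps:
    def _est(self, ch):
        return RFEstimate(channel=ch, left=0, right=1, bottom=0, top=1,
                          centre=(0.5, 0.5), diameter=math.sqrt(2))

    def test_disjoint_union(self):
        thin = {1: self._est(1)}
        thick = {2: self._est(2)}
        merged, missing = merge_maps(thin, thick, {1: "thin", 2: "thick"})
        assert set(merged) == {1, 2}
        assert missing == []

    def test_assigned_source_wins(self):
        thin = {1: self._est(1)}
        thick = {1: self._est(1)}
        thick[1].left = -9.0
        merged, _ = merge_maps(thin, thick, {1: "thick"})
        assert merged[1].left == -9.0

    def test_unmappable_channel_flagged_missing(self):
        merged, missing = merge_maps({}, {1: self._est(1)}, {2: "thin"})
        assert merged == {} and missing == [2]

    def test_unknown_assignment_rejected(self):
        with pytest.raises(ConfigurationError):
            merge_maps({}, {}, {1: "medium"})


def _run_rf_recovery(spec, gids):
    gt = generate_ground_truth(spec)
    tab = gt.trials
    geoms = {d: SweepGeometry(direction=d, speed=spec.bar_speed,
                              start_position=float(
                                  tab[tab.direction == d].start_position.iloc[0]))
             for d in OPPOSITE}
    onset_bins = {d: (tab[tab.direction == d].onset_sample.to_numpy() // 30)
                  .astype(int) for d in OPPOSITE}
    n_bins = int(tab.sweep_duration.iloc[0] * 1000)
    mu = channel_muae(spec, gt, gids)
    out = {}
    for i, gid in enumerate(gids):
        fits = {}
        for d in OPPOSITE:
            ob = onset_bins[d]
            ob = ob[ob + n_bins <= mu.shape[1]]
            trials = extract_trials(mu[i], ob, 0, n_bins)
            fits[d] = fit_response_gaussian(trials.mean(axis=0),
                                            (0.0, float(n_bins)))
        out[gid] = estimate_rf(fits, geoms, channel=gid)
    return gt, out


class TestPlantedRecovery:
    def test_translation_equivariance(self):
        """Shifting all planted centres by (dx, dy) shifts the estimates by
        the same amount (noiseless, small n)."""
        base = np.array([[1.0, -1.0], [2.0, -2.0]])
        shift = np.array([0.6, -0.4])
        ests = []
        for centres in (base, base + shift):
            spec = SessionSpec(task_kind="rf", duration=13.0, n_arrays=2,
                               electrodes_per_array=1, noise_sd=0.0,
                               evoked_amplitude=1.0, rf_centres=centres,
                               per_channel_latency_ms=0.0, seed=3,
                               nsp_offsets=np.zeros((1, 2), int))
            _, est = _run_rf_recovery(spec, [1, 2])
            ests.append(est)
        for gid in (1, 2):
            d = np.array(ests[1][gid].centre) - np.array(ests[0][gid].centre)
            np.testing.assert_allclose(d, shift, atol=0.05)

    def test_diameter_monotone_in_planted_size(self):
        centres = np.tile([[1.5, -1.5]], (3, 1))
        spec = SessionSpec(task_kind="rf", duration=13.0, n_arrays=2,
                           electrodes_per_array=2, noise_sd=0.0,
                           evoked_amplitude=1.0, rf_centres=centres[[0, 0, 0]],
                           rf_sizes=np.array([0.5, 1.0, 1.6]),
                           per_channel_latency_ms=0.0, seed=4,
                           nsp_offsets=np.zeros((1, 2), int))
        spec.rf_centres = np.tile([[1.5, -1.5]], (4, 1))
        spec.rf_sizes = np.array([0.5, 1.0, 1.6, 1.6])
        _, est = _run_rf_recovery(spec, [1, 2, 3])
        d = [est[g].diameter for g in (1, 2, 3)]
        assert d[0] < d[1] < d[2]
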