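import numpy as np
import pytest

from arrayqc import build_lut
from arrayqc.errors import ConfigurationError
from arrayqc.synchrofact import (CrossingRaster, SynchronyFlags, compute_sp,
                                 count_synchrony, extract_crossings,
                                 iterative_removal, preprocess_for_crossings,
                                 surrogate_test)
from arrayqc.synthetic import SynchrofactGroup, generate_crossing_raster


# ---------------------------------------------------------------------------
# independent brute-force oracle: O(n^2) pairwise transitive chaining
# ---------------------------------------------------------------------------

def brute_force_events(raster: CrossingRaster, max_gap: int = 1):
    """Union-find over all crossing pairs within max_gap samples."""
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
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    events = []
    for members in groups.values():
        electrodes = {crossings[i][1] for i in members}
        events.append((len(electrodes), len(members)))
    return sorted(events)


def random_raster(rng, max_electrodes=10, max_crossings=100, span=20_000):
    n_elec = int(rng.integers(2, max_electrodes + 1))
    times = []
    for _ in range(n_elec):
        k = int(rng.integers(0, max_crossings + 1))
        times.append(np.unique(rng.integers(0, span, size=k)))
    return CrossingRaster(electrode_ids=np.arange(1, n_elec + 1), times=times,
                          n_samples=span)


class TestCountSynchrony:
    def test_simultaneous_three_electrodes(self):
        raster = CrossingRaster(np.array([1, 2, 3]),
                                [np.array([1000])] * 3, n_samples=2000)
        c = count_synchrony(raster)
        assert c.n_events == 1
        assert c.complexity.tolist() == [3]
        assert c.histogram[3] == 1

    def test_adjacent_bin_chaining(self):
        # 1000 and 1001 chain; 1003 is separate
        raster = CrossingRaster(np.array([1, 2, 3]),
                                [np.array([1000]), np.array([1001]),
                                 np.array([1003])], n_samples=2000)
        c = count_synchrony(raster)
        assert sorted(c.complexity.tolist()) == [1, 2]

    def test_transitive_chaining(self):
        # a-b adjacent and b-c adjacent -> one event of complexity 3
        raster = CrossingRaster(np.array([1, 2, 3]),
                                [np.array([1000]), np.array([1001]),
                                 np.array([1002])], n_samples=2000)
        c = count_synchrony(raster)
        assert c.n_events == 1 and c.complexity[0] == 3

    def test_conservation(self):
        """Every crossing lands in exactly one event."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            raster = random_raster(rng)
            c = count_synchrony(raster)
            assert c.total_crossings_assigned() == raster.counts().sum()

    def test_matches_brute_force_oracle(self):
        """Exact agreement with an independent union-find oracle on random
        toy rasters (the acceptance suite runs the 1000-raster sweep)."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            raster = random_raster(rng)
            c = count_synchrony(raster)
            mine = sorted(zip(c.complexity.tolist(), c.event_sizes.tolist()))
            assert mine == brute_force_events(raster)

    def test_injected_thirty_electrode_event(self):
        grp = SynchrofactGroup(members=tuple(range(1, 31)), rate_hz=0.5)
        raster, times = generate_crossing_raster(
            40, 30.0, background_rate_hz=0.0, groups=(grp,), seed=2)
        c = count_synchrony(raster)
        assert c.histogram[30] == len(times[0])


class TestExtractCrossings:
    def test_single_spike(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, 30_000)
        sigma = np.median(np.abs(x)) / 0.6745
        x[10_000:10_020] -= 10.0 * sigma
        t = extract_crossings(x)
        assert t.size == 1
        assert t[0] == 10_000

    def test_positive_deflections_ignored(self):
        # negative-polarity convention: upward deflections never cross
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1.0, 30_000)
        base = extract_crossings(x).size
        x[5_000:5_020] += 50.0
        assert extract_crossings(x).size == base

    def test_all_zero_trace(self):
        assert extract_crossings(np.zeros(10_000)).size == 0

    def test_gaussian_noise_rate_low(self):
        """White noise at the -5 sigma threshold with a 1-ms lockout yields
        well under 0.1 crossings/s."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, 60 * 30_000)
        rate = extract_crossings(x).size / 60.0
        assert rate < 0.1

    def test_lockout_merges_burst(self):
        x = np.zeros(30_000)
        x[1000:1025] = -10.0
        x[1010] = 0.0  # two excursions within 1 ms
        x[2000::5000] = 1e-6  # keep sigma nonzero
        x += np.random.default_rng(6).normal(0, 0.01, x.size)
        t = extract_crossings(x)
        assert t.size == 1


class TestPreprocess:
    def test_identical_traces_removed(self, small_lut):
        rng = np.random.default_rng(7)
        common = rng.normal(0, 1.0, 30_000)
        traces = np.tile(common, (4, 1))
        gids = small_lut.globals_for_array(1)  # one reference group
        out = preprocess_for_crossings(traces, gids, small_lut)
        assert np.abs(out).max() < 1e-6

    def test_matches_eigendecomposition_oracle(self, small_lut):
        """PC removal equals projecting out the leading covariance
        eigenvector, checked directly on a 4-channel toy."""
        rng = np.random.default_rng(8)
        common = rng.normal(0, 1.0, 30_000)
        traces = np.vstack([common + 0.1 * rng.normal(size=30_000)
                            for _ in range(4)])
        gids = small_lut.globals_for_array(1)
        out = preprocess_for_crossings(traces, gids, small_lut)
        # oracle: band-pass identically, then eigh-project
        from scipy import signal as sps
        sos = sps.butter(4, [250, 9000], btype="bandpass", fs=30_000,
                         output="sos")
        f = sps.sosfiltfilt(sos, traces, axis=-1)
        vals, vecs = np.linalg.eigh(f @ f.T / f.shape[1])
        u = vecs[:, -1:]
        expect = f - u @ (u.T @ f)
        np.testing.assert_allclose(out, expect, atol=1e-8)

    def test_zero_traces(self, small_lut):
        gids = small_lut.globals_for_array(1)
        out = preprocess_for_crossings(np.zeros((4, 10_000)), gids, small_lut)
        np.testing.assert_allclose(out, 0.0)

    def test_single_channel_group_warns(self):
        lut = build_lut(n_arrays=2, electrodes_per_array=1)
        with pytest.warns(UserWarning, match="single channel"):
            preprocess_for_crossings(np.zeros((1, 5_000)), np.array([1]), lut)


class TestSurrogates:
    def test_counts_preserved(self):
        raster, _ = generate_crossing_raster(8, 20.0, seed=10)
        from arrayqc.synchrofact import _surrogate_hists
        rng = np.random.default_rng(0)
        h = _surrogate_hists(raster, 5, 150, rng, per_electrode=True)
        # sum over complexities of (count * c) per electrode... each
        # electrode's total event participation equals its crossing count
        # when no two of its crossings chain; at these rates that holds
        per_elec_events = h.sum(axis=2)
        for s in range(5):
            np.testing.assert_array_equal(per_elec_events[s], raster.counts())

    def test_zero_dither_no_flags(self):
        """Surrogates identical to the observation can never flag anything."""
        grp = SynchrofactGroup(members=tuple(range(1, 9)), rate_hz=1.0)
        raster, _ = generate_crossing_raster(8, 20.0, groups=(grp,), seed=11)
        flags = surrogate_test(raster, n_surrogates=50, dither_ms=0.0, rng=0)
        assert not flags.above_chance.any()

    def test_planted_group_flagged(self):
        grp = SynchrofactGroup(members=tuple(range(1, 31)), rate_hz=1.0)
        raster, _ = generate_crossing_raster(
            64, 60.0, background_rate_hz=3.0, groups=(grp,), seed=12)
        flags = surrogate_test(raster, n_surrogates=200, rng=1)
        flagged = flags.flagged_complexities()
        assert any(28 <= c <= 33 for c in flagged)

    def test_empty_raster_rejected(self):
        raster = CrossingRaster(np.array([1]), [np.array([], dtype=int)],
                                n_samples=100)
        with pytest.raises(ConfigurationError):
            surrogate_test(raster, n_surrogates=10, rng=0)

    def test_bad_surrogate_count_rejected(self):
        raster, _ = generate_crossing_raster(4, 5.0, seed=13)
        with pytest.raises(ConfigurationError):
            surrogate_test(raster, n_surrogates=0, rng=0)


class TestComputeSp:
    def _flags(self, n_elec, width, flagged):
        above = np.zeros((n_elec, width), dtype=bool)
        for c in flagged:
            above[:, c] = True
        return SynchronyFlags(mode="per_electrode", alpha=0.05, n_surrogates=1,
                              above_chance=above, quantiles=np.zeros_like(above,
                              dtype=float), observed=np.zeros_like(above,
                              dtype=int))

    def test_worked_example(self):
        """4 above-chance events out of 10 -> SP = 0.4."""
        # electrode 1: 6 isolated events, 4 events of complexity 2 (flagged)
        t1 = np.arange(6) * 1000
        shared = 10_000 + np.arange(4) * 1000
        raster = CrossingRaster(np.array([1, 2]),
                                [np.sort(np.concatenate([t1, shared])), shared],
                                n_samples=20_000)
        flags = self._flags(2, 3, flagged=[2])
        sp = compute_sp(raster, flags)
        assert sp[sp.electrode == 1].sp.iloc[0] == pytest.approx(0.4)
        assert sp[sp.electrode == 2].sp.iloc[0] == pytest.approx(1.0)

    def test_no_flags_zero_sp(self):
        raster, _ = generate_crossing_raster(4, 10.0, seed=14)
        flags = surrogate_test(raster, n_surrogates=20, dither_ms=0.0, rng=0)
        sp = compute_sp(raster, flags)
        assert (sp.sp == 0).all()

    def test_low_fr_excluded(self):
        raster = CrossingRaster(np.array([1, 2]),
                                [np.array([100]), np.arange(100) * 3000 + 50],
                                n_samples=600_000)  # 20 s: 0.05/s vs 5/s
        flags = self._flags(2, 3, flagged=[])
        sp = compute_sp(raster, flags, fr_min=0.1)
        assert sp[sp.electrode == 1].excluded.iloc[0]
        assert not sp[sp.electrode == 2].excluded.iloc[0]

    def test_low_snr_excluded(self):
        raster, _ = generate_crossing_raster(2, 10.0, seed=15)
        flags = self._flags(2, 3, flagged=[])
        sp = compute_sp(raster, flags, snr={1: 0.5, 2: 5.0})
        assert sp[sp.electrode == 1].exclusion_reason.iloc[0].startswith("SNR")
        assert not sp[sp.electrode == 2].excluded.iloc[0]


class TestIterativeRemoval:
    def test_planted_group_removed_first(self):
        """With a single planted 10-electrode group, the removals are all
        group members (the last member drops out of synchrony once its
        partners are gone)."""
        grp = SynchrofactGroup(members=tuple(range(5, 15)), rate_hz=1.5)
        raster, _ = generate_crossing_raster(
            24, 40.0, background_rate_hz=3.0, groups=(grp,), seed=16)
        res = iterative_removal(raster, max_remove=12, n_surrogates=100, rng=1)
        removed = res.removed_ids
        assert 9 <= len(removed) <= 10
        assert np.isin(removed, grp.members).all()

    def test_no_synchrony_empty_removal(self):
        raster, _ = generate_crossing_raster(16, 30.0, background_rate_hz=2.0,
                                             seed=17)
        res = iterative_removal(raster, max_remove=5, n_surrogates=100, rng=2)
        assert len(res.removals) == 0

    def test_excluded_never_pruned(self):
        grp = SynchrofactGroup(members=(1, 2, 3, 4), rate_hz=2.0)
        raster, _ = generate_crossing_raster(
            8, 30.0, background_rate_hz=2.0, groups=(grp,), seed=18)
        snr = {e: (0.5 if e == 1 else 5.0) for e in range(1, 9)}
        res = iterative_removal(raster, max_remove=5, n_surrogates=100,
                                snr=snr, rng=3)
        assert 1 not in res.removed_ids
        assert 1 in res.excluded.electrode.to_numpy()

    def test_max_remove_too_large_rejected(self):
        raster, _ = generate_crossing_raster(4, 5.0, seed=19)
        with pytest.raises(ConfigurationError):
            iterative_removal(raster, max_remove=4, n_surrogates=5, rng=0)

    def test_sp_in_unit_interval(self):
        grp = SynchrofactGroup(members=(1, 2, 3), rate_hz=1.0)
        raster, _ = generate_crossing_raster(
            8, 20.0, background_rate_hz=3.0, groups=(grp,), seed=20)
        flags = surrogate_test(raster, n_surrogates=50, rng=4)
        sp = compute_sp(raster, flags)
        assert ((sp.sp >= 0) & (sp.sp <= 1)).all()
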