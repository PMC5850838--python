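import numpy as np
import pytest

from propagule import coalsim as cs
from propagule import demography as dg
from propagule import rates as rt


@pytest.fixture(scope="module")
def disc16():
    return rt.TimeDiscretization.default(k=16)


@pytest.fixture(scope="module")
def const_tracks(const_scenario):
    """Het tracks of two island pseudo-diploids on 2 x 3 Mb at Ne = 30 K."""
    layout = dg.GenomeLayout.reduced(2, 3_000_000)
    scen = const_scenario.replace(layout=layout)
    panel = cs.simulate_genome(scen, 6, 2, seed=11)
    pairs = cs.make_pseudo_diploids(panel, "island", 1)[:2]
    tracks = []
    for p in pairs:
        tracks.extend(cs.het_windows(panel, p, 100).values())
    return tracks


class TestTimeDiscretization:
    def test_default_shape(self):
        d = rt.TimeDiscretization.default(k=32)
        assert d.k == 32
        assert d.boundaries[0] == 0
        assert np.isinf(d.boundaries[-1])
        assert d.midpoints.size == 32

    def test_validation(self):
        with pytest.raises(ValueError):
            rt.TimeDiscretization(np.array([0.0, 2.0, 1.0, np.inf]))
        with pytest.raises(ValueError):
            rt.TimeDiscretization(np.array([1.0, 2.0, np.inf]))


class TestRatesFromGenealogies:
    def test_constant_ne_rate_recovered(self, disc16):
        scen = dg.build_baseline().replace(
            island=dg.NeTrajectory.constant(10_000),
            mainland=dg.NeTrajectory.constant(10_000),
            split_time=1e7,
        )
        t = cs.sample_pair_times(scen, "within-island", 100_000, seed=1)
        curve = rt.rates_from_genealogies(t, disc16)
        well = curve.events > 200
        assert np.all(np.abs(curve.lam[well] / 5e-5 - 1) < 0.1)

    def test_all_times_in_one_bin(self, disc16):
        curve = rt.rates_from_genealogies(np.full(500, 1500.0), disc16)
        j = int(disc16.bin_of(1500.0))
        assert curve.lam[j] > 0
        # no events beyond that bin; more recent bins have exposure but 0 events
        assert np.nansum(curve.events) == 500
        assert np.all(np.isnan(curve.lam[j + 1 :]))
        assert np.all(curve.lam[:j] == 0)

    def test_cross_rate_zero_before_split(self, disc16):
        scen = dg.build_baseline()
        t = cs.sample_pair_times(scen, "cross", 50_000, seed=2)
        curve = rt.rates_from_genealogies(t, disc16)
        split_g = scen.split_time
        recent = disc16.boundaries[1:] <= split_g
        assert np.all(curve.lam[recent[: disc16.k]] == 0)

    def test_empty_input(self, disc16):
        with pytest.raises(ValueError):
            rt.rates_from_genealogies([], disc16)

    def test_oracle_recovers_piecewise_trajectory(self):
        """CI-style coverage: empirical hazard tracks 1/(2 Ne(t)) for a
        piecewise trajectory."""
        traj = dg.NeTrajectory.from_anchors(
            [(1.0, 20_000), (5e4, 20_000), (5.0001e4, 5_000), (2e5, 5_000)]
        )
        scen = dg.build_baseline().replace(
            island=traj, mainland=traj, split_time=1e7
        )
        t = cs.sample_pair_times(scen, "within-island", 200_000, seed=3)
        disc = rt.TimeDiscretization(
            np.array([0, 1e4, 2.5e4, 4e4, 6e4, 9e4, 1.4e5, np.inf])
        )
        curve = rt.rates_from_genealogies(t, disc)
        hz = cs.PairHazard.from_trajectory(traj, ())
        checked = 0
        for j in range(disc.k):
            left, right = disc.boundaries[j], disc.boundaries[j + 1]
            if curve.events[j] < 100 or not np.isfinite(right):
                continue
            if not np.isclose(float(hz.size(left)), float(hz.size(right - 1))):
                continue  # bin straddles the size change: hazard is a mixture
            assert curve.lam[j] == pytest.approx(
                1.0 / (2.0 * float(hz.size(disc.midpoints[j]))), rel=0.25
            )
            checked += 1
        assert checked >= 4


class TestAggregateCI:
    def test_identical_values(self):
        assert rt.aggregate_ci([1, 1, 1]) == (1.0, 0.0)

    def test_hand_arithmetic(self):
        mean, half = rt.aggregate_ci([0, 2])
        assert mean == pytest.approx(1.0)
        assert half == pytest.approx(1.96)  # sd = sqrt(2), SE = 1

    def test_permutation_invariance(self, rng):
        v = rng.normal(size=20)
        a, b = rt.aggregate_ci(v), rt.aggregate_ci(v[::-1])
        assert a == pytest.approx(b)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            rt.aggregate_ci([1.0])


class TestCrossCoalescence:
    def test_equal_rates_give_one(self, disc16):
        lam = np.full(disc16.k, 1e-5)
        c = rt.CoalRateCurve(disc16, lam)
        ccr = rt.cross_coalescence(c, c, c)
        assert ccr.values == pytest.approx(np.ones(disc16.k))

    def test_zero_cross_gives_zero(self, disc16):
        w = rt.CoalRateCurve(disc16, np.full(disc16.k, 1e-5))
        x = rt.CoalRateCurve(disc16, np.zeros(disc16.k))
        assert rt.cross_coalescence(w, w, x).values == pytest.approx(0.0)

    def test_scale_invariance(self, disc16, rng):
        lam = rng.uniform(1e-6, 1e-4, size=(3, disc16.k))
        curves = [rt.CoalRateCurve(disc16, l) for l in lam]
        base = rt.cross_coalescence(*curves).values
        scaled = rt.cross_coalescence(*[c.scaled(7.3) for c in curves]).values
        assert scaled == pytest.approx(base)

    def test_mismatched_discretizations(self, disc16):
        other = rt.TimeDiscretization.default(k=8)
        a = rt.CoalRateCurve(disc16, np.full(disc16.k, 1e-5))
        b = rt.CoalRateCurve(other, np.full(other.k, 1e-5))
        with pytest.raises(ValueError):
            rt.cross_coalescence(a, a, b)

    def test_nan_propagates(self, disc16):
        lam = np.full(disc16.k, 1e-5)
        lam[3] = np.nan
        w = rt.CoalRateCurve(disc16, lam)
        x = rt.CoalRateCurve(disc16, np.full(disc16.k, 1e-5))
        assert np.isnan(rt.cross_coalescence(w, w, x).values[3])

    def test_oracle_step_for_clean_split(self, disc16):
        scen = dg.build_baseline()
        curves = {}
        for i, pc in enumerate(cs.PAIR_CLASSES):
            t = cs.sample_pair_times(scen, pc, 100_000, seed=20 + i)
            curves[pc] = rt.rates_from_genealogies(t, disc16)
        ccr = rt.cross_coalescence(
            curves["within-island"], curves["within-mainland"], curves["cross"]
        )
        split_bin = int(disc16.bin_of(scen.split_time))
        recent = ccr.values[2:split_bin]
        ancient = ccr.values[split_bin + 1 : split_bin + 4]
        assert np.nanmax(recent) < 0.1
        assert np.nanmin(ancient) > 0.8


class TestSmoothing:
    def test_constant_input_stays_constant(self, disc16):
        c = rt.CCRCurve(disc16, np.full(disc16.k, 0.42))
        sm = rt.smooth_curve(c)
        t = np.geomspace(1e3, 1e6, 30)
        assert sm(t) == pytest.approx(0.42)

    def test_monotone_input_no_overshoot(self, disc16):
        v = np.linspace(0, 1, disc16.k) ** 2
        sm = rt.smooth_curve(rt.CCRCurve(disc16, v))
        t = np.geomspace(disc16.midpoints[0], disc16.midpoints[-1], 300)
        y = sm(t)
        assert y.min() >= -1e-9 and y.max() <= 1 + 1e-9
        assert np.all(np.diff(y) >= -1e-9)  # shape preserving

    def test_single_curve_median_is_value(self, disc16):
        v = np.linspace(0.1, 0.9, disc16.k)
        sm = rt.smooth_curve(rt.CCRCurve(disc16, v))
        assert sm(disc16.midpoints[5]) == pytest.approx(v[5], abs=1e-9)

    def test_too_few_bins_warns(self, disc16):
        v = np.full(disc16.k, np.nan)
        v[3:6] = 0.5
        with pytest.warns(UserWarning):
            sm = rt.smooth_curve(rt.CCRCurve(disc16, v))
        assert not sm.smoothed


class TestEstimateSplitTime:
    def test_step_curve_collapses_to_step(self):
        times = np.geomspace(1e3, 1e6, 40)
        vals = np.where(times < 8e4, 0.0, 1.0)
        sm = rt.SmoothedCurve(times, vals, smoothed=False)
        est = rt.estimate_split_time(sm, (0.70, 0.75))
        assert est.conclusive
        assert est.upper / est.lower < 1.2
        assert est.expected == pytest.approx(8e4, rel=0.2)

    def test_identically_one_inconclusive(self):
        times = np.geomspace(1e3, 1e6, 40)
        sm = rt.SmoothedCurve(times, np.ones(40), smoothed=False)
        assert not rt.estimate_split_time(sm, (0.70, 0.75)).conclusive

    def test_oracle_ccr_crossing_near_split(self, disc16):
        scen = dg.build_baseline()
        curves = []
        for i, pc in enumerate(cs.PAIR_CLASSES):
            t = cs.sample_pair_times(scen, pc, 100_000, seed=30 + i)
            curves.append(rt.rates_from_genealogies(t, disc16))
        ccr = rt.cross_coalescence(curves[0], curves[1], curves[2])
        sm = rt.smooth_curve(ccr)
        at_split = sm(scen.split_time)
        assert 0.0 < at_split < 1.0
        est = rt.estimate_split_time(sm, (0.3, 0.7))
        assert est.conclusive
        assert est.expected == pytest.approx(scen.split_time, rel=0.35)


class TestPairwiseSMC:
    def test_recovers_constant_ne(self, const_tracks, disc16):
        curve, info = rt.infer_pairwise_smc(
            const_tracks, disc16, mu=7.1e-9, rho=3.6e-8 * 0.02, window=100
        )
        mids = disc16.midpoints
        sel = (mids > 8e3) & (mids < 2e5)  # well-resolved middle intervals
        assert np.median(curve.ne[sel]) == pytest.approx(30_000, rel=0.25)

    def test_loglik_monotone(self, const_tracks, disc16):
        _, info = rt.infer_pairwise_smc(
            const_tracks, disc16, mu=7.1e-9, rho=3.6e-8 * 0.02, window=100
        )
        ll = np.array(info["loglik"])
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_pair_order_symmetry(self, const_scenario, disc16):
        panel = cs.simulate_genome(const_scenario, 2, 1, seed=77)
        t_ab = cs.het_windows(panel, (0, 1), 100)
        t_ba = cs.het_windows(panel, (1, 0), 100)
        for c in t_ab:
            assert np.array_equal(t_ab[c], t_ba[c])
        a, _ = rt.infer_pairwise_smc(list(t_ab.values()), disc16, 7.1e-9, 7.2e-10)
        b, _ = rt.infer_pairwise_smc(list(t_ba.values()), disc16, 7.1e-9, 7.2e-10)
        assert a.lam == pytest.approx(b.lam)

    def test_zero_heterozygosity_flagged(self, disc16):
        tracks = [np.zeros(5000, dtype=np.uint8)]
        curve, info = rt.infer_pairwise_smc(tracks, disc16, 7.1e-9, 7.2e-10)
        assert info["low_information"]
        # posterior mass check: the fitted rates put essentially all
        # coalescence probability in the most recent interval
        survival_past_first = np.exp(-curve.lam[0] * disc16.boundaries[1])
        assert survival_past_first < 0.01

    def test_bad_mu(self, disc16):
        with pytest.raises(ValueError):
            rt.infer_pairwise_smc([np.zeros(10, dtype=np.uint8)], disc16, mu=0)


class TestCalibration:
    def test_input_validation(self):
        base = dg.build_baseline()
        with pytest.raises(ValueError):
            rt.calibrate_ccr_threshold([85.4e3], base, n_reps=2)
        with pytest.raises(ValueError):
            rt.calibrate_ccr_threshold([50e3, 85.4e3], base, n_reps=1)

    def test_recent_split_decays_more_steeply(self):
        """Genealogy-oracle check of the calibration property: the more
        recent the split, the steeper the CCR decay at the split."""
        disc = rt.TimeDiscretization.default(k=32)
        slopes = {}
        for split in (37e3, 160e3):
            scen = dg.build_baseline().replace(split_time=split)
            curves = []
            for i, pc in enumerate(cs.PAIR_CLASSES):
                t = cs.sample_pair_times(scen, pc, 80_000, seed=50 + i)
                curves.append(rt.rates_from_genealogies(t, disc))
            sm = rt.smooth_curve(rt.cross_coalescence(*curves))
            eps = 0.08 * split
            slopes[split] = (sm(split + eps) - sm(split - eps)) / (2 * eps)
        assert slopes[37e3] > slopes[160e3] > 0
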