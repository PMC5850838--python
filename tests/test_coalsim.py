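import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp, spearmanr

from propagule import coalsim as cs
from propagule import demography as dg


def _hazard_scenarios():
    base = dg.build_baseline()
    bn = dg.BottleneckSpec(onset_time=50e3, duration=200, severity=0.8)
    smooth = dg.BottleneckSpec(
        onset_time=40e3, duration=20_000, severity=1.5, recovery="smooth"
    )
    return [
        ("baseline", base.island, ()),
        ("bottleneck", dg.NeTrajectory.constant(25_000), (bn,)),
        ("smooth-recovery", base.island, (smooth,)),
    ]


class TestPairHazard:
    @pytest.mark.parametrize(
        "name, traj, bns", _hazard_scenarios(), ids=[s[0] for s in _hazard_scenarios()]
    )
    def test_cumulative_hazard_matches_numerical_integration(self, name, traj, bns):
        hz = cs.PairHazard.from_trajectory(traj, bns, generation_time=1.0)

        def rate(t):
            return 1.0 / (2.0 * hz.size(t))

        for t in (5e3, 3.3e4, 4.97e4, 7e4, 3e5, 2.5e6):
            # integrate piecewise so narrow bottleneck spikes are not missed
            edges = [e for e in hz.t0 if 0 < e < t] + [t]
            lo, expected = 0.0, 0.0
            for hi in sorted(edges):
                expected += quad(rate, lo, hi, limit=400)[0]
                lo = hi
            assert hz.cumhaz(t) == pytest.approx(expected, rel=2e-3)

    def test_inverse_is_inverse(self):
        hz = cs.PairHazard.from_trajectory(dg.build_baseline().island, ())
        t = np.geomspace(10, 1e6, 50)
        assert hz.inv_cumhaz(hz.cumhaz(t)) == pytest.approx(t, rel=1e-8)


class TestSamplePairTimes:
    def test_constant_ne_mean_is_2ne(self):
        scen = dg.build_baseline().replace(
            island=dg.NeTrajectory.constant(10_000),
            mainland=dg.NeTrajectory.constant(10_000),
            split_time=1e7,  # effectively a single population
        )
        t = cs.sample_pair_times(scen, "within-island", 100_000, seed=1)
        se = 2 * 10_000 / np.sqrt(t.size)  # exponential: sd == mean
        assert t.mean() == pytest.approx(20_000, abs=4 * se)

    def test_cross_pairs_never_coalesce_before_split(self):
        scen = dg.build_baseline()
        t = cs.sample_pair_times(scen, "cross", 20_000, seed=2)
        assert t.min() >= scen.split_time / scen.generation_time

    def test_invalid_pair_class(self):
        with pytest.raises(ValueError):
            cs.sample_pair_times(dg.build_baseline(), "sideways", 10)

    def test_bottleneck_coalescence_probability(self):
        """Of the pairs uncoalesced when the bottleneck starts, a fraction
        1 - exp(-severity/2) (plus the background hazard over the interval)
        coalesces during it; checked against numerical hazard integration."""
        sev, dur = 0.5, 100.0
        bn = dg.BottleneckSpec(onset_time=50e3, duration=dur, severity=sev)
        scen = dg.build_baseline().replace(
            island=dg.NeTrajectory.constant(30_000),
            mainland=dg.NeTrajectory.constant(30_000),
            bottlenecks=(bn,),
        )
        t = cs.sample_pair_times(scen, "within-island", 200_000, seed=3)
        lo, hi = 50e3 - dur, 50e3
        at_risk = t >= lo
        frac = ((t >= lo) & (t < hi)).sum() / at_risk.sum()
        hz = cs.PairHazard.from_trajectory(scen.island, (bn,))
        integral = quad(lambda x: 1.0 / (2 * hz.size(x)), lo, hi, limit=400)[0]
        expected = 1.0 - np.exp(-integral)
        assert integral == pytest.approx(sev / 2, rel=0.02)
        assert frac == pytest.approx(expected, abs=0.01)

    def test_migration_pulse_allows_early_cross_coalescence(self):
        pulse = dg.MigrationPulse(time=50e3, fraction=0.5)
        scen = dg.build_baseline().replace(pulses=(pulse,))
        t = cs.sample_pair_times(scen, "cross", 50_000, seed=4)
        early = t < scen.split_time
        # pulsed lineages may coalesce between the pulse and the split
        assert 0 < early.sum() < t.size
        assert t[early].min() >= pulse.time

    @pytest.mark.parametrize("pair_class", ["within-island", "cross"])
    def test_matches_coalescent_engine_in_distribution(self, pair_class):
        scen = dg.build_baseline()
        ours = cs.sample_pair_times(scen, pair_class, 4000, seed=11)
        engine = cs.sample_pair_times_engine(scen, pair_class, 4000, seed=12)
        assert ks_2samp(ours, engine).pvalue > 0.01


class TestSimulateGenome:
    def test_deterministic_given_seed(self, baseline_small):
        a = cs.simulate_genome(baseline_small, 3, 3, seed=42)
        b = cs.simulate_genome(baseline_small, 3, 3, seed=42)
        for c in a.chromosomes:
            assert np.array_equal(a.positions[c], b.positions[c])
            assert np.array_equal(a.genotypes[c], b.genotypes[c])

    def test_pair_diversity_matches_expectation(self, const_layout):
        """A haploid pair at constant Ne: E[pi per bp] = 4*Ne*mu."""
        scen = dg.build_baseline(layout=const_layout).replace(
            island=dg.NeTrajectory.constant(30_000),
            mainland=dg.NeTrajectory.constant(30_000),
        )
        diffs = []
        for seed in (7, 8, 9, 10):
            p = cs.simulate_genome(scen, 2, 1, seed=seed)
            i0, i1 = p.deme_indices("island")
            d = sum(
                (p.genotypes[c][i0] != p.genotypes[c][i1]).sum()
                for c in p.chromosomes
            )
            diffs.append(d / p.total_length)
        expected = 4 * 30_000 * 7.1e-9
        assert np.mean(diffs) == pytest.approx(expected, rel=0.35)

    def test_site_conservation(self, small_panel):
        """Every genotype column is a segregating site and counts match."""
        for c in small_panel.chromosomes:
            g = small_panel.genotypes[c]
            assert g.shape[1] == small_panel.positions[c].size
            assert g.any(axis=0).all()

    def test_variable_mu_orders_diversity(self):
        layout = dg.GenomeLayout(
            tuple(
                dg.Chromosome(str(i + 1), 400_000, float(m), 3.6e-8)
                for i, m in enumerate(np.linspace(2.2e-9, 7.1e-9, 5))
            ),
            outcrossing=0.02,
        )
        scen = dg.build_baseline(layout=layout).replace(
            island=dg.NeTrajectory.constant(30_000),
            mainland=dg.NeTrajectory.constant(30_000),
        )
        per_chrom = np.zeros(5)
        for seed in (21, 22, 23):
            p = cs.simulate_genome(scen, 6, 2, seed=seed)
            for i, c in enumerate(p.chromosomes):
                per_chrom[i] += p.positions[c].size
        rho = spearmanr(np.arange(5), per_chrom).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(dg.ConfigError):
            dg.Chromosome("1", 0, 7.1e-9, 3.6e-8)


class TestPseudoDiploids:
    @pytest.mark.parametrize("n, expected_pairs", [(11, 6), (18, 9), (2, 1)])
    def test_pair_counts(self, n, expected_pairs):
        panel = _toy_panel(n_island=n)
        pairs = cs.make_pseudo_diploids(panel, "island", pairing_seed=0)
        assert len(pairs) == expected_pairs
        counts = np.bincount([h for p in pairs for h in p])
        if n % 2 == 1:
            assert sorted(counts[counts > 0])[-1] == 2
            assert (counts == 2).sum() == 1  # one haplotype reused exactly once
        else:
            assert set(counts[counts > 0]) == {1}

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError):
            cs.make_pseudo_diploids(_toy_panel(n_island=1), "island")

    def test_cross_pairs_draw_one_per_deme(self, small_panel):
        pairs = cs.cross_pairs(small_panel, n_pairs=3, seed=1)
        for i, j in pairs:
            assert small_panel.demes[i] == "island"
            assert small_panel.demes[j] == "mainland"


def _toy_panel(n_island=4, n_mainland=2, n_sites=5, length=1000):
    rng = np.random.default_rng(0)
    n = n_island + n_mainland
    g = rng.integers(0, 2, size=(n, n_sites), dtype=np.int8)
    g[0, :] = 1  # keep every column segregating
    pos = np.sort(rng.choice(np.arange(1, length), size=n_sites, replace=False))
    demes = np.array(["island"] * n_island + ["mainland"] * n_mainland)
    return cs.HaplotypePanel(["1"], {"1": length}, {"1": pos}, {"1": g}, demes)


class TestPanelValidation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cs.HaplotypePanel(
                ["1"],
                {"1": 100},
                {"1": np.array([1, 2])},
                {"1": np.zeros((3, 3), dtype=np.int8)},
                np.array(["island"] * 3),
            )

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            cs.HaplotypePanel(
                ["1"],
                {"1": 100},
                {"1": np.array([5, 2])},
                {"1": np.ones((2, 2), dtype=np.int8)},
                np.array(["island"] * 2),
            )

    def test_subset_drops_monomorphic_columns(self, small_panel):
        sub = small_panel.subset(small_panel.deme_indices("island"))
        for c in sub.chromosomes:
            assert sub.genotypes[c].any(axis=0).all()


class TestScenarioGrid:
    def test_split_scan_range(self):
        scans = cs.scenario_grid("split-scan")
        times = [s.split_time for s in scans]
        assert min(times) == pytest.approx(37e3)
        assert max(times) == pytest.approx(200e3)

    def test_dual_migration_defaults(self):
        scans = cs.scenario_grid("dual-migration")
        for s in scans:
            assert s.split_time == pytest.approx(85.4e3)
            (pulse,) = s.pulses
            assert pulse.fraction == pytest.approx(0.5)
            assert 36.6e3 <= pulse.time <= 64e3

    def test_variable_mu_range(self):
        (scen,) = cs.scenario_grid("variable-mu")
        mus = [c.mutation_rate for c in scen.layout.chromosomes]
        assert min(mus) == pytest.approx(2.2e-9)
        assert max(mus) == pytest.approx(7.1e-9)

    def test_bottleneck_scan_ranges(self):
        scans = cs.scenario_grid("bottleneck-scan")
        sevs = {b.severity for s in scans for b in s.bottlenecks}
        durs = {b.duration for s in scans for b in s.bottlenecks}
        assert min(sevs) == pytest.approx(0.1)
        assert max(sevs) == pytest.approx(2.0)
        assert min(durs) == pytest.approx(10)
        assert max(durs) == pytest.approx(30_000)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            cs.scenario_grid("upside-down")
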