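"""Synthetic-data generator for the two-deme colonization model.

Two modes:

* **genealogy mode** (`sample_pair_times`): i.i.d. pair-coalescence times at
  independent loci, drawn from the exact hazard implied by a scenario
  (1/(2*Ne(t)) per generation for a pair in the same deme, 0 for a cross pair
  more recently than the split, bottlenecks folded into the hazard).  This is
  implemented from scratch with closed-form cumulative hazards and serves as
  the oracle for everything downstream.

* **sequence mode** (`simulate_genome`): recombining chromosomes with
  mutations, via the msprime coalescent engine, returning a haploid 0/1
  genotype panel (0 = ancestral).

Convention: all sampled genomes are haploid lineages (inbred accessions
approximated as haploids) and the pair-coalescence hazard within a deme of
size Ne is 1/(2*Ne) per generation.  msprime is therefore run with ploidy=1
and population sizes of 2*Ne, which realises exactly this hazard.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np

from .demography import (
    BottleneckSpec,
    ConfigError,
    DemographicScenario,
    GenomeLayout,
    MigrationPulse,
    NeTrajectory,
    build_baseline,
)

__all__ = [
    "PAIR_CLASSES",
    "PairHazard",
    "HaplotypePanel",
    "sample_pair_times",
    "simulate_genome",
    "make_pseudo_diploids",
    "cross_pairs",
    "het_windows",
    "scenario_grid",
]

PAIR_CLASSES = ("within-island", "within-mainland", "cross")


# ---------------------------------------------------------------------------
# closed-form piecewise-exponential hazard
# ---------------------------------------------------------------------------


class PairHazard:
    """Pair-coalescence hazard 1/(2*N(t)) for a piecewise-exponential size
    function N(t) (in generations), with closed-form cumulative hazard and
    inverse -- the machinery behind genealogy-mode sampling.

    Segments are half-open intervals [t0, t1) on which
    ``N(t) = N0 * exp(beta * (t - t0))``; the last segment extends to
    infinity at constant size.
    """

    def __init__(self, t0, t1, n0, n1):
        self.t0 = np.asarray(t0, dtype=float)
        self.t1 = np.asarray(t1, dtype=float)
        self.n0 = np.asarray(n0, dtype=float)
        self.n1 = np.asarray(n1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            span = self.t1 - self.t0
            self.beta = np.where(
                np.isfinite(span) & (span > 0),
                np.log(self.n1 / self.n0) / np.where(span > 0, span, 1.0),
                0.0,
            )
        # cumulative hazard at segment starts
        seg = self._segment_hazard(self.t1 - self.t0)
        seg[-1] = np.inf
        self.cum = np.concatenate([[0.0], np.cumsum(seg)])

    def _segment_hazard(self, s):
        """Integral of 1/(2 N(t)) over the first ``s`` generations of each
        segment: (1 - exp(-beta s)) / (2 N0 beta), with the beta -> 0 limit
        s / (2 N0)."""
        s = np.asarray(s, dtype=float)
        out = np.empty_like(self.n0)
        b = self.beta
        small = np.abs(b * np.where(np.isfinite(s), s, 0.0)) < 1e-12
        with np.errstate(over="ignore", invalid="ignore"):
            out = np.where(
                small,
                np.where(np.isfinite(s), s, np.inf) / (2 * self.n0),
                -np.expm1(-b * s) / (2 * self.n0 * np.where(b == 0, 1.0, b)),
            )
        return out

    @classmethod
    def from_trajectory(
        cls,
        traj: NeTrajectory,
        bottlenecks: tuple[BottleneckSpec, ...] = (),
        generation_time: float = 1.0,
    ) -> "PairHazard":
        gt = generation_time
        anchors_g = traj.times / gt
        # override intervals (constant bottleneck size, optional smooth ramp)
        overrides = []  # (lo, hi, kind, payload)
        for b in bottlenecks:
            hi = b.onset_time / gt
            lo = hi - b.duration
            overrides.append((lo, hi, "const", b.size))
            if b.recovery == "smooth":
                span = b.recovery_span / gt
                r_lo = max(0.0, lo - span)
                if r_lo < lo:
                    n_bg = float(traj.ne(r_lo * gt))
                    overrides.append((r_lo, lo, "ramp", (n_bg, b.size)))
        overrides.sort()
        for (a_lo, a_hi, *_), (b_lo, b_hi, *_) in zip(overrides, overrides[1:]):
            if b_lo < a_hi - 1e-9:
                raise ConfigError("overlapping bottleneck intervals")

        breaks = {0.0}
        breaks.update(float(a) for a in anchors_g)
        for lo, hi, *_ in overrides:
            breaks.update((float(lo), float(hi)))
        edges = np.array(sorted(b for b in breaks if b >= 0.0))

        def value(t, side):
            """Size at time t; `side` breaks ties at override edges."""
            for lo, hi, kind, payload in overrides:
                inside = (lo < t < hi) or (t == lo and side == "right") or (
                    t == hi and side == "left"
                )
                if inside:
                    if kind == "const":
                        return float(payload)
                    n_lo, n_hi = payload
                    f = (t - lo) / (hi - lo)
                    return float(n_lo * (n_hi / n_lo) ** f)
            return float(traj.ne(t * gt))

        t0, t1, n0, n1 = [], [], [], []
        for a, b_edge in zip(edges, edges[1:]):
            if b_edge - a <= 0:
                continue
            t0.append(a)
            t1.append(b_edge)
            n0.append(value(a, "right"))
            n1.append(value(b_edge, "left"))
        # final, constant, unbounded segment
        last = edges[-1]
        t0.append(last)
        t1.append(np.inf)
        n_last = value(last, "right")
        n0.append(n_last)
        n1.append(n_last)
        return cls(t0, t1, n0, n1)

    # -- evaluation --------------------------------------------------------

    def _segment_index(self, t):
        return np.clip(np.searchsorted(self.t0, t, side="right") - 1, 0, len(self.t0) - 1)

    def size(self, t):
        t = np.asarray(t, dtype=float)
        i = self._segment_index(t)
        return self.n0[i] * np.exp(self.beta[i] * (t - self.t0[i]))

    def cumhaz(self, t):
        """Cumulative pair-coalescence hazard from 0 to t (generations)."""
        t = np.asarray(t, dtype=float)
        i = self._segment_index(t)
        s = t - self.t0[i]
        b = self.beta[i]
        n0 = self.n0[i]
        small = np.abs(b * s) < 1e-12
        with np.errstate(over="ignore"):
            part = np.where(
                small, s / (2 * n0), -np.expm1(-b * s) / (2 * n0 * np.where(b == 0, 1.0, b))
            )
        return self.cum[i] + part

    def inv_cumhaz(self, h):
        """Inverse of `cumhaz` (vectorized); h may be any positive value."""
        h = np.asarray(h, dtype=float)
        i = np.clip(np.searchsorted(self.cum, h, side="right") - 1, 0, len(self.t0) - 1)
        dh = h - self.cum[i]
        b = self.beta[i]
        n0 = self.n0[i]
        small = np.abs(b) < 1e-300
        with np.errstate(invalid="ignore", divide="ignore"):
            arg = 1.0 - 2.0 * n0 * b * dh
            s_exp = -np.log(np.clip(arg, 1e-300, None)) / np.where(b == 0, 1.0, b)
        s = np.where(small, 2.0 * n0 * dh, s_exp)
        return self.t0[i] + s


# ---------------------------------------------------------------------------
# genealogy mode
# ---------------------------------------------------------------------------


def sample_pair_times(
    scenario: DemographicScenario,
    pair_class: str,
    n_loci: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw i.i.d. pair-coalescence times (generations) at independent loci.

    A pair in the same deme coalesces at hazard 1/(2*Ne(t)) per generation;
    a cross pair cannot coalesce more recently than the split; migration
    pulses move island lineages into the mainland deme with the stated
    probability; bottlenecks multiply the island hazard through the size
    function.
    """
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}; use one of {PAIR_CLASSES}")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    gt = scenario.generation_time
    split_g = scenario.split_time / gt

    island = PairHazard.from_trajectory(scenario.island, scenario.bottlenecks, gt)
    mainland = PairHazard.from_trajectory(scenario.mainland, (), gt)

    li = np.full(
        n_loci,
        {"within-island": 2, "cross": 1, "within-mainland": 0}[pair_class],
        dtype=np.int8,
    )
    t_coal = np.full(n_loci, np.nan)

    events: list[tuple[float, str, float]] = [
        (p.time / gt, "pulse", p.fraction) for p in scenario.pulses
    ]
    events.sort()
    events.append((split_g, "split", 1.0))
    events.append((np.inf, "end", 0.0))

    a = 0.0
    for when, kind, frac in events:
        active = np.isnan(t_coal)
        for count, hz in ((2, island), (0, mainland)):
            m = active & (li == count)
            if not np.any(m):
                continue
            e = rng.exponential(size=int(m.sum()))
            t_c = hz.inv_cumhaz(hz.cumhaz(a) + e)
            hit = t_c < when
            idx = np.where(m)[0][hit]
            t_coal[idx] = t_c[hit]
        if kind == "end":
            break
        active = np.isnan(t_coal)
        if kind == "pulse":
            two = active & (li == 2)
            if np.any(two):
                moved = rng.random((int(two.sum()), 2)) < frac
                li[two] -= moved.sum(axis=1).astype(np.int8)
            one = active & (li == 1)
            if np.any(one):
                li[np.where(one)[0][rng.random(int(one.sum())) < frac]] = 0
        elif kind == "split":
            li[active] = 0
        a = when
    return t_coal


def sample_pair_times_engine(
    scenario: DemographicScenario,
    pair_class: str,
    n_loci: int,
    seed: int | None = None,
) -> np.ndarray:
    """Pair coalescence times from the msprime engine (one-locus replicates,
    no recombination) -- the independent cross-check for genealogy mode."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}")
    samples = {
        "within-island": {"island": 2, "mainland": 0},
        "within-mainland": {"island": 0, "mainland": 2},
        "cross": {"island": 1, "mainland": 1},
    }[pair_class]
    dem = _msprime_demography(scenario)
    out = np.empty(n_loci)
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        ploidy=1,
        sequence_length=1,
        num_replicates=n_loci,
        random_seed=None if seed is None else max(int(seed), 1),
    )
    for i, ts in enumerate(reps):
        tree = ts.first()
        out[i] = tree.time(tree.root)
    return out


# ---------------------------------------------------------------------------
# sequence mode
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Segregating-site tables for a set of haploid genomes.

    ``genotypes[chrom]`` is an (n_haplotypes, n_sites) 0/1 matrix, 0 being the
    ancestral allele; ``positions[chrom]`` are 1-based bp coordinates,
    strictly increasing.  ``demes`` labels each haplotype ("island" or
    "mainland").
    """

    chromosomes: list[str]
    lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    demes: np.ndarray
    polarized: bool = True

    def __post_init__(self):
        self.demes = np.asarray(self.demes)
        n = self.n_haplotypes
        for c in self.chromosomes:
            pos = np.asarray(self.positions[c])
            g = np.asarray(self.genotypes[c])
            if g.shape != (n, pos.size):
                raise ValueError(f"chromosome {c}: genotype/position shape mismatch")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"chromosome {c}: positions must be strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > self.lengths[c]):
                raise ValueError(f"chromosome {c}: positions outside [1, length]")
            if g.size and not np.isin(g, (0, 1)).all():
                raise ValueError(f"chromosome {c}: genotypes must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return int(self.demes.size)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths[c] for c in self.chromosomes))

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(self.positions[c].size for c in self.chromosomes))

    def deme_indices(self, deme: str) -> np.ndarray:
        return np.where(self.demes == deme)[0]

    def subset(self, indices) -> "HaplotypePanel":
        """Panel restricted to a haplotype subset; sites monomorphic in the
        subset are dropped (they are no longer segregating)."""
        indices = np.asarray(indices)
        pos, gen = {}, {}
        for c in self.chromosomes:
            g = self.genotypes[c][indices]
            # fixed-derived columns stay (informative under polarization);
            # all-ancestral columns are no longer sites
            keep = g.any(axis=0)
            pos[c] = self.positions[c][keep]
            gen[c] = g[:, keep]
        return HaplotypePanel(
            list(self.chromosomes),
            dict(self.lengths),
            pos,
            gen,
            self.demes[indices],
            self.polarized,
        )


def _msprime_demography(scenario: DemographicScenario) -> msprime.Demography:
    """Translate a scenario into an msprime demography (ploidy-1 convention:
    population sizes are 2*Ne so a pair coalesces at rate 1/(2*Ne))."""
    gt = scenario.generation_time
    dem = msprime.Demography()
    for name, traj, bns in (
        ("island", scenario.island, scenario.bottlenecks),
        ("mainland", scenario.mainland, ()),
    ):
        hz = PairHazard.from_trajectory(traj, bns, gt)
        dem.add_population(
            name=name,
            initial_size=2.0 * hz.n0[0],
            growth_rate=-hz.beta[0],
        )
        for t0, n0, beta in zip(hz.t0[1:], hz.n0[1:], hz.beta[1:]):
            dem.add_population_parameters_change(
                time=t0, initial_size=2.0 * n0, growth_rate=-beta, population=name
            )
    for p in scenario.pulses:
        dem.add_mass_migration(
            time=p.time / gt, source="island", dest="mainland", proportion=p.fraction
        )
    dem.add_mass_migration(
        time=scenario.split_time / gt, source="island", dest="mainland", proportion=1.0
    )
    dem.sort_events()
    return dem


def simulate_genome(
    scenario: DemographicScenario,
    n_island: int,
    n_mainland: int,
    seed: int | None = None,
) -> HaplotypePanel:
    """Simulate a recombining multi-chromosome genome panel under a scenario.

    Each chromosome is an independent coalescent simulation with its own
    mutation rate; recombination is the map rate scaled by the outcrossing
    factor.  Deterministic given ``seed``.
    """
    if n_island < 1 or n_mainland < 1:
        raise ValueError("sample sizes must be >= 1")
    for c in scenario.layout.chromosomes:
        if c.length <= 0:
            raise ConfigError(f"chromosome {c.name} has non-positive length")
    rng = np.random.default_rng(seed)
    dem = _msprime_demography(scenario)

    chroms, lengths, positions, genotypes = [], {}, {}, {}
    demes = None
    for chrom in scenario.layout.chromosomes:
        s_anc, s_mut = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples={"island": n_island, "mainland": n_mainland},
            demography=dem,
            ploidy=1,
            sequence_length=chrom.length,
            recombination_rate=scenario.layout.effective_recombination(chrom),
            random_seed=int(s_anc),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=chrom.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(s_mut),
            discrete_genome=True,
        )
        if demes is None:
            pop_names = {p.id: p.metadata["name"] for p in mts.populations()}
            demes = np.array(
                [pop_names[mts.node(u).population] for u in mts.samples()]
            )
        keep, pos = [], []
        for site in mts.sites():
            if len(site.mutations) == 1:  # drop multi-hit sites: clean 0/1 polarity
                keep.append(site.id)
                pos.append(int(site.position) + 1)
        g = mts.genotype_matrix()[keep].astype(np.int8)
        seg = g.any(axis=1)
        chroms.append(chrom.name)
        lengths[chrom.name] = int(chrom.length)
        positions[chrom.name] = np.array(pos, dtype=np.int64)[seg]
        genotypes[chrom.name] = g[seg].T
    return HaplotypePanel(chroms, lengths, positions, genotypes, demes, polarized=True)


# ---------------------------------------------------------------------------
# pseudo-diploids and heterozygosity tracks
# ---------------------------------------------------------------------------


def make_pseudo_diploids(
    panel: HaplotypePanel, deme: str, pairing_seed: int | None = None
) -> list[tuple[int, int]]:
    """Combine haploid genomes of one deme into pseudo-diploid pairs.

    With n haplotypes this yields ceil(n/2) pairs; with odd n one haplotype is
    reused exactly once (11 haplotypes -> 6 pairs).
    """
    idx = panel.deme_indices(deme)
    if idx.size < 2:
        raise ValueError(f"need at least 2 haplotypes in deme {deme!r}")
    rng = np.random.default_rng(pairing_seed)
    order = rng.permutation(idx)
    pairs = [(int(order[i]), int(order[i + 1])) for i in range(0, order.size - 1, 2)]
    if order.size % 2 == 1:
        pairs.append((int(order[-1]), int(order[0])))
    return pairs


def cross_pairs(
    panel: HaplotypePanel, n_pairs: int | None = None, seed: int | None = None
) -> list[tuple[int, int]]:
    """Pseudo-diploids drawing one haplotype per deme (cross pairs)."""
    isl = panel.deme_indices("island")
    mld = panel.deme_indices("mainland")
    if isl.size < 1 or mld.size < 1:
        raise ValueError("need haplotypes in both demes")
    rng = np.random.default_rng(seed)
    k = min(isl.size, mld.size) if n_pairs is None else n_pairs
    a = rng.permutation(isl)
    b = rng.permutation(mld)
    return [(int(a[i % a.size]), int(b[i % b.size])) for i in range(k)]


def het_windows(
    panel: HaplotypePanel, pair: tuple[int, int], window: int = 100
) -> dict[str, np.ndarray]:
    """Binarized heterozygosity track of a pseudo-diploid: one 0/1 value per
    ``window`` bp (1 if the two haplotypes differ at >= 1 site)."""
    i, j = pair
    out = {}
    for c in panel.chromosomes:
        n_win = int(np.ceil(panel.lengths[c] / window))
        track = np.zeros(n_win, dtype=np.uint8)
        het = panel.genotypes[c][i] != panel.genotypes[c][j]
        if het.any():
            w = (panel.positions[c][het] - 1) // window
            track[w] = 1
        out[c] = track
    return out


# ---------------------------------------------------------------------------
# scenario grids
# ---------------------------------------------------------------------------


def scenario_grid(kind: str, base: DemographicScenario | None = None, **params):
    """Families of perturbed scenarios used in the simulation studies.

    kinds: ``split-scan`` (split times 37-200 ka), ``bottleneck-scan``
    (duration 10-30,000 generations x severity 0.1-2.0 on a constant 30 K
    island), ``dual-migration`` (a 50% secondary pulse between 64.0 and
    36.6 ka), ``variable-mu`` (per-chromosome mutation rates spanning
    2.2e-9 to 7.1e-9).
    """
    base = base if base is not None else build_baseline()
    if kind == "split-scan":
        times = params.get("split_times")
        if times is None:
            times = np.geomspace(37e3, 200e3, int(params.get("n", 7)))
        return [
            base.replace(split_time=float(t), name=f"split-{t / 1e3:.1f}ka")
            for t in times
        ]
    if kind == "bottleneck-scan":
        durations = params.get("durations", np.geomspace(10, 30000, 4))
        severities = params.get("severities", (0.1, 0.5, 1.0, 2.0))
        onset = float(params.get("onset", 40e3))
        recovery = params.get("recovery", "instantaneous")
        island = NeTrajectory.constant(params.get("carrying", 30e3))
        out = []
        for d in durations:
            for s in severities:
                bn = BottleneckSpec(
                    onset_time=onset,
                    duration=float(round(d)),
                    severity=float(s),
                    recovery=recovery,
                )
                out.append(
                    base.replace(
                        island=island,
                        bottlenecks=(bn,),
                        name=f"bn-d{round(d)}-s{s}",
                    )
                )
        return out
    if kind == "dual-migration":
        times = params.get("pulse_times")
        if times is None:
            times = np.linspace(64e3, 36.6e3, int(params.get("n", 4)))
        frac = float(params.get("fraction", 0.5))
        return [
            base.replace(
                pulses=(MigrationPulse(time=float(t), fraction=frac),),
                name=f"dual-{t / 1e3:.1f}ka",
            )
            for t in times
        ]
    if kind == "variable-mu":
        layout = GenomeLayout.variable_mu(
            mu_min=float(params.get("mu_min", 2.2e-9)),
            mu_max=float(params.get("mu_max", 7.1e-9)),
            outcrossing=base.layout.outcrossing,
        )
        return [base.replace(layout=layout, name="variable-mu")]
    raise ValueError(f"unknown scenario grid kind {kind!r}")
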