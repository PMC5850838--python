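# Methods

`propagule` implements a simulation-based model-checking and inference
workflow for the colonization of an oceanic island by a selfing annual plant
(the motivating system is *Arabidopsis thaliana* on Madeira, colonized from
the Iberian ancestral stock). This note documents the models, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices.

## The demographic model

Two demes, island and mainland, each with an effective size trajectory
Ne(t). Trajectories are anchored point sets connected by exponential
interpolation (linear in log Ne) and constant beyond the anchored range. The
default anchor grid is 23 points evenly spaced on a log scale between 3 ka
and 2 Ma, the resolution at which sequentially-Markovian-coalescent output is
typically re-fitted into a simulable demography.

Going back in time, island lineages join the mainland deme at the split time
(default 85.4 ka). Optional components:

* **Colonization / glacial bottlenecks.** A bottleneck is a transient drop to
  `size` individuals for `duration` generations. Strength is summarized by
  the dimensionless *severity* = duration / size: a single-generation
  bottleneck of severity 0.1 is a founding propagule of 10 individuals.
  `onset_time` is the ancient edge: the bottleneck occupies
  `[onset − duration·generation_time, onset]` years BP, so a bottleneck with
  onset at the split sits immediately after colonization without moving the
  merge time. Recovery is instantaneous or smooth (exponential regrowth over
  a configurable span, default 15 ka — the recovery shape is not identifiable
  from the data this models, so both are exposed).
* **Migration pulses.** An instantaneous transfer of a fraction of island
  lineages to the mainland deme, for secondary-contact model checks.

The shipped baseline anchor fixture is a round-number approximation of the
published point estimates (which exist only in supplementary material):
island 30 K plateau with a 10 K glacial trough between 15 and 40 ka, spliced
onto the ancestral (mainland) trajectory at 200 ka; mainland ~45–50 K with a
mild excursion near 40 ka. Only the round main-text values (30 K, 10 K) are
relied on anywhere; the fixture is user-replaceable
(`build_baseline(anchors=...)`).

`candidate_models()` returns the six demographies consistent with the data:
{baseline; 30 K plateau with glacial trough, instantaneous recovery; same
with smooth recovery} × {no colonization bottleneck; severity-0.1 bottleneck
at the split}.

## Ploidy and rate conventions

All sampled genomes are haploid lineages (inbred accessions approximated as
haploids). The pair-coalescence hazard within a deme of size Ne is
**1/(2 Ne) per generation**; consequently E[pairwise TMRCA] = 2 Ne and
E[π] = 4 Ne μ per bp for a haploid pair. The msprime backend is run with
ploidy 1 and population sizes of 2 Ne, which realises exactly this hazard.
Times are years BP at the interface, converted to generations (default
generation time 1 year) at the simulator boundary.

## Synthetic data

**Genealogy mode** (`sample_pair_times`) draws i.i.d. pair-coalescence times
at independent loci from the exact hazard implied by a scenario, using
closed-form cumulative hazards of the piecewise-exponential size functions
(segment-wise `(1 − e^{−βs})/(2 N₀ β)` with analytic inversion). It is
written from scratch, independent of any coalescent engine, and serves as
the oracle throughout; a test verifies it against msprime one-locus
replicates by two-sample Kolmogorov–Smirnov.

**Sequence mode** (`simulate_genome`) simulates recombining chromosomes with
mutations through msprime. Defaults: the five TAIR10 chromosome lengths, a
uniform map rate of 3.6e-8 per bp scaled by an outcrossing factor of 0.02
(predominantly selfing populations realise only a few percent of the map as
effective crossovers; the exact correction factor is not printed in the
sources this models, so it is configurable and reported in run metadata), and
mutation rates between 2.2e-9 (natural-population estimate) and 7.1e-9
(mutation-accumulation estimate) per bp per generation — uniform at 7.1e-9 by
default, spanning the range across the five chromosomes in the variable-rate
scenario. Mutations use a binary 0/1 model with 0 ancestral; sites hit more
than once are dropped so the polarization of the panel is exact.

What the generator does **not** emulate: mutation-rate and recombination-map
variation below the chromosome scale, gene conversion, selection,
sequencing/calling error, missing data, and more than two demes. Passing
tests therefore demonstrate correctness of the inference machinery under the
neutral two-deme model, not robustness to these real-data complications. In
particular, the exact polarization of real panels (reference-based) is an
approximation the synthetic data does not stress.

**Pseudo-diploids.** Haploid genomes are combined into "fake diploids":
n haplotypes give ceil(n/2) pairs, one haplotype being reused exactly once
when n is odd (11 → 6 pairs, 18 → 9). Cross pairs draw one haplotype per
deme. Heterozygosity of a pair marks cross-haplotype differences.

## Coalescence-rate inference

Two estimators share a `TimeDiscretization` (default: 32 intervals,
boundaries log-spaced between 1 ka and 4 Ma in generation units, padded by
[0, ·) and [·, ∞); the originally used segment pattern is not printed, so a
neutral log spacing is the default).

* `rates_from_genealogies`: empirical hazard — events per bin over
  lineage-time at risk per bin; bins with zero exposure are flagged
  inestimable (NaN).
* `infer_pairwise_smc`: a pairwise sequentially-Markovian-coalescent HMM.
  Hidden states are the discretized TMRCA intervals of one pseudo-diploid;
  the observation is a binarized 100-bp-window heterozygosity track (window
  size configurable; 100 bp keeps per-window het probabilities ≪ 1 at the
  relevant TMRCAs). Emission: P(het | T=m_j) = 1 − exp(−2 μ w m_j), with m_j
  the within-interval conditional mean TMRCA. Transition: recombination
  strikes the 2 m_j branch length with probability 1 − exp(−2 ρ w m_j); the
  breakpoint is uniform on (0, m_j) and the floating lineage re-coalesces
  under the current piecewise-constant rates (the re-coalescence integral is
  evaluated by 16-node Gauss–Legendre quadrature over the breakpoint height).
  Estimation is expectation–maximization: forward–backward collects initial,
  transition and emission posterior counts; the M-step maximizes the exact Q
  function over log-rates with L-BFGS-B (bounds 1e-9 to 0.5 per generation).
  The likelihood is asserted non-decreasing every run. Convergence: relative
  log-likelihood change below 1e-4, at most 30 iterations; non-convergence
  flags the result instead of raising. ρ is supplied by the caller (the
  pipeline passes the scenario's effective rate); a coarse first-pass grid
  search (`fit_rho=True`) is available when ρ is unknown. Multiple pairs are
  combined as a composite likelihood with shared rates.

**CCR.** The cross-coalescence rate per interval is
2 λ_cross / (λ_within1 + λ_within2): ~1 while the ancestral population is
uniform, 0 after a complete split, invariant to common rescaling of all
three curves. Curves are smoothed with a shape-preserving cubic Hermite
(PCHIP) spline through per-bin medians on a log-time axis — "cubic spline
across medians" with a monotonicity-safe variant, so the no-overshoot
property holds exactly. Medians are taken across everything supplied
(pairs are pooled inside the composite likelihood; replicates are pooled at
the smoothing step).

**Split-time estimation.** The smoothed CCR decay is bracketed by a band:
the crossing time of each band edge is the most recent upward crossing, the
estimate is the midpoint, and a curve that never traverses the band is
flagged inconclusive. Two published bands are exposed: [0.70, 0.75] (from
the original calibration) and the wider [0.70, 0.85] expectation range;
which applies where was never settled upstream, so both are available and
the default bracketing band is the wider one. `calibrate_ccr_threshold` recomputes the band for *this*
pipeline by simulation: for each split time it simulates, runs the full
pipeline, reads the smoothed CCR at the true split, and reports per-split
distributions plus the pooled central 95% band.

**A calibration result to be aware of.** Under this package's
pairwise-composite estimator the smoothed CCR at a true 85.4-ka split of the
baseline demography is ~0.45 (10-Mb genome, 10 replicates; per-bin step
value ~0.6). The original analysis, built on the multi-haplotype MSMC2
executable, calibrated 0.70–0.75 for the same conditions. The difference is
estimator smear: the pairwise HMM localizes the cross-coalescence step more
sharply than the multi-haplotype machinery, whose likelihood this package
deliberately does not reproduce. The practical consequence is unchanged —
the threshold band must always come from `calibrate_ccr_threshold` run
through the same pipeline as the data analysis — but absolute CCR-at-split
values are not transferable between estimators. Split-time estimates with a
self-calibrated band recover a synthetic 85.4-ka split within ~10–20% at
10-Mb scale.

## Selection scans

**CLR sweep scan.** At each grid point (spacings 5/10/50/100 kb) the
composite likelihood of nearby derived-allele frequencies is compared
between the genome-wide background spectrum and a sweep model: each of the n
lineages escapes the sweep with probability 1 − exp(−α d) (d = recombination
distance, α = sweep strength); non-escapees coalesce into one lineage; the
ancestral alleles of the escapees plus the trapped block are drawn from the
background by hypergeometric downsampling. Class probabilities are
renormalized over the included classes (polymorphic-only, or polymorphic
plus fixed-derived) and floored at 1e-9. CLR = 2 × the log-likelihood ratio
maximized over α on a log grid of footprints (~1 kb to 1 Mb) with optional
golden-section refinement; α → ∞ recovers the background model, so CLR ≥ 0
by construction. Sites beyond α d = 12 contribute nothing and are skipped.
Grid points with no sites in scan range report NaN, not 0. Significance
thresholds are simulation-derived: pooled per-grid-point CLR values across
neutral replicates of the six candidate demographies, 99th percentile, max
across scenarios (pooled-value thresholding matches drawing one horizontal
line over all points; a per-replicate-maximum variant is a flag away).
Polarization against a reference/outgroup proxy is an approximation;
misoriented sites inflate the fixed-derived class, which is why the
polymorphic-only configuration is the conservative default.

**McDonald–Kreitman screen.** Per-gene 2×2 tables of nonsynonymous vs
synonymous counts in divergence (Dn, Ds) and polymorphism (Pn, Ps);
α = 1 − (Ds·Pn)/(Dn·Ps) (undefined when Dn or Ps is 0); two-sided Fisher
exact P by minimum-likelihood summation (documented because two-sided
conventions differ; the test suite verifies it against full hypergeometric
enumeration). Eligibility requires all row and column sums positive; the
screen tiers genes as eligible → significant (P < 0.01) → candidate
(significant with α > 0). Variant-effect classification is an input, not
computed here. The synthetic-counts generator draws independent Poisson
counts per gene with an inflated Dn mean for a selected fraction; under
neutrality the candidate rate is bounded by p_cut/2 (two-sided halved by the
positive-α condition) and in practice sits well below it because Fisher's
exact test is conservative on discrete tables.

## Distances, trees, resampling

Pairwise differences per callable bp (denominator: total length, a scalar,
or a per-pair matrix; zero-callable pairs flagged missing), nucleotide
diversity θπ as mean pairwise difference per bp, and fold reductions
reported to one decimal. Neighbor joining uses the canonical Q-criterion
with deterministic lowest-index tie-breaking; negative branch lengths are
clamped to zero with the remainder moved to the sister branch; the final
three nodes are resolved by the three-point formulas, giving the usual
unrooted trifurcation. The packaged split-time matrix (units ka; island plus
thirteen mainland clusters) is symmetrized by averaging its minor printed
asymmetries, with raw values retained. The cluster-resampling harness draws
up to 20 members per cluster without replacement, 100 times by default,
deterministically per seed.

## Problem sizes in tests and the acceptance script

Simulation-backed tests run on reduced genomes (1–10 Mb, 1–2 chromosomes)
with 2–10 replicates and 2 pseudo-diploid pairs per class — sizes chosen so
the full suite exercises every pipeline stage at Monte-Carlo tolerances
while staying desk-scale; full-scale settings (five chromosomes, 200
replicates) are plain configuration changes. The acceptance script runs the
10-Mb, 10-replicate CCR calibration described above.

## Known limitations

* The pairwise SMC approximates, but does not reproduce, multi-haplotype
  MSMC2 estimates; absolute CCR-at-split values differ (see above).
* The sweep scan models hard sweeps via the escape-probability mixture only;
  soft sweeps, background selection and the structural-variant false-positive
  mode of reference-distant samples are out of scope.
* Real-data mode requires user-supplied callable-site denominators and
  variant-effect annotations; neither is recoverable from sequence alone.
* The genealogy-mode state machine covers two demes and one pair; it is an
  oracle, not a general simulator.
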