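# propagule

A two-deme coalescent pipeline for island-colonization population genomics:
demographic model checking by simulation, split-time inference from
cross-coalescence rates, and selection screens with simulation-derived
significance thresholds.

The motivating system is *Arabidopsis thaliana* on the oceanic island of
Madeira — a clean natural long-range dispersal event: a small set of founders
(a *propagule*) colonizes an island, evolves in isolation at a reduced
carrying capacity, and leaves genomic signatures that are not confounded by
continental admixture. The package answers, on synthetic or real haploid
panels, the questions such a system poses:

* **When did the island split from its mainland source?** Pairs of inbred
  (haploid) genomes are combined into pseudo-diploids; a pairwise
  sequentially-Markovian-coalescent HMM infers time-binned coalescence
  rates λ within and across demes, and the **cross-coalescence rate**
  CCR(t) = 2·λ_cross / (λ_within1 + λ_within2) decays from 1 to 0 through
  the split. Where on that decay the true split sits is *calibrated by
  simulation* under the fitted demography.
* **How severe was the founder bottleneck?** Bottleneck strength is
  *severity* = duration/size; simulation shows which severities would be
  visible as a dip in inferred Ne(t). A single-generation severity-0.1
  bottleneck corresponds to a 10-founder propagule.
* **What was selected after colonization?** A SweepFinder-style composite
  likelihood ratio (CLR) scan against the genome-wide site-frequency
  spectrum, thresholded at the highest 99th percentile across six candidate
  demographies, and a McDonald–Kreitman screen
  (α = 1 − (Ds·Pn)/(Dn·Ps), two-sided Fisher exact test).
* **How do clusters relate?** Pairwise-difference matrices, θπ, neighbor
  joining — including on the packaged matrix of pairwise split times
  between the island and thirteen Eurasian/African mainland clusters.

Modules: `demography` (Ne(t) trajectories, scenarios, the six candidate
models), `coalsim` (genealogy-mode oracle + msprime-backed sequence
simulation), `rates` (pairwise SMC, CCR, calibration, split-time
estimation), `sweep` (CLR scan and null thresholds), `mk`
(McDonald–Kreitman), `popstruct` + `io` (distances, NJ, resampling, VCF /
multihetsep / table formats). A thin `propagule` command-line interface
wraps the library (`propagule --help`).

## Worked example

Simulate the baseline island/mainland demography (split 85.4 ka, island
plateau 30 K with a 10 K glacial trough, ancestral ~50 K) on a reduced
10-Mb genome, then recover the split from sequence data alone:

```python
import numpy as np
from propagule import demography as dg, coalsim, rates, popstruct

scen = dg.build_baseline(layout=dg.GenomeLayout.reduced(2, 5_000_000))
panel = coalsim.simulate_genome(scen, n_island=11, n_mainland=20, seed=1)

pi_i = 100 * popstruct.theta_pi(panel, "island")
pi_m = 100 * popstruct.theta_pi(panel, "mainland")
print(pi_i, pi_m, popstruct.fold_reduction(pi_i, pi_m))

disc = rates.TimeDiscretization.default()
res = rates.ccr_from_panel(panel, disc, mu=7.1e-9, rho=7.2e-10, seed=1)
sm = rates.smooth_curve(res.ccr)
est = rates.estimate_split_time(sm, band=(0.30, 0.60))
print(sm(85_400), est.expected, est.lower, est.upper)
```

prints (seed 1):

```
theta_pi island:   0.064%
theta_pi mainland: 0.144%
fold reduction:    2.2
CCR at 85.4 ka:    0.56
split estimate:    79.4 ka (range 71.5 – 87.2 ka)
```

The island's diversity is reduced relative to the mainland (2.2-fold here;
the published island-vs-worldwide contrast, θπ 0.112% vs 0.483%, is
4.3-fold — `fold_reduction(0.112, 0.483)` returns exactly that). The CCR
decay, bracketed with a band calibrated for *this* pipeline
(`rates.calibrate_ccr_threshold`), recovers the true 85.4-ka split within
~7%. Note that the calibrated band is estimator-specific: this package's
pairwise-composite HMM places the CCR decay lower at the true split (~0.45
median across replicates) than the 0.70–0.75 published for the original
multi-haplotype machinery — see `docs/methods.md` for the analysis.

The packaged split-time matrix reproduces the printed nearest-neighbor
relation of the island cluster:

```python
dm, raw = popstruct.load_split_time_matrix()
popstruct.nearest_neighbor_report(dm)      # row Mad -> nearest Ir at 72.8 ka
print(popstruct.nj_tree(dm))       # Newick; Mad attaches next to Ir
```

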