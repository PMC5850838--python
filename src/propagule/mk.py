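"""McDonald-Kreitman screen: per-gene 2x2 tables, Fisher's exact test, alpha.

For each gene the table contrasts nonsynonymous vs synonymous counts in
divergence (fixed differences Dn, Ds) and polymorphism (Pn, Ps).  Under
neutrality Dn/Ds ~ Pn/Ps; an excess of nonsynonymous divergence gives a
positive ``alpha = 1 - (Ds*Pn)/(Dn*Ps)``, the estimated fraction of adaptive
substitutions.  A gene is *eligible* when both row sums and both column sums
of its table are nonzero; candidates are eligible genes with Fisher P below
the cutoff and positive alpha.

Variant-effect classification (synonymous vs nonsynonymous) is taken as
input; this module works from count tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "MKRecord",
    "ScreenResult",
    "mk_alpha",
    "fisher_exact_2x2",
    "gene_screen",
    "synth_mk_counts",
    "records_from_table",
]


def mk_alpha(dn: int, ds: int, pn: int, ps: int) -> float | None:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); None (undefined) when Dn or Ps is zero.

    The sign of alpha equals the sign of Dn*Ps - Ds*Pn whenever defined.
    """
    if min(dn, ds, pn, ps) < 0:
        raise ValueError("counts must be non-negative")
    if dn == 0 or ps == 0:
        return None
    return 1.0 - (ds * pn) / (dn * ps)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact P for a 2x2 table of non-negative integers.

    Two-sided by minimum-likelihood summation: the P-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=np.int64).reshape(2, 2)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


@dataclass
class MKRecord:
    """Per-gene counts with the derived statistics."""

    gene: str
    dn: int
    ds: int
    pn: int
    ps: int
    alpha: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        for c in (self.dn, self.ds, self.pn, self.ps):
            if c < 0 or int(c) != c:
                raise ValueError("counts must be non-negative integers")
        self.alpha = mk_alpha(self.dn, self.ds, self.pn, self.ps)

    @property
    def eligible(self) -> bool:
        """Both rows and both columns of the 2x2 table nonempty."""
        return (
            self.dn + self.ds > 0
            and self.pn + self.ps > 0
            and self.dn + self.pn > 0
            and self.ds + self.ps > 0
        )

    def test(self) -> float:
        self.p_value = fisher_exact_2x2([[self.dn, self.ds], [self.pn, self.ps]])
        return self.p_value


@dataclass
class ScreenResult:
    records: list[MKRecord]
    eligible: list[MKRecord]
    significant: list[MKRecord]
    candidates: list[MKRecord]
    p_cut: float

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.eligible), len(self.significant), len(self.candidates))

    def to_frame(self) -> pd.DataFrame:
        sig = {id(r) for r in self.significant}
        cand = {id(r) for r in self.candidates}
        rows = []
        for r in self.records:
            tier = (
                "candidate"
                if id(r) in cand
                else "significant"
                if id(r) in sig
                else "eligible"
                if r.eligible
                else "ineligible"
            )
            rows.append(
                {
                    "gene": r.gene,
                    "Dn": r.dn,
                    "Ds": r.ds,
                    "Pn": r.pn,
                    "Ps": r.ps,
                    "alpha": r.alpha,
                    "P": r.p_value,
                    "tier": tier,
                }
            )
        return pd.DataFrame(rows)


def gene_screen(records, p_cut: float = 0.01) -> ScreenResult:
    """Three-tier screen: eligible -> significant (P < p_cut) -> candidate
    (significant with alpha > 0)."""
    records = list(records)
    eligible = [r for r in records if r.eligible]
    for r in eligible:
        if r.p_value is None:
            r.test()
    significant = [r for r in eligible if r.p_value < p_cut]
    candidates = [r for r in significant if r.alpha is not None and r.alpha > 0]
    return ScreenResult(records, eligible, significant, candidates, p_cut)


def synth_mk_counts(
    n_genes: int,
    neutral_rates: dict | None = None,
    selected_fraction: float = 0.0,
    effect: float = 1.0,
    seed: int | None = None,
) -> list[MKRecord]:
    """Synthetic per-gene count tables for screen calibration.

    Counts are independent Poisson draws around the neutral per-gene means
    (keys dn, ds, pn, ps); a ``selected_fraction`` of genes receives a Dn mean
    inflated by ``effect``.  With fraction 0 (or effect 1) the screen sees
    pure neutrality.
    """
    if not (0.0 <= selected_fraction <= 1.0):
        raise ValueError("selected_fraction must be in [0, 1]")
    rates = dict(dn=2.0, ds=2.0, pn=4.0, ps=4.0)
    if neutral_rates:
        rates.update(neutral_rates)
    if min(rates.values()) <= 0:
        raise ValueError("neutral rates must be positive")
    rng = np.random.default_rng(seed)
    selected = rng.random(n_genes) < selected_fraction
    out = []
    for i in range(n_genes):
        dn_rate = rates["dn"] * (effect if selected[i] else 1.0)
        out.append(
            MKRecord(
                gene=f"g{i:05d}",
                dn=int(rng.poisson(dn_rate)),
                ds=int(rng.poisson(rates["ds"])),
                pn=int(rng.poisson(rates["pn"])),
                ps=int(rng.poisson(rates["ps"])),
            )
        )
    return out


def records_from_table(path_or_frame) -> list[MKRecord]:
    """Read per-gene counts (columns: gene, Dn, Ds, Pn, Ps; tab-separated)."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    return [
        MKRecord(
            gene=str(row[cols["gene"]]),
            dn=int(row[cols["dn"]]),
            ds=int(row[cols["ds"]]),
            pn=int(row[cols["pn"]]),
            ps=int(row[cols["ps"]]),
        )
        for _, row in df.iterrows()
    ]
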