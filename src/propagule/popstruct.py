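"""Distance and diversity statistics, neighbor joining, and cluster resampling.

Includes the packaged split-time matrix fixture (pairwise split times in ka
between the island cluster and thirteen mainland clusters, inferred from
cross-coalescence rates), the neighbor-joining tree machinery used to
visualise such matrices, and the even-subsampling harness used to balance
cluster sizes in population-structure analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .coalsim import HaplotypePanel

__all__ = [
    "DistanceMatrix",
    "pairwise_diff_matrix",
    "theta_pi",
    "fold_reduction",
    "nj_tree",
    "nj_path_distances",
    "nearest_neighbor_report",
    "load_split_time_matrix",
    "resample_clusters",
]


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite.T], rtol=0, atol=1e-9
        ):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, units: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.values, units)

    def complete(self) -> bool:
        return bool(np.isfinite(self.values).all())


def pairwise_diff_matrix(
    panel: HaplotypePanel, callable_sites=None
) -> DistanceMatrix:
    """Pairwise differences per callable base pair between all haplotypes.

    ``callable_sites`` is a scalar denominator, a (n, n) per-pair matrix, or
    None (all positions callable: the total genome length).  Pairs with zero
    callable sites get a missing (NaN) entry.
    """
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("need at least two haplotypes")
    diffs = np.zeros((n, n))
    for c in panel.chromosomes:
        g = panel.genotypes[c].astype(np.float64)
        diffs += g @ (1.0 - g).T + (1.0 - g) @ g.T
    if callable_sites is None:
        denom = np.full((n, n), float(panel.total_length))
    else:
        denom = np.asarray(callable_sites, dtype=float)
        if denom.ndim == 0:
            denom = np.full((n, n), float(denom))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, diffs / denom, np.nan)
    np.fill_diagonal(vals, 0.0)
    labels = [f"{d}_{i}" for i, d in enumerate(panel.demes)]
    return DistanceMatrix(labels, vals, units="differences/bp")


def theta_pi(panel: HaplotypePanel, deme: str | None = None) -> float:
    """Nucleotide diversity: mean pairwise differences per base pair."""
    idx = (
        panel.deme_indices(deme) if deme is not None else np.arange(panel.n_haplotypes)
    )
    n = idx.size
    if n < 2:
        raise ValueError("need at least two haplotypes")
    total = 0.0
    for c in panel.chromosomes:
        dac = panel.genotypes[c][idx].sum(axis=0)
        total += float(np.sum(dac * (n - dac)))
    n_pairs = n * (n - 1) / 2
    return total / n_pairs / panel.total_length


def fold_reduction(a: float, b: float) -> float:
    """How many fold smaller ``a`` is than ``b`` (b / a, one decimal)."""
    if a <= 0:
        raise ValueError("reference diversity must be positive")
    return round(b / a, 1)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{length:.17g}" for child, length in self.children
        )
        return f"({inner})"


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, moving the remainder to the sister."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def _nj(dm: DistanceMatrix) -> _Node:
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if not dm.complete():
        raise ValueError("distance matrix must be complete")
    nodes = [_Node(label) for label in dm.labels]
    d = dm.values.copy()
    active = list(range(dm.n))
    while len(active) > 3:
        m = len(active)
        r = np.array([sum(d[i, j] for j in active if j != i) for i in active])
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[ai] - r[aj]
                # strict < : ties resolve to the lowest-index pair
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * d[i, j] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        dn = np.array([0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in active])
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak, k in enumerate(active):
            d[-1, k] = d[k, -1] = max(dn[ak], 0.0)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # resolve the last three around a central node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return _Node(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (canonical Q-criterion) as an unrooted Newick
    string; negative branch lengths are clamped to zero with the remainder
    moved to the sister branch; Q ties break to the lowest-index pair."""
    return _nj(dm).newick() + ";"


def nj_path_distances(dm: DistanceMatrix) -> DistanceMatrix:
    """Leaf-to-leaf path (patristic) distances on the neighbor-joining tree."""
    root = _nj(dm)
    dists: dict[str, dict[str, float]] = {}

    def leaves_below(node, depth, acc):
        if not node.children:
            acc.append((node.label, depth))
        for child, length in node.children:
            leaves_below(child, depth + length, acc)
        return acc

    def walk(node):
        groups = []
        for child, length in node.children:
            groups.append(leaves_below(child, length, []))
            walk(child)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi]:
                    for lb, db in groups[gj]:
                        dists.setdefault(la, {})[lb] = da + db
                        dists.setdefault(lb, {})[la] = da + db

    walk(root)
    vals = np.zeros((dm.n, dm.n))
    for a, la in enumerate(dm.labels):
        for b, lb in enumerate(dm.labels):
            if a != b:
                vals[a, b] = dists[la][lb]
    return DistanceMatrix(dm.labels, vals, units=dm.units)


# ---------------------------------------------------------------------------
# the split-time matrix fixture
# ---------------------------------------------------------------------------


def load_split_time_matrix() -> tuple[DistanceMatrix, pd.DataFrame]:
    """The packaged split-time matrix (ka) between the island and the thirteen
    mainland clusters.

    The printed matrix contains minor asymmetries; the returned
    DistanceMatrix is symmetrized by averaging, and the raw (as-printed)
    values are returned alongside.
    """
    ref = resources.files("propagule.data").joinpath("split_time_matrix.tsv")
    with ref.open() as fh:
        raw = pd.read_csv(fh, sep="\t", index_col=0)
    vals = raw.values.astype(float)
    sym = 0.5 * (vals + vals.T)
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(list(raw.index), sym, units="ka"), raw


def nearest_neighbor_report(dm: DistanceMatrix) -> pd.DataFrame:
    """Per row: the minimum off-diagonal entry and its column label (each
    cluster's most recent split partner)."""
    rows = []
    for i, label in enumerate(dm.labels):
        row = dm.values[i].copy()
        row[i] = np.inf
        j = int(np.argmin(row))
        rows.append(
            {"cluster": label, "nearest": dm.labels[j], "split_time": float(row[j])}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cluster resampling harness
# ---------------------------------------------------------------------------


def resample_clusters(
    labels,
    target: int = 20,
    n_resamples: int = 100,
    seed: int | None = None,
    clusters=None,
) -> list[np.ndarray]:
    """Even subsampling of clusters to balance sample sizes.

    Per resample, up to ``target`` members of each cluster are drawn without
    replacement (all members when a cluster has fewer).  Deterministic given
    ``seed``.  Returns one sorted index array per resample.
    """
    labels = np.asarray(labels)
    if clusters is None:
        clusters = list(dict.fromkeys(labels.tolist()))
    member = {c: np.where(labels == c)[0] for c in clusters}
    for c, idx in member.items():
        if idx.size == 0:
            raise ValueError(f"cluster {c!r} has no members")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_resamples):
        picks = []
        for c in clusters:
            idx = member[c]
            if idx.size <= target:
                picks.append(idx)
            else:
                picks.append(rng.choice(idx, size=target, replace=False))
        out.append(np.sort(np.concatenate(picks)))
    return out
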