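"""File-format layer: minimal VCF, multihetsep, and tab-separated tables.

All coordinates are 1-based inclusive (VCF convention); multihetsep follows
its native 1-based convention.  The VCF writer emits haploid GT calls with an
AA (ancestral allele) INFO field; reading uses cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coalsim import HaplotypePanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_multihetsep",
    "read_multihetsep",
    "multihetsep_to_track",
    "write_sites_table",
    "read_sites_table",
]

_REF, _ALT = "A", "T"  # ancestral / derived placeholder alleles


def sample_names(panel: HaplotypePanel) -> list[str]:
    return [f"{deme}_{i}" for i, deme in enumerate(panel.demes)]


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Minimal VCF 4.2 with haploid genotypes (0 = ancestral allele)."""
    names = sample_names(panel)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID={c},length={panel.lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        for c in panel.chromosomes:
            g = panel.genotypes[c]
            for s, pos in enumerate(panel.positions[c]):
                gts = "\t".join(str(int(x)) for x in g[:, s])
                fh.write(
                    f"{c}\t{pos}\t.\t{_REF}\t{_ALT}\t.\tPASS\tAA={_REF}\tGT\t{gts}\n"
                )


def read_vcf(path, demes=None) -> HaplotypePanel:
    """Read a haploid VCF into a panel.

    Deme labels default to the prefix of each sample name (``island_0`` ->
    ``island``); pass ``demes`` to override.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    vcf = VCF(str(path))
    names = vcf.samples
    if demes is None:
        demes = [n.rsplit("_", 1)[0] for n in names]
    lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    pos: dict[str, list[int]] = {c: [] for c in vcf.seqnames}
    gts: dict[str, list[np.ndarray]] = {c: [] for c in vcf.seqnames}
    for v in vcf:
        arr = np.asarray(v.genotype.array())[:, 0]
        pos[v.CHROM].append(v.POS)
        gts[v.CHROM].append(arr.astype(np.int8))
    chroms = [c for c in vcf.seqnames]
    positions = {c: np.array(pos[c], dtype=np.int64) for c in chroms}
    genotypes = {
        c: (
            np.stack(gts[c], axis=1)
            if gts[c]
            else np.zeros((len(names), 0), dtype=np.int8)
        )
        for c in chroms
    }
    return HaplotypePanel(
        chroms, {c: int(lengths[c]) for c in chroms}, positions, genotypes,
        np.array(demes),
    )


def write_multihetsep(
    panel: HaplotypePanel, path, haplotypes=None, chroms=None
) -> None:
    """Per-chromosome text rows: chrom, pos, called-sites-since-last, alleles.

    Only sites segregating among the selected haplotypes are written; every
    position is assumed callable, so the third column is the distance to the
    previous written site.
    """
    if haplotypes is None:
        haplotypes = np.arange(panel.n_haplotypes)
    haplotypes = np.asarray(haplotypes)
    chroms = chroms if chroms is not None else panel.chromosomes
    alleles = np.array([_REF, _ALT])
    with open(path, "w") as fh:
        for c in chroms:
            g = panel.genotypes[c][haplotypes]
            seg = g.any(axis=0) & ~g.all(axis=0)
            prev = 0
            for s in np.where(seg)[0]:
                p = int(panel.positions[c][s])
                fh.write(f"{c}\t{p}\t{p - prev}\t{''.join(alleles[g[:, s]])}\n")
                prev = p


def read_multihetsep(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Parse multihetsep rows into per-chromosome (positions, called-counts,
    0/1 allele matrix); the alphabetically first allele maps to 0."""
    per_chrom: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, p, called, alleles = line.split()
            per_chrom.setdefault(chrom, []).append((int(p), int(called), alleles))
    out = {}
    for chrom, rows in per_chrom.items():
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        called = np.array([r[1] for r in rows], dtype=np.int64)
        width = len(rows[0][2])
        mat = np.zeros((width, len(rows)), dtype=np.int8)
        for s, (_, _, alleles) in enumerate(rows):
            lo = min(alleles)
            mat[:, s] = [0 if a == lo else 1 for a in alleles]
        out[chrom] = (pos, called, mat)
    return out


def multihetsep_to_track(
    data, lengths: dict[str, int], pair=(0, 1), window: int = 100
) -> list[np.ndarray]:
    """Binarized per-window heterozygosity tracks for one haplotype pair from
    parsed multihetsep data."""
    i, j = pair
    tracks = []
    for chrom, (pos, _called, mat) in data.items():
        n_win = int(np.ceil(lengths[chrom] / window))
        track = np.zeros(n_win, dtype=np.uint8)
        het = mat[i] != mat[j]
        if het.any():
            track[(pos[het] - 1) // window] = 1
        tracks.append(track)
    return tracks


def write_sites_table(panel: HaplotypePanel, path) -> None:
    """Plain segregating-sites table: chrom, pos, then one 0/1 column per
    haplotype (column names carry the deme labels)."""
    names = sample_names(panel)
    frames = []
    for c in panel.chromosomes:
        df = pd.DataFrame(
            panel.genotypes[c].T, columns=names
        )
        df.insert(0, "pos", panel.positions[c])
        df.insert(0, "chrom", c)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    # lengths travel in a sidecar header line-free format: a companion .lengths file
    with open(str(path) + ".lengths", "w") as fh:
        for c in panel.chromosomes:
            fh.write(f"{c}\t{panel.lengths[c]}\n")


def read_sites_table(path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    lengths = {}
    lengths_path = Path(str(path) + ".lengths")
    if lengths_path.exists():
        for line in lengths_path.read_text().splitlines():
            c, ln = line.split("\t")
            lengths[c] = int(ln)
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    demes = np.array([c.rsplit("_", 1)[0] for c in hap_cols])
    chroms = list(dict.fromkeys(df["chrom"].astype(str)))
    positions, genotypes = {}, {}
    for c in chroms:
        sub = df[df["chrom"].astype(str) == c]
        positions[c] = sub["pos"].to_numpy(dtype=np.int64)
        genotypes[c] = sub[hap_cols].to_numpy(dtype=np.int8).T
        lengths.setdefault(c, int(positions[c][-1]) if positions[c].size else 1)
    return HaplotypePanel(chroms, lengths, positions, genotypes, demes)
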