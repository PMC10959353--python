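"""Candidate-region extraction from per-SNP association p-values.

Consumes a GWAS p-value table (the mixed-model fit itself is upstream and out
of scope here), applies site filters (minor-allele frequency, missingness),
derives significance thresholds (Benjamini–Hochberg FDR and Bonferroni),
slides fixed windows over the significant SNPs, and intersects the kept
windows with gene annotations, including UpSet-style exclusive intersection
counts across families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CandidateWindow",
    "site_filters",
    "bh_fdr",
    "bonferroni_threshold",
    "candidate_windows",
    "genes_in_windows",
    "upset_counts",
    "snps_near_features",
    "read_gff3_genes",
]


@dataclass
class CandidateWindow:
    chrom: str
    start: int
    end: int
    n_significant_snps: int
    genes: list[str] = field(default_factory=list)


def site_filters(
    snps: pd.DataFrame, maf_min: float = 0.05, miss_max: float = 0.05
) -> pd.DataFrame:
    """Keep SNPs with maf >= maf_min and missingness <= miss_max.

    Both boundaries are inclusive-keep: a SNP missing in exactly 5% of the
    accessions passes ("more than 5%" is excluded).
    """
    keep = (snps["maf"] >= maf_min) & (snps["missingness"] <= miss_max)
    return snps.loc[keep].reset_index(drop=True)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ties by rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def candidate_windows(
    snps: pd.DataFrame,
    significant: Sequence[bool],
    window: int = 20_000,
    step: int = 10_000,
    min_snps: int = 2,
) -> list[CandidateWindow]:
    """Sliding candidate windows anchored at multiples of ``step`` from 0.

    A window [a, a+window) is kept iff at least ``min_snps`` significant SNPs
    fall inside it. Output is sorted by (chrom, start) and invariant to the
    input row order.
    """
    sig = np.asarray(significant, dtype=bool)
    if sig.size != len(snps):
        raise ValueError("significance flags must match the SNP table")
    out: list[CandidateWindow] = []
    for chrom, sub in snps.loc[sig].groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy(dtype=np.int64))
        if pos.size == 0:
            continue
        anchors = set()
        for p in pos:
            # every anchor whose window [a, a+window) can contain p
            first = max(0, (int(p) - window) // step + 1)
            last = int(p) // step
            anchors.update(range(first * step, last * step + 1, step))
        for a in sorted(anchors):
            n = int(np.searchsorted(pos, a + window, "left") - np.searchsorted(pos, a, "left"))
            if n >= min_snps:
                out.append(CandidateWindow(str(chrom), a, a + window, n))
    return out


def genes_in_windows(
    windows: Sequence[CandidateWindow],
    genes: Sequence[tuple[str, int, int, str]],
) -> set[str]:
    """Gene names whose span overlaps any kept window by >= 1 bp.

    Also fills each window's ``genes`` list in place.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in genes:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    hit: set[str] = set()
    for w in windows:
        tree = trees.get(w.chrom)
        w.genes = []
        if tree is None:
            continue
        for iv in sorted(tree.overlap(w.start, w.end)):
            w.genes.append(iv.data)
            hit.add(iv.data)
    return hit


def upset_counts(gene_sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """UpSet-style exclusive intersection sizes across per-family gene sets.

    Each gene contributes to exactly one cell: the tuple of families (sorted)
    whose sets contain it. Empty cells are omitted.
    """
    membership: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*gene_sets.values()) if gene_sets else set():
        fams = tuple(sorted(f for f, s in gene_sets.items() if gene in s))
        membership[gene] = fams
    counts: dict[tuple[str, ...], int] = {}
    for fams in membership.values():
        counts[fams] = counts.get(fams, 0) + 1
    return counts


def snps_near_features(
    snps: pd.DataFrame,
    features: Sequence[tuple[str, int, int, str]],
    dist: int = 10_000,
) -> np.ndarray:
    """Boolean mask of SNPs within ``dist`` bp of (or inside) any feature."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _name in features:
        trees.setdefault(chrom, IntervalTree()).addi(start - dist, end + dist)
    mask = np.zeros(len(snps), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps_point(int(pos)):
            mask[i] = True
    return mask


def read_gff3_genes(path: str) -> list[tuple[str, int, int, str]]:
    """Gene features from a GFF3 file as (chrom, start0, end, name) tuples.

    GFF3 is 1-based inclusive; output is 0-based half-open. Malformed lines
    raise a parse error naming the line number.
    """
    genes: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            name = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    name = kv[3:]
                    break
            genes.append((chrom, s, e, name or f"gene:{chrom}:{start}"))
    return genes
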