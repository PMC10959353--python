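"""Circle-forming regions from assembled mobilome contigs.

Rolling-circle amplification gives eccDNA-derived contigs very high coverage,
so the longest contigs of each sample's assembly are the best eccDNA
candidates. Aligned back to the reference genome, the genomic intervals they
hit are merged into *circle-forming regions*; regions supported by too few
samples are dropped, the rest are annotated with overlapping gene/TE features
and classified by how strongly their contigs concentrate in one stress or
genotype category (specificity > 50%) or recur across many samples
(recurrent: >= 10 samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .io_align import AlignmentRecord, Read

__all__ = [
    "ContigInterval",
    "CircleRegion",
    "SpecificityCall",
    "top_contigs",
    "contig_regions",
    "merge_regions",
    "retain_regions",
    "specificity",
    "annotate_regions",
]

log = logging.getLogger(__name__)

ContigInterval = tuple[str, int, int, str, str]  # chrom, start, end, sample, contig


@dataclass
class CircleRegion:
    chrom: str
    start: int
    end: int
    contig_ids: list[str] = field(default_factory=list)
    contig_samples: list[str] = field(default_factory=list)
    annotations: list[str] = field(default_factory=list)
    below_length: bool = False

    @property
    def samples(self) -> set[str]:
        return set(self.contig_samples)

    @property
    def sequence_length(self) -> int:
        return self.end - self.start


@dataclass
class SpecificityCall:
    region: CircleRegion
    axis: str
    top_category: str
    specificity: float
    n_samples: int
    klass: str  # SPECIFIC | RECURRENT | NONE


def top_contigs(contigs: Sequence[Read], n: int = 10) -> list[Read]:
    """The ``n`` longest contigs; ties broken by input order (stable sort)."""
    return sorted(contigs, key=lambda c: -len(c[1]))[:n]


def contig_regions(
    alignments: Sequence[AlignmentRecord], sample_id: str
) -> list[ContigInterval]:
    """Each matched block of a (split) contig alignment becomes one labeled interval."""
    intervals: list[ContigInterval] = []
    for rec in alignments:
        for bs, be in rec.matched_blocks:
            intervals.append((rec.reference_name, bs, be, sample_id, rec.read_id))
    return intervals


def merge_regions(intervals: Iterable[ContigInterval]) -> list[CircleRegion]:
    """Merge overlapping or book-ended intervals into circle-forming regions.

    Maximal sets of pairwise-touching intervals become one region that records
    the contributing contigs and the distinct samples. Output regions are
    disjoint and sorted; the total contig-interval count is conserved.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
    regions: list[CircleRegion] = []
    for chrom, start, end, sample, contig in by_pos:
        if (
            regions
            and regions[-1].chrom == chrom
            and start <= regions[-1].end  # book-ended intervals merge
        ):
            cur = regions[-1]
            cur.end = max(cur.end, end)
            cur.contig_ids.append(contig)
            cur.contig_samples.append(sample)
        else:
            regions.append(
                CircleRegion(chrom, start, end, [contig], [sample])
            )
    return regions


def retain_regions(
    regions: Sequence[CircleRegion], min_samples: int = 3
) -> list[CircleRegion]:
    """Keep regions hit by contigs from at least ``min_samples`` distinct samples."""
    return [r for r in regions if len(r.samples) >= min_samples]


def specificity(
    region: CircleRegion,
    sample_labels: Mapping[str, str],
    axis: str,
    min_recurrent_samples: int = 10,
) -> SpecificityCall:
    """Classify a region on one axis (stress or genotype).

    ``specificity`` is the fraction of the region's contigs whose sample
    belongs to the modal category. SPECIFIC requires a strict majority
    (> 0.5); otherwise the region is RECURRENT when seen in at least
    ``min_recurrent_samples`` samples, else NONE. A modal tie can never give
    a strict majority, so tied regions fall through to RECURRENT/NONE.
    """
    counts: dict[str, int] = {}
    for sample in region.contig_samples:
        if sample not in sample_labels:
            raise ValueError(f"sample {sample!r} has no {axis} label")
        cat = sample_labels[sample]
        counts[cat] = counts.get(cat, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("region has no contributing contigs")
    top_category, top_count = max(counts.items(), key=lambda kv: kv[1])
    spec = top_count / total
    n_samples = len(region.samples)
    if spec > 0.5:
        klass = "SPECIFIC"
    elif n_samples >= min_recurrent_samples:
        klass = "RECURRENT"
    else:
        klass = "NONE"
    return SpecificityCall(region, axis, top_category, spec, n_samples, klass)


def annotate_regions(
    regions: Sequence[CircleRegion],
    genes: Sequence[tuple[str, int, int, str]] = (),
    tes: Sequence[tuple[str, int, int, str]] = (),
    genome: Mapping[str, str] | None = None,
    min_seq_len: int = 2000,
) -> dict[str, str]:
    """Annotate regions in place with overlapping feature names; extract FASTA.

    Overlapping TE and gene names are concatenated in encounter order (the
    concatenated-annotation convention). When a genome is supplied, sequences
    of regions at least ``min_seq_len`` bp long are returned keyed by region
    coordinates; shorter regions are flagged ``below_length`` and skipped.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in list(tes) + list(genes):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    sequences: dict[str, str] = {}
    for region in regions:
        hits = []
        tree = trees.get(region.chrom)
        if tree is not None:
            for iv in sorted(tree.overlap(region.start, region.end)):
                hits.append(iv.data)
        region.annotations = hits
        region.below_length = region.sequence_length < min_seq_len
        if genome is not None:
            if region.chrom not in genome:
                raise ValueError(f"chromosome {region.chrom!r} missing from genome")
            if not region.below_length:
                key = f"{region.chrom}:{region.start}-{region.end}"
                sequences[key] = genome[region.chrom][region.start:region.end]
    return sequences
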