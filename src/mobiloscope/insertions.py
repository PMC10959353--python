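"""Transposon insertion polymorphism (TIP) filtering and zygosity hints.

Candidate TIPs called against a reference genome include many insertions that
are simply fixed differences between the sequenced line's genetic background
and the reference. Because such background insertions recur at the same site
across individuals of *different* backgrounds, they are removed by clustering
calls across individuals and discarding clusters observed in at least two
individuals spanning at least two distinct backgrounds.

The clipped-read statistic supports zygosity interpretation at a retained
insertion: reads from the carrier haplotype soft-clip at the insertion point
while reads from a non-carrier haplotype span it, so a ~50% clipped fraction
suggests a heterozygous insertion, ~100% homozygous, and a specifically low
fraction a somatic (subclonal) event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_align import AlignmentRecord

__all__ = [
    "TipCall",
    "filter_shared_tips",
    "clipped_fraction",
    "zygosity_hint",
]


@dataclass(frozen=True)
class TipCall:
    sample_id: str
    background: str
    chrom: str
    pos: int
    family: str
    n_split_support: int = 0
    n_spanning: int = 0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if min(self.n_split_support, self.n_spanning, self.n_clipped) < 0:
            raise ValueError("support counts must be >= 0")
        if not self.background:
            raise ValueError(f"call at {self.chrom}:{self.pos} lacks a background label")


def _cluster_calls(
    calls: Sequence[TipCall], site_tolerance: int
) -> list[list[TipCall]]:
    """Single-linkage clustering within ``site_tolerance`` bp per (family, chrom)."""
    by_key: dict[tuple[str, str], list[TipCall]] = {}
    for call in calls:
        by_key.setdefault((call.family, call.chrom), []).append(call)
    clusters: list[list[TipCall]] = []
    for group in by_key.values():
        group.sort(key=lambda c: c.pos)
        cur = [group[0]]
        for call in group[1:]:
            if call.pos - cur[-1].pos <= site_tolerance:
                cur.append(call)
            else:
                clusters.append(cur)
                cur = [call]
        clusters.append(cur)
    return clusters


def filter_shared_tips(
    calls: Sequence[TipCall], site_tolerance: int = 10
) -> list[TipCall]:
    """Remove insertion clusters shared across genetic backgrounds.

    Calls within ``site_tolerance`` bp on the same chromosome for the same
    family form one cluster (the tolerance absorbs TSD-induced breakpoint
    ambiguity). Clusters observed in >= 2 individuals spanning >= 2 distinct
    backgrounds are background noise and removed; everything else is retained.
    Input order is preserved.
    """
    removed: set[int] = set()
    for cluster in _cluster_calls(calls, site_tolerance):
        individuals = {c.sample_id for c in cluster}
        backgrounds = {c.background for c in cluster}
        if len(individuals) >= 2 and len(backgrounds) >= 2:
            removed.update(id(c) for c in cluster)
    return [c for c in calls if id(c) not in removed]


def clipped_fraction(
    alignments: Sequence[AlignmentRecord],
    chrom: str,
    pos: int,
    breakpoint_tolerance: int = 20,
) -> tuple[int, int, float | None]:
    """(n_clipped, n_spanning, fraction) among reads overlapping an insertion point.

    A read counts as *clipped* when it carries soft-clipped bases and its clip
    boundary falls within ``breakpoint_tolerance`` bp of the insertion point.
    Target-site duplications shift the apparent breakpoint by the TSD length,
    and an aligner's bounded-mismatch extension can push the clip boundary a
    few bases into the inserted sequence, hence the generous default
    tolerance. A read counts as *spanning* when a matched
    block covers the point with no clip boundary nearby. With no overlapping
    reads the fraction is None (missing), never 0.
    """
    n_clipped = 0
    n_spanning = 0
    for rec in alignments:
        if rec.reference_name != chrom:
            continue
        boundary_near = rec.n_clipped_bases > 0 and (
            abs(rec.ref_start - pos) <= breakpoint_tolerance
            or abs(rec.ref_end - pos) <= breakpoint_tolerance
        )
        if boundary_near:
            n_clipped += 1
        elif any(bs < pos < be for bs, be in rec.matched_blocks):
            n_spanning += 1
    total = n_clipped + n_spanning
    fraction = n_clipped / total if total > 0 else None
    return n_clipped, n_spanning, fraction


def zygosity_hint(
    fraction: float | None,
    n_split_support: int,
    min_support: int = 2,
    het_band: tuple[float, float] = (0.35, 0.65),
) -> str:
    """Qualitative zygosity call from the clipped fraction.

    The numeric bands are reporting conventions, not biological thresholds:
    below the band suggests a somatic/subclonal insertion, inside it a
    heterozygous one, above it a homozygous one. Calls with thin split-read
    support are labelled support-poor regardless of the fraction.
    """
    if n_split_support < min_support:
        return "support-poor"
    if fraction is None:
        return "missing"
    lo, hi = het_band
    if fraction < lo:
        return "somatic-like"
    if fraction > hi:
        return "homozygous-like"
    return "heterozygous-like"
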