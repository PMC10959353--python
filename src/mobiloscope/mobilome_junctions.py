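"""Tail-to-head 2-LTR junction detection from mobilome reads.

A 2-LTR circle is formed when a completely reverse-transcribed linear
LTR-retrotransposon copy is circularized by end-joining, so the end of its
3'LTR abuts the start of its 5'LTR — a sequence that does not exist in the
linear genome. For every annotated full-length copy we therefore build an
artificial *tail-to-head* reference by fusing the last ``flank`` bp of the
3'LTR to the first ``flank`` bp of the 5'LTR. Mobilome reads that align
contiguously across this fusion point, with at least ``min_overlap`` bp on
both LTRs, are specific evidence for 2-LTR circles: 1-LTR circles, fragmented
circles and linear genomic DNA cannot produce them (barring engineered
tandem arrangements, which the genomic-read background control catches).

Per-copy signals are duplicate-ignoring summed per-base depths, normalized by
the sample's total genome-wide coverage and summed per family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp
from .io_align import AlignmentRecord, KmerIndex, Read, mark_duplicates, naive_align
from .synthetic_data import FullLengthCopy

__all__ = [
    "JunctionRecord",
    "MobilitySignal",
    "build_junction_library",
    "junction_spanning_reads",
    "verify_junction_crossing",
    "junction_signal",
    "normalize_signal",
    "family_signal",
    "genomic_control",
    "scan_junctions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionRecord:
    """Artificial 3'LTR-tail → 5'LTR-head reference for one full-length copy."""

    copy_id: str
    family: str
    sequence: str
    junction_pos: int  # index where the 3'LTR suffix ends / 5'LTR prefix begins
    tail_len: int
    head_len: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.tail_len + self.head_len:
            raise ValueError("sequence length must equal tail_len + head_len")
        if self.junction_pos != self.tail_len:
            raise ValueError("junction_pos must equal tail_len")

    @property
    def header(self) -> str:
        return f"{self.copy_id}|junction={self.junction_pos}"


@dataclass
class MobilitySignal:
    sample_id: str
    copy_id: str
    family: str
    raw_junction_coverage: float
    normalized: float
    is_genomic_control: bool = False


def build_junction_library(
    copies: Sequence[FullLengthCopy],
    genome: Mapping[str, str],
    flank: int = 300,
) -> list[JunctionRecord]:
    """One tail-to-head record per copy with both LTRs annotated.

    Minus-strand copies are reverse-complemented to element orientation before
    extraction, so the record depends only on the element, not on which strand
    it sits on. Copies lacking an LTR annotation are skipped with a warning.
    ``tail_len``/``head_len`` are capped at the LTR lengths (min rule).
    """
    records: list[JunctionRecord] = []
    for copy in copies:
        if copy.ltr5 is None or copy.ltr3 is None:
            log.warning("copy %s lacks LTR annotations; skipped", copy.copy_id)
            continue
        elem = copy.element_seq(genome)
        l5, l3 = copy.ltr_lengths()
        tail_len = min(flank, l3)
        head_len = min(flank, l5)
        # element orientation: 5'LTR is the prefix, 3'LTR the suffix
        tail = elem[len(elem) - l3:][l3 - tail_len:]
        head = elem[:head_len]
        records.append(
            JunctionRecord(
                copy_id=copy.copy_id,
                family=copy.family,
                sequence=tail + head,
                junction_pos=tail_len,
                tail_len=tail_len,
                head_len=head_len,
            )
        )
    return records


def junction_spanning_reads(
    alignments: Sequence[AlignmentRecord],
    junction_pos: Mapping[str, int],
    min_overlap: int = 5,
) -> list[AlignmentRecord]:
    """Keep alignments whose single contiguous matched block crosses the junction
    with at least ``min_overlap`` bp on both LTRs.

    Split alignments whose blocks merely abut the junction do not count: a
    genuine circular template yields contiguous sequence across the fusion.
    """
    kept: list[AlignmentRecord] = []
    for rec in alignments:
        jp = junction_pos.get(rec.reference_name)
        if jp is None:
            continue
        for bs, be in rec.matched_blocks:
            if jp - bs >= min_overlap and be - jp >= min_overlap:
                kept.append(rec)
                break
    return kept


def verify_junction_crossing(
    records: Sequence[AlignmentRecord],
    reads: Mapping[str, str],
    library: Mapping[str, "JunctionRecord"],
    window: int = 10,
) -> list[AlignmentRecord]:
    """Require an exact sequence match across the junction.

    A bounded-mismatch extension can occasionally carry an alignment a few
    coincidentally matching bases past its true endpoint, which would let a
    linear-template read masquerade as junction-crossing. This guard re-checks
    the read bases over ``[junction - window, junction + window)`` against the
    junction record and keeps only exact matches over the full window — cheap,
    and a genuine circle-derived read (without a sequencing error at the
    junction) always passes.
    """
    kept: list[AlignmentRecord] = []
    for rec in records:
        jrec = library.get(rec.reference_name)
        seq = reads.get(rec.read_id)
        if jrec is None or seq is None:
            continue
        jp = jrec.junction_pos
        if rec.ref_start > jp - window or rec.ref_end < jp + window:
            continue
        oriented = seq if rec.strand == "+" else revcomp(seq)
        off = rec.query_start + (jp - window - rec.ref_start)
        if oriented[off: off + 2 * window] == jrec.sequence[jp - window: jp + window]:
            kept.append(rec)
    return kept


def junction_signal(
    filtered: Sequence[AlignmentRecord],
    dedup: bool = True,
) -> dict[str, float]:
    """Raw per-copy signal: summed per-base depth of junction-spanning reads.

    With ``dedup`` (default), coordinate-identical reads beyond the first are
    ignored, mirroring duplicate-ignoring coverage counting.
    """
    records = mark_duplicates(filtered) if dedup else filtered
    raw: dict[str, float] = {}
    for rec in records:
        if dedup and rec.is_duplicate:
            continue
        raw[rec.reference_name] = raw.get(rec.reference_name, 0.0) + rec.aligned_len
    return raw


def normalize_signal(
    raw: Mapping[str, float],
    sample_total_genome_coverage: float,
    sample_id: str,
    families: Mapping[str, str],
    is_genomic_control: bool = False,
    scale: float = 1e6,
) -> list[MobilitySignal]:
    """Normalize per-copy raw signals by the sample's total genome coverage.

    ``normalized = raw / total * scale`` (per-million-bases by default; the
    constant is inert for the ratio-based comparisons downstream).
    """
    if sample_total_genome_coverage <= 0:
        raise ValueError("sample total genome coverage must be positive")
    return [
        MobilitySignal(
            sample_id=sample_id,
            copy_id=copy_id,
            family=families.get(copy_id, copy_id),
            raw_junction_coverage=val,
            normalized=val / sample_total_genome_coverage * scale,
            is_genomic_control=is_genomic_control,
        )
        for copy_id, val in raw.items()
    ]


def family_signal(signals: Iterable[MobilitySignal]) -> list[MobilitySignal]:
    """Sum per-copy normalized signals per (sample, family, control-flag)."""
    agg: dict[tuple[str, str, bool], MobilitySignal] = {}
    for s in signals:
        key = (s.sample_id, s.family, s.is_genomic_control)
        if key in agg:
            agg[key].raw_junction_coverage += s.raw_junction_coverage
            agg[key].normalized += s.normalized
        else:
            agg[key] = MobilitySignal(
                sample_id=s.sample_id,
                copy_id=s.family,
                family=s.family,
                raw_junction_coverage=s.raw_junction_coverage,
                normalized=s.normalized,
                is_genomic_control=s.is_genomic_control,
            )
    return list(agg.values())


def scan_junctions(
    reads: Sequence[Read],
    library: Sequence[JunctionRecord],
    genome: Mapping[str, str] | KmerIndex,
    sample_id: str,
    min_overlap: int = 5,
    is_genomic_control: bool = False,
    junction_index: KmerIndex | None = None,
    verify_window: int = 10,
) -> list[MobilitySignal]:
    """End-to-end per-copy junction signal for one sample's read set.

    Aligns reads all-hits to the junction library, filters for
    junction-spanning reads (geometric >=``min_overlap`` bp rule, then exact
    sequence verification over ``verify_window`` bp on either side of the
    fusion), computes duplicate-ignoring coverage and normalizes by the
    sample's total genome-wide coverage (best-hit alignment of the same reads
    to the reference genome). Returns per-copy signals; empty input yields an
    empty list with a warning.
    """
    if not reads:
        log.warning("sample %s: no reads; zero-signal result", sample_id)
        return []
    lib_seqs = {rec.copy_id: rec.sequence for rec in library}
    jpos = {rec.copy_id: rec.junction_pos for rec in library}
    families = {rec.copy_id: rec.family for rec in library}
    if junction_index is None:
        junction_index = KmerIndex(lib_seqs)
    hits = naive_align(reads, junction_index, all_hits=True)
    spanning = junction_spanning_reads(hits, jpos, min_overlap=min_overlap)
    if verify_window:
        spanning = verify_junction_crossing(
            spanning, dict(reads), {r.copy_id: r for r in library}, window=verify_window
        )
    raw = junction_signal(spanning, dedup=True)
    genome_hits = naive_align(reads, genome, all_hits=False)
    total = float(sum(rec.aligned_len for rec in genome_hits))
    if total <= 0:
        log.warning("sample %s: no genomic coverage; zero-signal result", sample_id)
        return [
            MobilitySignal(sample_id, c, families[c], 0.0, 0.0, is_genomic_control)
            for c in raw
        ]
    sigs = normalize_signal(
        raw, total, sample_id, families, is_genomic_control=is_genomic_control
    )
    return sigs


def genomic_control(
    wgs_reads: Sequence[Read],
    library: Sequence[JunctionRecord],
    genome: Mapping[str, str] | KmerIndex,
    sample_id: str,
    min_overlap: int = 5,
    junction_index: KmerIndex | None = None,
) -> list[MobilitySignal]:
    """Background control: the identical computation applied to genomic reads.

    Reported side-by-side with mobilome signals, so the mobilome-specific
    signal is the excess over this genomic background (nonzero only when the
    genome itself contains tail-to-head-like junctions, e.g. tandem or nested
    arrangements).
    """
    return scan_junctions(
        wgs_reads,
        library,
        genome,
        sample_id,
        min_overlap=min_overlap,
        is_genomic_control=True,
        junction_index=junction_index,
    )
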