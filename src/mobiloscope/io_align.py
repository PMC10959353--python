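"""Format I/O, read-set utilities and a minimal all-hits aligner.

The aligner uses exact k-mer seeding plus ungapped extension with a bounded
mismatch budget, reporting every passing location when ``all_hits`` is set —
the "count every alignment" convention the coverage stages of the pipeline
rely on. It exists so the pipeline runs on synthetic data without external
binaries; external SAM alignments are accepted anywhere alignments are
consumed.

Internal coordinates are 0-based half-open everywhere; conversion happens only
at the SAM boundary (pysam handles it).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

__all__ = [
    "AlignmentRecord",
    "ReadSet",
    "KmerIndex",
    "downsample",
    "filter_organelle",
    "naive_align",
    "align_contig",
    "mark_duplicates",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_sam",
    "read_sam",
    "write_bed",
]

Read = tuple[str, str]  # (name, sequence)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One (possibly split, possibly soft-clipped) ungapped alignment."""

    read_id: str
    reference_name: str
    ref_start: int
    ref_end: int
    strand: str
    matched_blocks: list[tuple[int, int]]
    n_clipped_bases: int = 0
    query_start: int = 0  # offset of the first aligned base in the oriented read
    is_duplicate: bool = False
    mapq: int = 60
    n_mismatch: int = 0
    score: int = 0

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("ref_end must exceed ref_start")
        blocks = sorted(self.matched_blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if e1 > s2:
                raise ValueError("matched blocks must be non-overlapping")
        self.matched_blocks = blocks

    @property
    def aligned_len(self) -> int:
        return sum(e - s for s, e in self.matched_blocks)


@dataclass
class ReadSet:
    """A set of reads held in memory; paired reads are interleaved /1, /2."""

    reads: list[Read]
    paired: bool = False
    name: str = ""

    @property
    def read_count(self) -> int:
        return len(self.reads)

    @classmethod
    def from_fastq(cls, path: str | Path, paired: bool = False) -> "ReadSet":
        return cls(read_fastq(path), paired=paired, name=str(path))


# ---------------------------------------------------------------------------
# plain-text format I/O (Biopython / pysam backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable[Read], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in items
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    """Write BED6-style rows (chrom, start, end, name, score, strand, ...)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _cigar_from_record(rec: AlignmentRecord) -> list[tuple[int, int]]:
    cig: list[tuple[int, int]] = []
    if rec.query_start > 0:
        cig.append((4, rec.query_start))  # leading soft clip
    blocks = rec.matched_blocks
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cig.append((3, gap))  # N: skipped reference (split alignment)
        cig.append((0, e - s))  # M
    trailing = rec.n_clipped_bases - rec.query_start
    if trailing > 0:
        cig.append((4, trailing))
    return cig


def write_sam(
    records: Iterable[AlignmentRecord],
    references: Mapping[str, str] | Mapping[str, int],
    path: str | Path,
) -> None:
    """Write records as headerful SAM (@SQ lines from the reference set)."""
    ref_lens = {
        name: (len(v) if isinstance(v, str) else int(v))
        for name, v in references.items()
    }
    names = list(ref_lens)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ref_lens[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = tid[rec.reference_name]
            a.reference_start = rec.ref_start
            a.mapping_quality = rec.mapq
            a.cigar = _cigar_from_record(rec)
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_duplicate:
                flag |= 0x400
            a.flag = flag
            a.query_sequence = None
            out.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            blocks = [(s, e) for s, e in a.get_blocks()]
            cig = a.cigartuples or []
            clipped = sum(length for op, length in cig if op in (4, 5))
            qstart = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    reference_name=a.reference_name,
                    ref_start=a.reference_start,
                    ref_end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                    matched_blocks=blocks,
                    n_clipped_bases=clipped,
                    query_start=qstart,
                    is_duplicate=a.is_duplicate,
                    mapq=a.mapping_quality,
                )
            )
    return records


# ---------------------------------------------------------------------------
# read-set utilities
# ---------------------------------------------------------------------------

def downsample(readsets: Sequence[ReadSet], seed: int = 0) -> list[ReadSet]:
    """Downsample every set to the read count of the smallest set.

    Sampling is uniform without replacement; mates of a paired set are kept
    together (pairs are sampled as units).
    """
    if not readsets:
        raise ValueError("need at least one readset")
    if any(rs.read_count == 0 for rs in readsets):
        raise ValueError("cannot downsample an empty readset")
    target = min(rs.read_count for rs in readsets)
    rng = np.random.default_rng(seed)
    out: list[ReadSet] = []
    for rs in readsets:
        if rs.read_count == target:
            out.append(ReadSet(list(rs.reads), rs.paired, rs.name))
            continue
        if rs.paired:
            n_pairs = rs.read_count // 2
            keep = rng.choice(n_pairs, size=target // 2, replace=False)
            keep.sort()
            reads = [r for i in keep for r in rs.reads[2 * i: 2 * i + 2]]
        else:
            keep = rng.choice(rs.read_count, size=target, replace=False)
            keep.sort()
            reads = [rs.reads[i] for i in keep]
        out.append(ReadSet(reads, rs.paired, rs.name))
    return out


# ---------------------------------------------------------------------------
# k-mer index + ungapped extension aligner
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer location index over a set of reference sequences."""

    def __init__(self, references: Mapping[str, str], k: int = 21):
        if not references:
            raise ValueError("reference set is empty")
        if any(len(s) < k for s in references.values()):
            raise ValueError(f"every reference must be at least k={k} bp long")
        self.k = k
        self.refs = {n: s.upper() for n, s in references.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.refs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i: i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, i))
        self.index = index

    def seed_hits(self, seq: str, stride: int) -> dict[tuple[str, int], int]:
        """Candidate (reference, diagonal) pairs; value = one seed query offset."""
        k = self.k
        positions = list(range(0, len(seq) - k + 1, stride))
        if positions and positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        cands: dict[tuple[str, int], int] = {}
        for q in positions:
            for name, pos in self.index.get(seq[q: q + k], ()):
                cands.setdefault((name, pos - q), q)
        return cands


_MISMATCH_PENALTY = 3
_XDROP = 12


def _extend(
    seq: str,
    ref: str,
    diag: int,
    seed_q: int,
    k: int,
    budget: int,
) -> tuple[int, int, int] | None:
    """Grow a match window around the seed on one diagonal.

    Extension stops at the mismatch budget or when the running score
    (+1 match, −3 mismatch) drops ``_XDROP`` below its best — the X-drop rule
    keeps blocks from drifting into unrelated sequence past a true boundary.
    Returns (query_start, query_end, mismatches) of the accepted window in
    read coordinates, or None when the overlap is empty.
    """
    L = len(seq)
    s = max(diag, 0)
    e = min(diag + L, len(ref))
    if e - s < k:
        return None
    qs, qe = s - diag, e - diag
    sub_r = ref[s:e]
    sub_q = seq[qs:qe]
    if sub_q == sub_r:
        return qs, qe, 0
    mm = [a != b for a, b in zip(sub_q, sub_r)]
    a = seed_q - qs
    b = a + k
    used = sum(mm[a:b])
    if used > budget:
        return None

    # forward: best-scoring exclusive end >= b (endpoints always on a match)
    score = best = used_f = used_f_best = 0
    j_best = b
    j = b
    while j < len(mm):
        if mm[j]:
            if used + used_f + 1 > budget:
                break
            used_f += 1
            score -= _MISMATCH_PENALTY
            if score < best - _XDROP:
                break
        else:
            score += 1
            if score > best:
                best, j_best, used_f_best = score, j + 1, used_f
        j += 1
    used += used_f_best
    # backward: best-scoring inclusive start <= a
    score = best = used_b = used_b_best = 0
    i_best = a
    i = a - 1
    while i >= 0:
        if mm[i]:
            if used + used_b + 1 > budget:
                break
            used_b += 1
            score -= _MISMATCH_PENALTY
            if score < best - _XDROP:
                break
        else:
            score += 1
            if score > best:
                best, i_best, used_b_best = score, i, used_b
        i -= 1
    used += used_b_best
    if j_best <= i_best:
        return None
    return qs + i_best, qs + j_best, used


def naive_align(
    reads: Iterable[Read],
    reference: Mapping[str, str] | KmerIndex,
    seed_len: int = 21,
    all_hits: bool = True,
    max_mismatch_rate: float = 0.05,
    min_block: int | None = None,
    seed_stride: int | None = None,
) -> list[AlignmentRecord]:
    """Align reads by exact-k-mer seeding and ungapped extension.

    With ``all_hits`` every passing location is reported (the all-alignments
    coverage convention); otherwise only the best-scoring location per read.
    Soft-clipped tails (bases outside the accepted window) are recorded in
    ``n_clipped_bases``. Score = matched bases − 2·mismatches.
    """
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, seed_len)
    k = index.k
    if min_block is None:
        min_block = k
    results: list[AlignmentRecord] = []
    for read_id, seq in reads:
        seq = seq.upper()
        if len(seq) < k:
            continue
        stride = seed_stride or max(1, (len(seq) - k) // 4 or 1)
        budget = int(max_mismatch_rate * len(seq))
        hits: dict[tuple[str, int, int, str], AlignmentRecord] = {}
        best: AlignmentRecord | None = None
        perfect = False
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            if perfect and not all_hits:
                break
            for (ref_name, diag), seed_q in index.seed_hits(oriented, stride).items():
                ext = _extend(oriented, index.refs[ref_name], diag, seed_q, k, budget)
                if ext is None:
                    continue
                qs, qe, n_mm = ext
                if qe - qs < min_block:
                    continue
                rs, re_ = diag + qs, diag + qe
                key = (ref_name, rs, re_, strand)
                if key in hits:
                    continue
                rec = AlignmentRecord(
                    read_id=read_id,
                    reference_name=ref_name,
                    ref_start=rs,
                    ref_end=re_,
                    strand=strand,
                    matched_blocks=[(rs, re_)],
                    n_clipped_bases=len(seq) - (qe - qs),
                    query_start=qs,
                    n_mismatch=n_mm,
                    score=(qe - qs) - 2 * n_mm,
                )
                hits[key] = rec
                if best is None or rec.score > best.score:
                    best = rec
                if n_mm == 0 and qe - qs == len(seq):
                    perfect = True
                    if not all_hits:
                        break
        if all_hits:
            results.extend(hits.values())
        elif best is not None:
            results.append(best)
    return results


def align_contig(
    contig: Read,
    reference: Mapping[str, str] | KmerIndex,
    seed_len: int = 21,
    seed_stride: int = 50,
    max_mismatch_rate: float = 0.05,
    min_block: int = 50,
) -> list[AlignmentRecord]:
    """Split-align a long query: one record per selected diagonal block.

    Each candidate diagonal is extended to a block; blocks are then greedily
    selected by score so that accepted blocks cover mostly disjoint parts of
    the query — the analogue of a primary + supplementary split alignment. A
    contig built from a rotated circular template therefore yields two blocks
    flanking the circle closure.
    """
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, seed_len)
    k = index.k
    name, seq = contig
    seq = seq.upper()
    candidates: list[tuple[int, int, int, str, str, int]] = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        budget = int(max_mismatch_rate * len(oriented))
        for (ref_name, diag), seed_q in index.seed_hits(oriented, seed_stride).items():
            ext = _extend(oriented, index.refs[ref_name], diag, seed_q, k, budget)
            if ext is None:
                continue
            qs, qe, n_mm = ext
            if qe - qs < min_block:
                continue
            score = (qe - qs) - 2 * n_mm
            candidates.append((score, qs, qe, strand, ref_name, diag))
    candidates.sort(key=lambda c: -c[0])
    chosen: list[AlignmentRecord] = []
    covered: list[tuple[int, int]] = []
    for score, qs, qe, strand, ref_name, diag in candidates:
        overlap = sum(max(0, min(qe, e) - max(qs, s)) for s, e in covered)
        if overlap > 0.5 * (qe - qs):
            continue
        covered.append((qs, qe))
        rs, re_ = diag + qs, diag + qe
        chosen.append(
            AlignmentRecord(
                read_id=name,
                reference_name=ref_name,
                ref_start=rs,
                ref_end=re_,
                strand=strand,
                matched_blocks=[(rs, re_)],
                n_clipped_bases=len(seq) - (qe - qs),
                query_start=qs,
                score=score,
            )
        )
    return chosen


def mark_duplicates(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Flag records identical in (reference, start, end, strand) beyond the first.

    Mirrors duplicate-ignoring coverage counting: the first record of each
    coordinate-identical group stays unflagged, the rest become duplicates.
    """
    seen: set[tuple[str, int, int, str]] = set()
    out: list[AlignmentRecord] = []
    for rec in records:
        key = (rec.reference_name, rec.ref_start, rec.ref_end, rec.strand)
        dup = key in seen
        seen.add(key)
        out.append(replace(rec, is_duplicate=dup or rec.is_duplicate))
    return out


def filter_organelle(
    reads: ReadSet,
    organelle_refs: Mapping[str, str] | KmerIndex,
    seed_len: int = 21,
    max_mismatch_rate: float = 0.05,
) -> ReadSet:
    """Retain only reads that fail to align to any organelle reference.

    Mirrors keeping unmapped reads after an organelle alignment: a read with
    any accepted hit (seed match + extension within the mismatch budget) is
    discarded.
    """
    index = (
        organelle_refs
        if isinstance(organelle_refs, KmerIndex)
        else KmerIndex(organelle_refs, seed_len)
    )
    kept: list[Read] = []
    for read in reads.reads:
        hits = naive_align(
            [read], index, all_hits=False, max_mismatch_rate=max_mismatch_rate
        )
        if not hits:
            kept.append(read)
    return ReadSet(kept, paired=reads.paired, name=reads.name)
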