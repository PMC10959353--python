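"""Ground-truthed synthetic inputs for the mobilome / copy-number pipeline.

This module simulates the data structures the analysis assumes, each with an
explicit truth record so every downstream estimate can be scored against a
known answer:

* LTR-retrotransposon *families*: a consensus built as LTR + internal + LTR,
  with mutually dissimilar random sequences per family.
* A *genome* carrying non-overlapping full-length copies of those families,
  each flanked by a target-site duplication (TSD) and annotated with per-copy
  LTR intervals.
* *eccDNA pools*: 2-LTR circles (the full-length element circularized so the
  3'LTR end abuts the 5'LTR start — the hallmark of a transposition-competent
  element), 1-LTR circles, and fragmented circles.
* Rolling-circle-amplified (RCA) *mobilome reads* sampled with wrap-around on
  the circle, and plain *WGS reads* sampled linearly.
* A multi-accession *panel* of copy numbers generated under a random-intercept
  linear mixed model with clade structure and bioclimatic fixed effects.

All randomness flows from a single integer seed through a named generator per
sub-task, so adding one simulation does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import gc_content, mutate, random_seq, revcomp

__all__ = [
    "FamilyModel",
    "FullLengthCopy",
    "SyntheticGenome",
    "CircleKind",
    "EccCircle",
    "PanelSpec",
    "PlacementError",
    "make_family_panel",
    "build_genome",
    "simulate_eccdna_pool",
    "rca_reads",
    "wgs_reads",
    "simulate_accession_panel",
    "panel_spec_for_marginal_r2",
]


class PlacementError(RuntimeError):
    """Raised when copies cannot be placed without overlap after bounded retries."""


def _rng(seed: int, task: str) -> np.random.Generator:
    """Named child generator: one stream per simulation sub-task."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(task.encode())])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyModel:
    """An LTR-RT family: consensus = LTR + internal region + identical LTR."""

    name: str
    classification: str  # "RLC" (Ty1/Copia-like) or "RLG" (Ty3-like)
    ltr_seq: str
    internal_seq: str

    def __post_init__(self) -> None:
        if self.classification not in ("RLC", "RLG"):
            raise ValueError(f"classification must be RLC or RLG, got {self.classification!r}")
        if len(self.ltr_seq) < 1:
            raise ValueError("LTR length must be >= 1")
        if set(self.ltr_seq + self.internal_seq) - set("ACGT"):
            raise ValueError("family sequences must be over the alphabet {A,C,G,T}")

    @property
    def ltr_len(self) -> int:
        return len(self.ltr_seq)

    @property
    def consensus(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq


@dataclass
class FullLengthCopy:
    """A genomic full-length element with per-copy LTR intervals.

    Coordinates are 0-based half-open on the genome. ``ltr5``/``ltr3`` refer
    to the element's own 5'/3' LTR in element orientation; for a minus-strand
    copy the 5'LTR therefore sits at the *right* end in genome coordinates.
    """

    copy_id: str
    family: str
    chrom: str
    start: int
    end: int
    strand: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("copy end must exceed start")
        for iv in (self.ltr5, self.ltr3):
            if iv is not None and not (self.start <= iv[0] < iv[1] <= self.end):
                raise ValueError("LTR interval must be non-empty and inside the copy")

    def element_seq(self, chromosomes: Mapping[str, str]) -> str:
        """Copy sequence in element orientation (5'LTR first)."""
        s = chromosomes[self.chrom][self.start:self.end]
        return revcomp(s) if self.strand == "-" else s

    def ltr_lengths(self) -> tuple[int, int]:
        return (self.ltr5[1] - self.ltr5[0], self.ltr3[1] - self.ltr3[0])


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    copies: list[FullLengthCopy]
    tsd_len: int

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


class CircleKind(str, Enum):
    TWO_LTR = "TWO_LTR"
    ONE_LTR = "ONE_LTR"
    FRAGMENT = "FRAGMENT"


@dataclass
class EccCircle:
    """A circular molecule stored as its linear sequence plus a circular flag.

    Sampling with wrap-around uses the doubled sequence, so no special circular
    data structure is needed.
    """

    circle_id: str
    kind: CircleKind
    sequence: str
    source_copy: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def doubled(self) -> str:
        return self.sequence + self.sequence


# ---------------------------------------------------------------------------
# families and genome
# ---------------------------------------------------------------------------

def make_family_panel(
    n_families: int,
    ltr_len: int = 300,
    internal_len: int = 4000,
    seed: int = 0,
    rlc_fraction: float = 0.5,
) -> list[FamilyModel]:
    """Generate ``n_families`` mutually dissimilar LTR-RT family models.

    LTR and internal sequences are drawn i.i.d. uniform per family, so the
    expected pairwise identity between the LTRs of two families is 25% —
    far below the 80% dissimilarity requirement.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if ltr_len < 10:
        raise ValueError("ltr_len must be >= 10")
    if internal_len < 0:
        raise ValueError("internal_len must be >= 0")
    rng = _rng(seed, "families")
    n_rlc = int(round(rlc_fraction * n_families))
    families = []
    for i in range(n_families):
        cls = "RLC" if i < n_rlc else "RLG"
        prefix = "RLC_fam" if cls == "RLC" else "RLG_fam"
        families.append(
            FamilyModel(
                name=f"{prefix}{i:02d}",
                classification=cls,
                ltr_seq=random_seq(rng, ltr_len),
                internal_seq=random_seq(rng, internal_len),
            )
        )
    return families


def build_genome(
    families: Sequence[FamilyModel],
    copy_spec: Mapping[str, int],
    chrom_len: int,
    tsd_len: int = 5,
    divergence: float = 0.0,
    seed: int = 0,
    chrom_name: str = "chr1",
    max_retries: int = 200,
    min_separation: int = 100,
) -> SyntheticGenome:
    """Insert full-length copies into a random background chromosome.

    Every insertion is flanked by an exact target-site duplication of
    ``tsd_len`` bp (the integrase's direct repeat); per-copy ``divergence``
    applies uniform substitutions relative to the family consensus.
    """
    if not 0.0 <= divergence <= 0.1:
        raise ValueError("divergence must be in [0, 0.1]")
    if tsd_len < 0:
        raise ValueError("tsd_len must be >= 0")
    fam_by_name = {f.name: f for f in families}
    unknown = set(copy_spec) - set(fam_by_name)
    if unknown:
        raise ValueError(f"copy_spec names unknown families: {sorted(unknown)}")
    total_inserted = sum(
        (len(fam_by_name[n].consensus) + tsd_len) * c for n, c in copy_spec.items()
    )
    if total_inserted >= chrom_len:
        raise ValueError("total inserted length must be smaller than chrom_len")

    rng = _rng(seed, "genome")
    background = random_seq(rng, chrom_len)

    jobs: list[str] = []
    for name, count in copy_spec.items():
        if count < 0:
            raise ValueError("copy counts must be >= 0")
        jobs.extend([name] * count)
    rng.shuffle(jobs)

    # sample insertion points in background coordinates, enforcing separation
    # (keeps inserted elements apart so coverage blocks stay attributable)
    margin = tsd_len + 1
    min_sep = max(min_separation, tsd_len + 1)
    points: list[int] = []
    for _ in range(len(jobs)):
        for attempt in range(max_retries):
            p = int(rng.integers(margin, chrom_len - margin - tsd_len))
            if all(abs(p - q) >= min_sep for q in points):
                points.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {len(jobs)} copies into {chrom_len} bp "
                f"after {max_retries} retries each"
            )
    order = np.argsort(points)
    jobs = [jobs[i] for i in order]
    points = [points[i] for i in order]

    pieces: list[str] = []
    copies: list[FullLengthCopy] = []
    prev = 0
    offset = 0
    for name, p in zip(jobs, points):
        fam = fam_by_name[name]
        elem = mutate(rng, fam.consensus, divergence)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = elem if strand == "+" else revcomp(elem)
        pieces.append(background[prev: p + tsd_len])
        pieces.append(inserted)
        prev = p
        start = p + tsd_len + offset
        end = start + len(elem)
        ell = fam.ltr_len
        if strand == "+":
            ltr5, ltr3 = (start, start + ell), (end - ell, end)
        else:
            ltr5, ltr3 = (end - ell, end), (start, start + ell)
        copies.append(
            FullLengthCopy(
                copy_id=f"{name}_{chrom_name}_{start}",
                family=name,
                chrom=chrom_name,
                start=start,
                end=end,
                strand=strand,
                ltr5=ltr5,
                ltr3=ltr3,
                meta={
                    "age_pct": 100.0 * divergence,
                    "gc_pct": 100.0 * gc_content(elem),
                },
            )
        )
        offset += len(elem) + tsd_len
    pieces.append(background[prev:])
    return SyntheticGenome(
        chromosomes={chrom_name: "".join(pieces)}, copies=copies, tsd_len=tsd_len
    )


# ---------------------------------------------------------------------------
# eccDNA pools and reads
# ---------------------------------------------------------------------------

def simulate_eccdna_pool(
    genome: SyntheticGenome,
    mix: Mapping[CircleKind | str, int],
    copies: Sequence[FullLengthCopy] | None = None,
    seed: int = 0,
    min_fragment: int = 500,
) -> list[EccCircle]:
    """Produce circles of each requested kind from each selected copy.

    * ``TWO_LTR``: the full-length linear element circularized, so the doubled
      sequence contains the 3'LTR-end → 5'LTR-start junction.
    * ``ONE_LTR``: the element minus its 5'LTR (exactly one LTR remains).
    * ``FRAGMENT``: a proper substring of the internal region circularized,
      never containing a complete LTR.
    """
    rng = _rng(seed, "eccdna")
    if copies is None:
        copies = genome.copies
    mix = {CircleKind(k): int(v) for k, v in mix.items()}
    circles: list[EccCircle] = []
    for copy in copies:
        elem = copy.element_seq(genome.chromosomes)
        if copy.ltr5 is None or copy.ltr3 is None:
            raise ValueError(f"copy {copy.copy_id} lacks LTR annotations")
        l5, l3 = copy.ltr_lengths()
        for kind, count in mix.items():
            for i in range(count):
                cid = f"{copy.copy_id}_{kind.value}_{i}"
                if kind is CircleKind.TWO_LTR:
                    seq = elem
                elif kind is CircleKind.ONE_LTR:
                    seq = elem[l5:]
                else:
                    internal = elem[l5: len(elem) - l3]
                    if len(internal) <= min_fragment:
                        frag_len = max(1, len(internal) - 1)
                    else:
                        frag_len = int(rng.integers(min_fragment, len(internal)))
                    start = int(rng.integers(0, len(internal) - frag_len + 1))
                    seq = internal[start: start + frag_len]
                circles.append(EccCircle(cid, kind, seq, copy.copy_id))
    return circles


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    return mutate(rng, seq, error_rate) if error_rate > 0 else seq


def rca_reads(
    circles: Sequence[EccCircle],
    depth: float = 20.0,
    read_len: int = 100,
    frag_len: int = 300,
    paired: bool = False,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Rolling-circle-amplified reads: fragments sampled uniformly with wrap-around.

    Fragments start uniformly on the circle and extend over the closure point
    (concatemeric template), so a read crosses the closure with probability
    ``read_len / circle_len``. Returns ``(reads, truth)`` where truth records
    each read's source circle, circular offset and strand.

    Reads are (name, sequence) tuples; FASTQ serialization lives in
    :mod:`mobiloscope.io_align`.
    """
    if read_len > frag_len:
        raise ValueError("read_len must not exceed frag_len")
    rng = _rng(seed, "rca")
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    reads_per_frag = 2 if paired else 1
    for circle in circles:
        L = len(circle.sequence)
        if L == 0:
            continue
        n_frags = max(0, int(round(depth * L / (read_len * reads_per_frag))))
        doubled = circle.doubled
        for i in range(n_frags):
            flen = min(frag_len, 2 * L)
            start = int(rng.integers(0, L))
            frag = doubled[start: start + flen]
            while len(frag) < flen:  # fragment longer than one full turn
                frag += doubled[: flen - len(frag)]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            r1 = _apply_errors(rng, frag[:read_len], error_rate)
            name = f"{circle.circle_id}|rca{i}"
            reads.append((f"{name}/1" if paired else name, r1))
            truth_rows.append(
                {
                    "read_id": f"{name}/1" if paired else name,
                    "circle_id": circle.circle_id,
                    "kind": circle.kind.value,
                    "offset": start,
                    "strand": strand,
                    "mate": 1,
                }
            )
            if paired:
                r2 = _apply_errors(rng, revcomp(frag[-read_len:]), error_rate)
                reads.append((f"{name}/2", r2))
                truth_rows.append(
                    {
                        "read_id": f"{name}/2",
                        "circle_id": circle.circle_id,
                        "kind": circle.kind.value,
                        "offset": (start + flen - read_len) % L,
                        "strand": strand,
                        "mate": 2,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "circle_id", "kind", "offset", "strand", "mate"],
    )
    return reads, truth


def wgs_reads(
    genome: SyntheticGenome,
    depth: float = 15.0,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    paired: bool = False,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform linear sampling of whole-genome shotgun reads with truth positions."""
    rng = _rng(seed, "wgs")
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    reads_per_unit = 2 if paired else 1
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        if L < read_len:
            continue
        n = int(round(depth * L / (read_len * reads_per_unit)))
        starts = rng.integers(0, L - read_len + 1, size=n)
        strands = rng.random(n) < 0.5
        for i, (s, minus) in enumerate(zip(starts, strands)):
            s = int(s)
            frag = seq[s: s + read_len]
            r = revcomp(frag) if minus else frag
            name = f"{chrom}|wgs{i}"
            if paired:
                # insert of 2*read_len: mate maps read_len downstream
                s2 = min(s + read_len, L - read_len)
                frag2 = seq[s2: s2 + read_len]
                r2 = frag2 if minus else revcomp(frag2)
                reads.append((f"{name}/1", _apply_errors(rng, r, error_rate)))
                reads.append((f"{name}/2", _apply_errors(rng, r2, error_rate)))
                truth_rows.append({"read_id": f"{name}/1", "chrom": chrom, "pos": s,
                                   "strand": "-" if minus else "+"})
                truth_rows.append({"read_id": f"{name}/2", "chrom": chrom, "pos": s2,
                                   "strand": "+" if minus else "-"})
            else:
                reads.append((name, _apply_errors(rng, r, error_rate)))
                truth_rows.append({"read_id": name, "chrom": chrom, "pos": s,
                                   "strand": "-" if minus else "+"})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "chrom", "pos", "strand"])
    return reads, truth


# ---------------------------------------------------------------------------
# accession panel under the random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclass
class PanelSpec:
    """Generating model for a multi-accession copy-number panel.

    ``pcn = baseline + clade_intercept + x @ effect_sizes + noise`` with
    ``clade_intercept ~ N(0, clade_var)`` and ``noise ~ N(0, resid_var)``,
    truncated at zero. Bioclimatic covariates are i.i.d. standard normal,
    so the generating fixed-effect variance is ``sum(effect_sizes**2)``.
    """

    n_accessions: int = 320
    n_clades: int = 5
    effect_sizes: Sequence[float] = (0.0,)
    clade_var: float = 1.0
    resid_var: float = 1.0
    baseline: float = 50.0
    family: str = "fam0"

    def __post_init__(self) -> None:
        if self.clade_var < 0 or self.resid_var < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_clades < 1 or self.n_accessions < self.n_clades:
            raise ValueError("need n_accessions >= n_clades >= 1")

    @property
    def fixed_var(self) -> float:
        return float(np.sum(np.asarray(self.effect_sizes, dtype=float) ** 2))

    @property
    def generating_marginal_r2(self) -> float:
        denom = self.fixed_var + self.clade_var + self.resid_var
        if denom == 0:
            raise ValueError("all variance components are zero")
        return self.fixed_var / denom


def panel_spec_for_marginal_r2(
    r2m: float,
    n_accessions: int = 320,
    n_clades: int = 5,
    clade_var: float = 1.0,
    resid_var: float = 1.0,
    baseline: float = 50.0,
) -> PanelSpec:
    """One-covariate spec whose generating marginal R² equals ``r2m``."""
    if not 0.0 <= r2m < 1.0:
        raise ValueError("marginal R2 must be in [0, 1)")
    beta = float(np.sqrt(r2m * (clade_var + resid_var) / (1.0 - r2m)))
    return PanelSpec(
        n_accessions=n_accessions,
        n_clades=n_clades,
        effect_sizes=(beta,),
        clade_var=clade_var,
        resid_var=resid_var,
        baseline=baseline,
    )


def simulate_accession_panel(
    spec: PanelSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate an accession panel table plus generating-model truth metadata.

    Returns a long table with columns ``accession, clade, bio_1.., pcn`` and a
    dict holding the generating marginal R² and the drawn clade intercepts.
    """
    rng = _rng(seed, "panel")
    n, g = spec.n_accessions, spec.n_clades
    betas = np.asarray(spec.effect_sizes, dtype=float)
    k = betas.size
    clades = np.array([f"clade_{i % g}" for i in range(n)])
    rng.shuffle(clades)
    x = rng.standard_normal((n, k))
    intercepts = rng.normal(0.0, np.sqrt(spec.clade_var), size=g)
    clade_idx = np.array([int(c.split("_")[1]) for c in clades])
    y = (
        spec.baseline
        + intercepts[clade_idx]
        + x @ betas
        + rng.normal(0.0, np.sqrt(spec.resid_var), size=n)
    )
    y = np.clip(y, 0.0, None)
    df = pd.DataFrame({"accession": [f"acc{i:04d}" for i in range(n)], "clade": clades})
    for j in range(k):
        df[f"bio_{j + 1}"] = x[:, j]
    df["pcn"] = y
    truth = {
        "generating_marginal_r2": spec.generating_marginal_r2,
        "clade_intercepts": intercepts,
        "effect_sizes": betas,
        "clade_var": spec.clade_var,
        "resid_var": spec.resid_var,
    }
    return df, truth
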