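"""End-to-end study workflows on synthetic data.

These functions wire the generator and the analysis stages together the way
the corresponding wet-lab + bioinformatics study would: a multi-family genome,
mobilome samples split over genotypes and stresses, 2-LTR circles for the
active family only, rolling-circle reads, junction scanning with a
genomic-read background control, and circle-forming-region discovery from
synthetic assembly contigs. They exist so that validation experiments and the
worked examples run through one audited code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import random_seq
from .circle_regions import (
    CircleRegion,
    SpecificityCall,
    annotate_regions,
    contig_regions,
    merge_regions,
    retain_regions,
    specificity,
    top_contigs,
)
from .io_align import AlignmentRecord, KmerIndex, align_contig, naive_align
from .mobilome_junctions import (
    MobilitySignal,
    build_junction_library,
    family_signal,
    genomic_control,
    scan_junctions,
)
from .synthetic_data import (
    CircleKind,
    EccCircle,
    SyntheticGenome,
    build_genome,
    make_family_panel,
    rca_reads,
    simulate_eccdna_pool,
    wgs_reads,
)

__all__ = [
    "MobilomeStudyResult",
    "run_mobilome_study",
    "simulate_insertion_site_reads",
]

STRESSES = (
    "control", "cold", "drought", "heat", "salt",
    "submergence", "rice_blast", "glyphosate",
)


@dataclass
class MobilomeStudyResult:
    genome: SyntheticGenome
    active_family: str
    samples: pd.DataFrame  # sample_id, genotype, stress
    family_signals: pd.DataFrame  # sample_id, family, normalized, is_genomic_control
    regions: list[CircleRegion]
    genotype_calls: list[SpecificityCall]
    stress_calls: list[SpecificityCall]


def _synthetic_assembly(circles, rng, max_trim: int = 200):
    """Stand-in for de novo assembly of RCA reads: each circle becomes one
    contig, rotated to a random phase and lightly trimmed, as an assembler
    reconstructing a circular template from its concatemeric reads would
    produce."""
    contigs = []
    for i, circle in enumerate(circles):
        L = len(circle.sequence)
        r = int(rng.integers(0, L))
        seq = circle.sequence[r:] + circle.sequence[:r]
        trim = int(rng.integers(0, min(max_trim, max(1, L // 10))))
        if trim:
            seq = seq[: L - trim]
        contigs.append((f"{circle.circle_id}|contig{i}", seq))
    return contigs


def run_mobilome_study(
    seed: int = 0,
    n_families: int = 4,
    copies_per_family: int = 5,
    chrom_len: int = 500_000,
    n_samples: int = 12,
    mutant_fraction: float = 0.5,
    ltr_len: int = 300,
    internal_len: int = 4000,
    divergence: float = 0.01,
    circle_depth: float = 20.0,
    carryover_reads: int = 200,
    active_copies: int = 2,
    min_region_samples: int = 3,
) -> MobilomeStudyResult:
    """Simulate and analyse one full mobilome experiment.

    ``n_families`` families, ``copies_per_family`` full-length copies each, in
    a ``chrom_len`` genome. Samples are split into "mutant" and "wildtype"
    genotypes with stresses assigned round-robin; only mutant samples receive
    2-LTR circles, and only from the first family (the active one). Every
    sample additionally carries a little undigested linear genomic DNA
    (``carryover_reads``), so normalization totals are positive even for
    circle-free samples. The analysis half runs the junction pipeline
    (per-family normalized signals plus a WGS genomic control) and the
    circle-forming-region pipeline (synthetic assembly contigs, top-10
    selection, split alignment, merge, >= ``min_region_samples`` retention,
    TE annotation, stress/genotype specificity).
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x5EED])
    families = make_family_panel(
        n_families, ltr_len=ltr_len, internal_len=internal_len, seed=seed
    )
    copy_spec = {f.name: copies_per_family for f in families}
    genome = build_genome(
        families, copy_spec, chrom_len, divergence=divergence, seed=seed
    )
    active = families[0].name
    active_copy_list = [c for c in genome.copies if c.family == active][:active_copies]

    library = build_junction_library(genome.copies, genome.chromosomes)
    genome_index = KmerIndex(genome.chromosomes)
    junction_index = KmerIndex({r.copy_id: r.sequence for r in library})

    n_mut = int(round(mutant_fraction * n_samples))
    rows = []
    for i in range(n_samples):
        rows.append(
            {
                "sample_id": f"s{i:02d}",
                "genotype": "mutant" if i < n_mut else "wildtype",
                "stress": STRESSES[i % len(STRESSES)],
            }
        )
    samples = pd.DataFrame(rows)

    all_signals: list[MobilitySignal] = []
    intervals = []
    te_features = [(c.chrom, c.start, c.end, c.family) for c in genome.copies]
    for i, row in samples.iterrows():
        sid = row["sample_id"]
        circles: list[EccCircle] = []
        if row["genotype"] == "mutant":
            circles = simulate_eccdna_pool(
                genome, {CircleKind.TWO_LTR: 1}, copies=active_copy_list,
                seed=seed * 1009 + i,
            )
        reads, _ = rca_reads(circles, depth=circle_depth, seed=seed * 2003 + i)
        if carryover_reads > 0:
            linear, _ = wgs_reads(
                genome,
                depth=carryover_reads * 100 / genome.length,
                seed=seed * 3001 + i,
            )
            reads = reads + linear
        sigs = scan_junctions(
            reads, library, genome_index, sid, junction_index=junction_index
        )
        all_signals.extend(sigs)

        contigs = _synthetic_assembly(circles, rng)
        selected = top_contigs(contigs, n=10)
        recs: list[AlignmentRecord] = []
        for contig in selected:
            recs.extend(align_contig(contig, genome_index))
        intervals.extend(contig_regions(recs, sid))

    # genomic-read background control from one WGS run on the same genome
    wgs, _ = wgs_reads(genome, depth=2.0, seed=seed * 4001 + 17)
    all_signals.extend(
        genomic_control(wgs, library, genome_index, "genomic",
                        junction_index=junction_index)
    )

    fam_sigs = family_signal(all_signals)
    fam_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "family": s.family,
                "normalized": s.normalized,
                "is_genomic_control": s.is_genomic_control,
            }
            for s in fam_sigs
        ],
        columns=["sample_id", "family", "normalized", "is_genomic_control"],
    )

    regions = retain_regions(merge_regions(intervals), min_samples=min_region_samples)
    annotate_regions(regions, tes=te_features, genome=genome.chromosomes)
    genotype_labels = dict(zip(samples["sample_id"], samples["genotype"]))
    stress_labels = dict(zip(samples["sample_id"], samples["stress"]))
    genotype_calls = [specificity(r, genotype_labels, "genotype") for r in regions]
    stress_calls = [specificity(r, stress_labels, "stress") for r in regions]

    return MobilomeStudyResult(
        genome=genome,
        active_family=active,
        samples=samples,
        family_signals=fam_df,
        regions=regions,
        genotype_calls=genotype_calls,
        stress_calls=stress_calls,
    )


def simulate_insertion_site_reads(
    seed: int = 0,
    carrier_fraction: float = 0.5,
    n_reads: int = 30,
    read_len: int = 100,
    tsd_len: int = 5,
    te_len: int = 2000,
    flank_len: int = 4000,
    min_anchor: int = 21,
) -> tuple[list[AlignmentRecord], str, int]:
    """Reads covering a non-reference TE insertion point, for zygosity analysis.

    Builds a reference sequence and a carrier haplotype with a TE inserted
    (with target-site duplication) at its midpoint, then samples ``n_reads``
    reads whose span covers the insertion point, each drawn from the carrier
    haplotype with probability ``carrier_fraction`` (0.5 emulates a
    heterozygous plant, 1.0 a homozygous one). Read starts are restricted so
    both haplotypes' reads keep at least ``min_anchor`` aligned bases on the
    reference, giving each read an equal chance to be observed. Returns the
    best-hit alignments to the reference, the reference chromosome name, and
    the insertion position.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x71B])
    ref = random_seq(rng, 2 * flank_len)
    te = random_seq(rng, te_len)
    p = flank_len
    tsd = ref[p: p + tsd_len]
    carrier = ref[:p] + tsd + te + ref[p:]
    # reads anchored on the left flank, spanning the insertion point
    lo = p - read_len + min_anchor + tsd_len
    hi = p - min_anchor
    reads = []
    for i in range(n_reads):
        hap = carrier if rng.random() < carrier_fraction else ref
        s = int(rng.integers(lo, hi + 1))
        reads.append((f"site{i}", hap[s: s + read_len]))
    index = KmerIndex({"ref": ref})
    recs = naive_align(reads, index, all_hits=False, min_block=min_anchor)
    return recs, "ref", p
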