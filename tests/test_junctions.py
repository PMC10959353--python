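"""Tail-to-head junction library, spanning-read filter and signals."""

import numpy as np
import pytest

from mobiloscope._seq import random_seq, revcomp
from mobiloscope.io_align import AlignmentRecord, naive_align
from mobiloscope.mobilome_junctions import (
    build_junction_library,
    family_signal,
    genomic_control,
    junction_signal,
    junction_spanning_reads,
    normalize_signal,
    scan_junctions,
)
from mobiloscope.synthetic_data import (
    CircleKind,
    FullLengthCopy,
    build_genome,
    make_family_panel,
    rca_reads,
    simulate_eccdna_pool,
    wgs_reads,
)
from mobiloscope.mobilome_junctions import MobilitySignal


class TestJunctionLibrary:
    def test_flank_capped_record(self):
        fams = make_family_panel(1, ltr_len=300, internal_len=1000, seed=31)
        g = build_genome(fams, {fams[0].name: 1}, 30_000, seed=32)
        (rec,) = build_junction_library(g.copies, g.chromosomes, flank=300)
        assert len(rec.sequence) == 600 and rec.junction_pos == 300

    def test_short_ltr_min_rule(self):
        fams = make_family_panel(1, ltr_len=120, internal_len=1000, seed=33)
        g = build_genome(fams, {fams[0].name: 1}, 30_000, seed=34)
        (rec,) = build_junction_library(g.copies, g.chromosomes, flank=300)
        assert len(rec.sequence) == 240 and rec.junction_pos == 120

    def test_record_equals_element_tail_plus_head(self, small_genome):
        lib = build_junction_library(small_genome.copies, small_genome.chromosomes)
        for rec, copy in zip(lib, small_genome.copies):
            elem = copy.element_seq(small_genome.chromosomes)
            assert rec.sequence == elem[-rec.tail_len:] + elem[: rec.head_len]

    def test_strand_invariance(self, small_families, rng):
        # a record depends only on the element sequence, not the genomic strand
        elem = small_families[0].consensus
        L, ell = len(elem), small_families[0].ltr_len
        bg = random_seq(rng, 3000)
        chrom = bg + elem + bg + revcomp(elem) + bg
        plus = FullLengthCopy("plus", "fam", "c", 3000, 3000 + L, "+",
                              ltr5=(3000, 3000 + ell), ltr3=(3000 + L - ell, 3000 + L))
        start2 = 6000 + L
        minus = FullLengthCopy("minus", "fam", "c", start2, start2 + L, "-",
                               ltr5=(start2 + L - ell, start2 + L),
                               ltr3=(start2, start2 + ell))
        rec_p, rec_m = build_junction_library([plus, minus], {"c": chrom})
        assert rec_p.sequence == rec_m.sequence
        assert rec_p.junction_pos == rec_m.junction_pos

    def test_copy_without_ltr_annotation_skipped(self, small_genome, caplog):
        import dataclasses

        broken = [dataclasses.replace(small_genome.copies[0], ltr5=None)]
        with caplog.at_level("WARNING"):
            lib = build_junction_library(broken, small_genome.chromosomes)
        assert lib == []
        assert "lacks LTR annotations" in caplog.text

    def test_two_ltr_circle_contains_record_once_per_wrap(self, small_genome):
        lib = build_junction_library(small_genome.copies, small_genome.chromosomes)
        copy = small_genome.copies[0]
        rec = next(r for r in lib if r.copy_id == copy.copy_id)
        (circle,) = simulate_eccdna_pool(
            small_genome, {CircleKind.TWO_LTR: 1}, copies=[copy], seed=1
        )
        assert circle.doubled.count(rec.sequence) == 1


class TestSpanningFilter:
    def _rec(self, start, end, ref="copy1"):
        return AlignmentRecord("r", ref, start, end, "+", [(start, end)])

    def test_five_bp_rule_boundaries(self):
        jp = {"copy1": 300}
        assert junction_spanning_reads([self._rec(295, 310)], jp)  # 5 and 10
        assert not junction_spanning_reads([self._rec(296, 310)], jp)  # 4 < 5
        assert not junction_spanning_reads([self._rec(290, 304)], jp)  # right 4
        assert junction_spanning_reads([self._rec(295, 305)], jp)  # exactly 5/5

    def test_split_blocks_abutting_junction_do_not_count(self):
        rec = AlignmentRecord("r", "copy1", 200, 400, "+", [(200, 300), (300, 400)])
        assert junction_spanning_reads([rec], {"copy1": 300}) == []

    def test_tiling_kept_count_matches_brute_force(self, small_genome):
        lib = build_junction_library(small_genome.copies, small_genome.chromosomes,
                                     flank=120)
        rec = lib[0]
        L, rl = len(rec.sequence), 60
        reads = [(f"t{s}", rec.sequence[s: s + rl]) for s in range(L - rl + 1)]
        hits = naive_align(reads, {rec.copy_id: rec.sequence}, all_hits=True)
        kept = {r.read_id for r in junction_spanning_reads(hits, {rec.copy_id: 120})}
        brute = {
            f"t{s}" for s in range(L - rl + 1)
            if 120 - s >= 5 and s + rl - 120 >= 5
        }
        assert kept == brute


class TestSignals:
    def test_single_read_coverage(self):
        rec = AlignmentRecord("r", "c", 250, 350, "+", [(250, 350)])
        assert junction_signal([rec]) == {"c": 100.0}

    def test_duplicates_collapse(self):
        recs = [
            AlignmentRecord("a", "c", 250, 350, "+", [(250, 350)]),
            AlignmentRecord("b", "c", 250, 350, "+", [(250, 350)]),
        ]
        assert junction_signal(recs, dedup=True) == {"c": 100.0}
        assert junction_signal(recs, dedup=False) == {"c": 200.0}

    def test_matches_independent_pileup(self, rng):
        recs = []
        cover = np.zeros(600, dtype=int)
        starts = rng.choice(500, size=50, replace=False)
        for i, s in enumerate(starts):
            s = int(s)
            recs.append(AlignmentRecord(f"r{i}", "c", s, s + 100, "+", [(s, s + 100)]))
            cover[s: s + 100] += 1
        assert junction_signal(recs)["c"] == pytest.approx(cover.sum())

    def test_normalize_arithmetic(self):
        (sig,) = normalize_signal({"c": 600.0}, 6e6, "s1", {"c": "fam"})
        assert sig.normalized == pytest.approx(100.0)
        with pytest.raises(ValueError):
            normalize_signal({"c": 1.0}, 0.0, "s1", {})

    def test_family_signal_additivity(self):
        sigs = [
            MobilitySignal("s1", "c1", "fam", 200.0, 2.0),
            MobilitySignal("s1", "c2", "fam", 300.0, 3.0),
            MobilitySignal("s1", "c3", "other", 100.0, 1.0),
        ]
        out = {s.family: s.normalized for s in family_signal(sigs)}
        assert out == {"fam": pytest.approx(5.0), "other": pytest.approx(1.0)}


class TestSpecificityAndControl:
    def test_one_ltr_and_fragment_circles_give_no_signal(self, small_genome):
        lib = build_junction_library(small_genome.copies, small_genome.chromosomes)
        circles = simulate_eccdna_pool(
            small_genome, {CircleKind.ONE_LTR: 1, CircleKind.FRAGMENT: 1}, seed=41
        )
        reads, _ = rca_reads(circles, depth=10, seed=42)
        sigs = scan_junctions(reads, lib, small_genome.chromosomes, "s")
        assert all(s.normalized == 0 for s in sigs)

    def test_plain_genome_wgs_gives_zero_control(self, small_genome):
        lib = build_junction_library(small_genome.copies, small_genome.chromosomes)
        reads, _ = wgs_reads(small_genome, depth=3, seed=43)
        sigs = genomic_control(reads, lib, small_genome.chromosomes, "ctl")
        assert all(s.normalized == 0 for s in sigs)
        assert all(s.is_genomic_control for s in sigs)

    def test_engineered_tandem_pair_triggers_control_signal(self):
        # two elements head-to-tail create a genomic tail-to-head-like junction
        fams = make_family_panel(1, ltr_len=120, internal_len=800, seed=44)
        elem = fams[0].consensus
        rng = np.random.default_rng(45)
        bg1, bg2 = random_seq(rng, 20_000), random_seq(rng, 20_000)
        chrom = bg1 + elem + elem + bg2
        s1 = len(bg1)
        copies = []
        for i, start in enumerate((s1, s1 + len(elem))):
            end = start + len(elem)
            copies.append(FullLengthCopy(
                copy_id=f"tandem{i}", family=fams[0].name, chrom="chr1",
                start=start, end=end, strand="+",
                ltr5=(start, start + 120), ltr3=(end - 120, end),
            ))
        from mobiloscope.synthetic_data import SyntheticGenome

        genome = SyntheticGenome({"chr1": chrom}, copies, tsd_len=0)
        lib = build_junction_library(copies, genome.chromosomes)
        reads, _ = wgs_reads(genome, depth=20, seed=46)
        sigs = genomic_control(reads, lib, genome.chromosomes, "ctl")
        assert sum(s.normalized for s in sigs) > 0
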