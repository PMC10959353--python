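"""Generator invariants: constructions, determinism, truth-record consistency."""

import numpy as np
import pytest

from mobiloscope._seq import revcomp
from mobiloscope.io_align import write_fasta
from mobiloscope.synthetic_data import (
    CircleKind,
    EccCircle,
    PanelSpec,
    build_genome,
    make_family_panel,
    panel_spec_for_marginal_r2,
    rca_reads,
    simulate_accession_panel,
    simulate_eccdna_pool,
    wgs_reads,
)


def occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


class TestFamilyPanel:
    def test_consensus_is_ltr_internal_ltr(self):
        fams = make_family_panel(1, ltr_len=10, internal_len=5, seed=0)
        c = fams[0].consensus
        assert len(c) == 25
        assert c[:10] == c[15:25]

    def test_deterministic_fasta_output(self, tmp_path):
        a = make_family_panel(3, ltr_len=50, internal_len=100, seed=5)
        b = make_family_panel(3, ltr_len=50, internal_len=100, seed=5)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta({f.name: f.consensus for f in a}, pa)
        write_fasta({f.name: f.consensus for f in b}, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_families_start_and_end_with_own_ltr_and_are_dissimilar(self):
        fams = make_family_panel(5, ltr_len=300, internal_len=500, seed=1)
        for f in fams:
            assert f.consensus.startswith(f.ltr_seq)
            assert f.consensus.endswith(f.ltr_seq)
        for i, a in enumerate(fams):
            for b in fams[i + 1:]:
                ident = np.mean([x == y for x, y in zip(a.ltr_seq, b.ltr_seq)])
                assert ident < 0.8

    @pytest.mark.parametrize("kwargs", [
        {"n_families": 0},
        {"n_families": 1, "ltr_len": 5},
        {"n_families": 1, "internal_len": -1},
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            make_family_panel(**{"ltr_len": 20, "internal_len": 10, **kwargs})


class TestBuildGenome:
    def test_zero_copies_absent_from_genome(self, small_families):
        fams = small_families
        g = build_genome(fams, {fams[0].name: 0}, 20_000, seed=3)
        assert g.copies == []
        assert fams[0].consensus not in g.chromosomes["chr1"]

    def test_tsd_flanks_match(self, small_genome):
        g = small_genome
        for c in g.copies:
            s = g.chromosomes[c.chrom]
            assert s[c.start - g.tsd_len: c.start] == s[c.end: c.end + g.tsd_len]

    def test_exact_copy_count_by_substring_scan(self, small_families):
        fams = small_families
        g = build_genome(fams, {fams[0].name: 8}, 80_000, divergence=0.0, seed=4)
        chrom = g.chromosomes["chr1"]
        total = occurrences(chrom, fams[0].consensus) + occurrences(
            revcomp(chrom), fams[0].consensus
        )
        assert total == 8

    def test_copy_sequence_matches_consensus_at_zero_divergence(self, small_genome,
                                                                small_families):
        by_name = {f.name: f for f in small_families}
        for c in small_genome.copies:
            assert c.element_seq(small_genome.chromosomes) == by_name[c.family].consensus

    def test_overfull_genome_rejected(self, small_families):
        fams = small_families
        with pytest.raises(ValueError):
            build_genome(fams, {fams[0].name: 10}, 5_000, seed=0)

    def test_divergence_bounds(self, small_families):
        with pytest.raises(ValueError):
            build_genome(small_families, {}, 10_000, divergence=0.5)


class TestEccdnaPool:
    def test_two_ltr_circle_is_full_element_with_junction(self, small_genome,
                                                          small_families):
        fam = small_families[0]
        copy = next(c for c in small_genome.copies if c.family == fam.name)
        (circle,) = simulate_eccdna_pool(
            small_genome, {CircleKind.TWO_LTR: 1}, copies=[copy], seed=1
        )
        elem = copy.element_seq(small_genome.chromosomes)
        assert len(circle.sequence) == copy.end - copy.start
        junction = elem[-120:] + elem[:120]  # 3'LTR tail + 5'LTR head
        assert junction in circle.doubled

    def test_one_ltr_circle_contains_exactly_one_ltr(self, small_genome, small_families):
        fam = small_families[0]
        copy = next(c for c in small_genome.copies if c.family == fam.name)
        (circle,) = simulate_eccdna_pool(
            small_genome, {CircleKind.ONE_LTR: 1}, copies=[copy], seed=1
        )
        assert len(circle.sequence) == (copy.end - copy.start) - fam.ltr_len
        assert occurrences(circle.sequence, fam.ltr_seq) == 1

    def test_fragment_never_contains_a_full_ltr(self, small_genome, small_families):
        circles = simulate_eccdna_pool(
            small_genome, {CircleKind.FRAGMENT: 3}, seed=2, min_fragment=200
        )
        by_name = {f.name: f for f in small_families}
        for circle in circles:
            fam = by_name[circle.source_copy.split("_chr")[0]]
            assert fam.ltr_seq not in circle.doubled


class TestRcaReads:
    def test_closure_crossing_fraction_matches_binomial(self, rng):
        L, read_len = 1000, 100
        circle = EccCircle("c0", CircleKind.FRAGMENT,
                           "".join(rng.choice(list("ACGT"), L)), "src")
        reads, truth = rca_reads([circle], depth=100, read_len=read_len,
                                 frag_len=read_len, seed=9)
        n = len(reads)
        p = (read_len - 1) / L  # offsets L-99..L-1 wrap the closure
        crossing = (truth["offset"] > L - read_len).mean()
        assert abs(crossing - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_error_free_reads_are_substrings_of_doubled_circle(self, small_genome):
        circles = simulate_eccdna_pool(small_genome, {CircleKind.TWO_LTR: 1}, seed=3)
        reads, truth = rca_reads(circles, depth=2, error_rate=0.0, seed=4)
        doubled = {c.circle_id: c.doubled for c in circles}
        strands = dict(zip(truth["read_id"], truth["strand"]))
        sources = dict(zip(truth["read_id"], truth["circle_id"]))
        for name, seq in reads:
            oriented = seq if strands[name] == "+" else revcomp(seq)
            assert oriented in doubled[sources[name]]

    def test_zero_circles_yield_empty_fastq(self):
        reads, truth = rca_reads([], depth=10, seed=0)
        assert reads == [] and truth.empty

    def test_read_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            rca_reads([], depth=1, read_len=200, frag_len=100)


class TestWgsReads:
    def test_read_count_arithmetic(self, small_families):
        g = build_genome(small_families, {}, 100_000, seed=5)
        reads, _ = wgs_reads(g, depth=10, read_len=100, seed=6)
        assert len(reads) == 10_000

    def test_error_free_reads_are_genomic_substrings(self, small_genome):
        reads, truth = wgs_reads(small_genome, depth=0.5, seed=7)
        chrom = small_genome.chromosomes["chr1"]
        strands = dict(zip(truth["read_id"], truth["strand"]))
        positions = dict(zip(truth["read_id"], truth["pos"]))
        for name, seq in reads:
            oriented = seq if strands[name] == "+" else revcomp(seq)
            assert chrom[positions[name]: positions[name] + 100] == oriented

    def test_fixed_seed_reproducible(self, small_genome):
        r1, _ = wgs_reads(small_genome, depth=0.2, seed=8)
        r2, _ = wgs_reads(small_genome, depth=0.2, seed=8)
        assert r1 == r2


class TestAccessionPanel:
    def test_zero_effects_give_zero_generating_r2(self):
        spec = PanelSpec(effect_sizes=(0.0,))
        assert spec.generating_marginal_r2 == 0.0

    def test_generating_r2_formula(self):
        # fixed-part variance 1, clade 0, resid 1 -> R2m = 0.5
        spec = PanelSpec(effect_sizes=(1.0,), clade_var=0.0, resid_var=1.0)
        assert spec.generating_marginal_r2 == pytest.approx(0.5)

    def test_spec_for_target_r2_roundtrips(self):
        for r2 in (0.0, 0.1, 0.4):
            spec = panel_spec_for_marginal_r2(r2)
            assert spec.generating_marginal_r2 == pytest.approx(r2)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            PanelSpec(clade_var=-1.0)

    def test_panel_table_shape_and_labels(self):
        spec = PanelSpec(n_accessions=40, n_clades=4, effect_sizes=(0.5, 0.2))
        df, truth = simulate_accession_panel(spec, seed=11)
        assert len(df) == 40
        assert set(df["clade"]) == {f"clade_{i}" for i in range(4)}
        assert {"bio_1", "bio_2", "pcn"} <= set(df.columns)
        assert (df["pcn"] >= 0).all()
        assert truth["generating_marginal_r2"] == pytest.approx(
            spec.generating_marginal_r2
        )

    def test_variance_decomposition_converges(self):
        # empirical variance components over replicates approach the generating values
        spec = PanelSpec(n_accessions=400, n_clades=8, effect_sizes=(0.0,),
                         clade_var=2.0, resid_var=1.0)
        within, between = [], []
        for rep in range(40):
            df, truth = simulate_accession_panel(spec, seed=200 + rep)
            grouped = df.groupby("clade")["pcn"]
            within.append(grouped.var().mean())
            between.append(np.var(truth["clade_intercepts"], ddof=1))
        assert np.mean(within) == pytest.approx(1.0, rel=0.1)
        assert np.mean(between) == pytest.approx(2.0, rel=0.35)
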