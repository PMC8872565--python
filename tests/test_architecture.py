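"""Dot-plot self-alignment, cassette decomposition, regulatory elements."""

import re

import numpy as np
import pytest

from trgkit.architecture import (
    StructureError,
    block_strings,
    build_cassettes,
    detect_duplication_units,
    homology_block_painting,
    locate_regulatory_elements,
    name_cassettes,
    scan_stat_motifs,
    self_dotplot,
)
from trgkit.model import GeneAnnotation, GenomicInterval, SequenceRecord, reverse_complement
from trgkit.simulate import LocusSpec, generate_locus

from conftest import random_dna


def _gene(name, gtype, start, end, seq_id="seq"):
    label = {"V": "V-EXON", "J": "J-REGION", "C": "EX1"}[gtype]
    return GeneAnnotation(name, gtype, [(label, GenomicInterval(seq_id, start, end))])


class TestDotplot:
    def test_random_sequence_only_main_diagonal(self):
        rng = np.random.default_rng(0)
        runs = self_dotplot(SequenceRecord("r", random_dna(rng, 10_000)))
        assert len(runs) == 1
        assert runs[0].off_diagonal_offset == 0 and runs[0].length == 10_000

    def test_tandem_duplication_detected(self):
        rng = np.random.default_rng(1)
        block = random_dna(rng, 5000)
        runs = self_dotplot(SequenceRecord("t", block + block))
        off = [r for r in runs if r.off_diagonal_offset > 0]
        assert {(r.start1, r.start2) for r in off} == {(1, 5001), (5001, 1)}
        assert all(r.length >= 4900 for r in off)

    def test_four_cassettes_three_parallel_lines(self):
        spec = LocusSpec(n_cassettes=4, v_per_cassette=[1] * 4, j_per_cassette=[1] * 4,
                         ex2_copies_per_cassette=[1] * 4, divergence=0.0, seed=2)
        rec, _ = generate_locus(spec)
        runs = self_dotplot(rec)
        offsets = {r.off_diagonal_offset for r in runs if r.off_diagonal_offset > 0}
        assert len(offsets) >= 3

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        block = random_dna(rng, 3000)
        runs = self_dotplot(SequenceRecord("t", block + random_dna(rng, 500) + block))
        off = [r for r in runs if r.off_diagonal_offset > 0]
        pairs = {(r.start1, r.start2, r.length) for r in off}
        assert pairs == {(b, a, l) for a, b, l in pairs}

    def test_masked_positions_yield_no_seeds(self):
        rng = np.random.default_rng(4)
        block = random_dna(rng, 3000)
        masked = block.lower()
        runs = self_dotplot(SequenceRecord("m", block + masked))
        assert all(r.off_diagonal_offset == 0 for r in runs)

    def test_k_floor(self):
        with pytest.raises(ValueError):
            self_dotplot(SequenceRecord("s", "ACGT" * 100), k=4)


class TestDuplicationUnits:
    def test_planted_jc_duplication(self):
        rng = np.random.default_rng(5)
        jc = random_dna(rng, 1200)
        seq = random_dna(rng, 800) + jc + random_dna(rng, 400) + jc + random_dna(rng, 800)
        runs = self_dotplot(SequenceRecord("s", seq))
        genes = [_gene("J1", "J", 801, 860), _gene("C1", "C", 1100, 1900),
                 _gene("J2", "J", 2401, 2460), _gene("C2", "C", 2700, 3500)]
        units = detect_duplication_units(runs, genes)
        assert len(units) == 1
        assert units[0].genes_left == ["J1", "C1"]
        assert units[0].genes_right == ["J2", "C2"]

    def test_no_off_diagonal_no_units(self):
        rng = np.random.default_rng(6)
        runs = self_dotplot(SequenceRecord("s", random_dna(rng, 5000)))
        assert detect_duplication_units(runs, []) == []


class TestBuildCassettes:
    def test_pig_like_pattern(self):
        order = "VVVVVJJC" "VJJC" "VJC" "VJC"
        genes = [_gene(f"{t}{i}", t, 100 * i + 1, 100 * i + 60) for i, t in enumerate(order)]
        cassettes, anomalies = build_cassettes(genes)
        assert len(cassettes) == 4 and not anomalies
        assert [len(c.v_genes) for c in cassettes] == [5, 1, 1, 1]
        assert [len(c.j_genes) for c in cassettes] == [2, 2, 1, 1]

    def test_single_cassette(self):
        genes = [_gene("V1", "V", 1, 60), _gene("J1", "J", 100, 160), _gene("C1", "C", 200, 400)]
        cassettes, anomalies = build_cassettes(genes)
        assert len(cassettes) == 1 and not anomalies

    def test_trailing_orphan_reported(self):
        genes = [_gene("J1", "J", 100, 160), _gene("C1", "C", 200, 400), _gene("V9", "V", 500, 560)]
        cassettes, anomalies = build_cassettes(genes)
        assert len(cassettes) == 1
        assert len(anomalies) == 1 and anomalies[0]["genes"] == ["V9"]

    def test_bad_block_reported_not_dropped(self):
        genes = [_gene("C0", "C", 10, 50), _gene("V1", "V", 100, 160),
                 _gene("J1", "J", 200, 260), _gene("C1", "C", 300, 500)]
        cassettes, anomalies = build_cassettes(genes)
        assert len(cassettes) == 1
        assert anomalies and anomalies[0]["pattern"] == "C"

    def test_no_c_is_structural_error(self):
        with pytest.raises(StructureError):
            build_cassettes([_gene("V1", "V", 1, 60), _gene("J1", "J", 100, 160)])

    def test_count_equals_c_genes(self, pig_like):
        from trgkit.annotate import annotate_locus

        rec, truth = pig_like
        genes = annotate_locus(rec, truth.c_exon_reference)
        cassettes, _ = build_cassettes(genes)
        assert len(cassettes) == sum(1 for g in genes if g.gene_type == "C")


class TestNameCassettes:
    def _refs(self, rec, truth, labels):
        refs = []
        for cas, label in zip(truth.cassettes, labels):
            refs.append(SequenceRecord(
                f"{label}_C", cas.c_gene.coding_sequence(rec.residues),
                f"cassette={label} gene_type=C",
            ))
            if cas.v_genes:
                refs.append(SequenceRecord(
                    f"{label}_V", cas.v_genes[0].coding_sequence(rec.residues),
                    f"cassette={label} gene_type=V",
                ))
        return refs

    def test_named_by_nearest_reference(self, pig_like):
        from trgkit.annotate import annotate_locus

        rec, truth = pig_like
        genes = annotate_locus(rec, truth.c_exon_reference)
        cassettes, _ = build_cassettes(genes)
        labels = ["TRGC5", "TRGC6", "TRGC3", "TRGC4"]  # 5'->3' ruminant naming
        named = name_cassettes(cassettes, rec, self._refs(rec, truth, labels))
        assert [c.name for c in named] == labels

    def test_tie_broken_by_v_gene(self, pig_like):
        rec, truth = pig_like
        cas1 = truth.cassettes[0]
        c_seq = cas1.c_gene.coding_sequence(rec.residues)
        v_seq = cas1.v_genes[0].coding_sequence(rec.residues)
        refs = [
            SequenceRecord("X_C", c_seq, "cassette=X gene_type=C"),
            SequenceRecord("Y_C", c_seq, "cassette=Y gene_type=C"),  # identical C: tie
            SequenceRecord("Y_V", v_seq, "cassette=Y gene_type=V"),
        ]
        named = name_cassettes([truth.cassettes[0]], rec, refs)
        assert named[0].name == "Y"

    def test_novel_below_identity_floor(self, pig_like):
        rec, truth = pig_like
        rng = np.random.default_rng(7)
        refs = [SequenceRecord("far", random_dna(rng, 900), "cassette=FAR gene_type=C")]
        named = name_cassettes(list(truth.cassettes), rec, refs)
        assert [c.name for c in named] == [f"novel-{i}" for i in range(1, 5)]

    def test_empty_reference_rejected(self, pig_like):
        _, truth = pig_like
        with pytest.raises(ValueError):
            name_cassettes(list(truth.cassettes), "ACGT", [])


class TestStatMotifs:
    def test_forward_hit(self):
        hits = scan_stat_motifs(SequenceRecord("m", "GGTTCAAAGAAGG"))
        fwd = [h for h in hits if h.interval.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].interval.start == 3 and fwd[0].matched_text == "TTCAAAGAA"

    def test_palindromic_hit_on_both_strands(self):
        hits = scan_stat_motifs(SequenceRecord("m", "TTCTTTGAA"))
        assert {(h.interval.start, h.interval.strand) for h in hits} == {(1, "+"), (1, "-")}

    def test_near_miss_rejected(self):
        assert scan_stat_motifs(SequenceRecord("m", "TTCAAAGAG")) == []

    def test_region_bounds_checked(self):
        with pytest.raises(ValueError):
            scan_stat_motifs(SequenceRecord("m", "ACGT"), GenomicInterval("m", 1, 10))

    def test_matches_independent_scan_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            text = random_dna(rng, 1000)
            got = {(h.interval.start, h.interval.strand) for h in
                   scan_stat_motifs(SequenceRecord("s", text))}
            expect = set()
            for i in range(len(text) - 8):
                if text[i : i + 3] == "TTC" and text[i + 6 : i + 9] == "GAA":
                    expect.add((i + 1, "+"))
            rc = reverse_complement(text)
            for i in range(len(rc) - 8):
                if rc[i : i + 3] == "TTC" and rc[i + 6 : i + 9] == "GAA":
                    expect.add((len(text) - i - 8, "-"))
            assert got == expect


class TestRegulatoryElements:
    def test_planted_pj_and_en_found(self, pig_like):
        from trgkit.annotate import annotate_locus

        rec, truth = pig_like
        genes = annotate_locus(rec, truth.c_exon_reference)
        cassettes, _ = build_cassettes(genes)
        for cas, tcas in zip(cassettes, truth.cassettes):
            cas, cores = locate_regulatory_elements(cas, rec, truth.pj_reference, truth.en_reference)
            assert cas.pj is not None and cas.pj.overlaps(tcas.pj)
            assert cas.en is not None and cas.en.overlaps(tcas.en)
            assert cores["PJ"] > 0 and cores["En"] > 0

    def test_en_within_downstream_window(self, pig_like):
        rec, truth = pig_like
        cas = truth.cassettes[0]
        c_end = cas.c_gene.span.end
        assert 0 < cas.en.start - c_end <= 4000  # ~2 kb downstream by design

    def test_absent_element_stays_none(self, pig_like):
        rec, truth = pig_like
        rng = np.random.default_rng(9)
        decoy_pj = SequenceRecord("pj", random_dna(rng, 600))
        decoy_en = SequenceRecord("en", random_dna(rng, 770))
        cas = truth.cassettes[1]
        cas.pj = cas.en = None
        cas, cores = locate_regulatory_elements(cas, rec, decoy_pj, decoy_en)
        assert cas.pj is None and cas.en is None and cores == {}


class TestBlockPainting:
    def test_identical_sequences_one_block(self):
        rng = np.random.default_rng(10)
        s = random_dna(rng, 4000)
        blocks = homology_block_painting([SequenceRecord("a", s), SequenceRecord("b", s)])
        assert len(blocks) == 1
        assert blocks[0].present_in == frozenset({"a", "b"})

    def test_insertion_private_block(self):
        rng = np.random.default_rng(11)
        p, q, r = random_dna(rng, 2000), random_dna(rng, 2000), random_dna(rng, 900)
        a = SequenceRecord("A", p + q)
        b = SequenceRecord("B", p + r + q)
        blocks = homology_block_painting([a, b])
        shared = [blk for blk in blocks if len(blk.present_in) == 2]
        private = [blk for blk in blocks if blk.present_in == frozenset({"B"})]
        assert len(shared) == 2 and len(private) == 1
        strings = block_strings(blocks, ["A", "B"])
        assert len(strings["A"]) == 2 and len(strings["B"]) == 3

    def test_diverged_cassette_copies_share_c_block(self):
        spec = LocusSpec(n_cassettes=3, v_per_cassette=[1] * 3, j_per_cassette=[1] * 3,
                         ex2_copies_per_cassette=[1] * 3, divergence=0.05, seed=12)
        rec, truth = generate_locus(spec)
        seqs = [SequenceRecord(c.name, c.span.slice(rec.residues)) for c in truth.cassettes]
        blocks = homology_block_painting(seqs)
        shared_all = [b for b in blocks if len(b.present_in) == 3]
        assert shared_all
        # at least one all-shared block covers (part of) the C gene region
        c0 = truth.cassettes[0]
        c_rel = GenomicInterval("cas1", c0.c_gene.span.start - c0.span.start + 1,
                                c0.c_gene.span.end - c0.span.start + 1)
        assert any(b.intervals["cas1"].overlaps(c_rel) for b in shared_all)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            homology_block_painting([SequenceRecord("a", "ACGT" * 100)])
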