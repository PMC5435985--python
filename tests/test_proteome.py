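import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtdkit.proteome import (
    GeneAnchor,
    build_peptide_index,
    digest_trypsin,
    genomic_to_mrna,
    longest_orf,
    mrna_to_genomic,
    select_anchor,
    translate_anchored,
    translate_fallback,
    ProteinRecord,
)

from .helpers import brute_force_orf_scan, make_tx


class TestCoordinateMaps:
    def test_round_trip_plus_and_minus(self):
        for strand in "+-":
            t = make_tx([(10, 15), (20, 30)], strand=strand)
            for off in range(t.exonic_length):
                pos = mrna_to_genomic(t, off)
                assert genomic_to_mrna(t, pos) == off

    def test_intronic_position_maps_to_none(self):
        t = make_tx([(10, 15), (20, 30)])
        assert genomic_to_mrna(t, 17) is None

    def test_minus_strand_offset_zero_is_highest_coordinate(self):
        t = make_tx([(10, 15), (20, 30)], strand="-")
        assert mrna_to_genomic(t, 0) == 29


class TestOrfScan:
    @settings(max_examples=100, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_matches_exhaustive_all_atg_oracle(self, seq):
        assert longest_orf(seq) == brute_force_orf_scan(seq)

    def test_two_equal_orfs_take_five_prime_most(self):
        # ATG AAA TAG ... ATG CCC TAG: both 9 nt
        seq = "ATGAAATAGTTATGCCCTAG"
        assert longest_orf(seq) == (0, 9)


class TestSelectAnchor:
    def test_longest_orf_transcript_wins(self, fixture_assembly, fixture_genome):
        from rtdkit.quasi import extract_sequences

        seqs = extract_sequences(fixture_assembly, fixture_genome)
        for gene_id, models in list(fixture_assembly.genes())[:10]:
            anchor = select_anchor(models, seqs)
            # exhaustive oracle over every ATG of every transcript
            best = None
            for t in sorted(models, key=lambda m: m.transcript_id):
                hit = brute_force_orf_scan(seqs[t.transcript_id])
                if hit and (best is None or hit[1] > best[2]):
                    best = (t.transcript_id, hit[0], hit[1])
            if best is None:
                assert anchor is None
            else:
                assert anchor.transcript_id == best[0]
                assert anchor.orf_length == best[2]
                winner = next(t for t in models if t.transcript_id == best[0])
                assert anchor.genomic_position == mrna_to_genomic(winner, best[1])

    def test_no_atg_gives_untranslatable_gene(self):
        t = make_tx([(0, 12)], tid="t1")
        assert select_anchor([t], {"t1": "CCCCCCCCCCCC"}) is None


class TestTranslateAnchored:
    def test_hand_translation_from_anchor_offset(self):
        # mRNA AAATGGCTTAAGG, ATG at offset 2 -> protein "MA"
        t = make_tx([(0, 13)], tid="t1")
        anchor = GeneAnchor("g1", "t1", 2, 9, (2, 3, 4))
        rec = translate_anchored(t, anchor, {"t1": "AAATGGCTTAAGG"})
        assert rec.sequence == "MA" and rec.mode == "anchored"
        assert rec.stop_status == "stop_found"

    def test_missing_anchor_exon_requires_fallback(self):
        # anchor bases live in [20,23) which this isoform splices out
        t = make_tx([(0, 10), (30, 40)], tid="t1")
        anchor = GeneAnchor("g1", "t0", 20, 30, (20, 21, 22))
        rec = translate_anchored(t, anchor, {"t1": "A" * 20})
        assert rec.mode == "requires_fallback"

    def test_anchor_bases_must_be_contiguous_in_mrna(self):
        # anchor codon spans the first junction: splicing isoforms translate,
        # an intron-retaining isoform sees non-contiguous bases and falls back
        donor = make_tx([(0, 2), (10, 22)], tid="d")
        retained = make_tx([(0, 22)], tid="r")
        seqs = {"d": "CA" + "TGAAATAGGGGG", "r": "CA" + "T" * 8 + "TGAAATAGGGGG"}
        anchor = GeneAnchor("g1", "d", 1, 9, (1, 10, 11))
        assert translate_anchored(donor, anchor, seqs).mode == "anchored"
        assert translate_anchored(retained, anchor, seqs).mode == "requires_fallback"

    def test_anchor_transcript_self_translation_equals_longest_orf(
        self, fixture_assembly, fixture_genome
    ):
        from rtdkit.quasi import extract_sequences

        seqs = extract_sequences(fixture_assembly, fixture_genome)
        for gene_id, models in list(fixture_assembly.genes())[:8]:
            anchor = select_anchor(models, seqs)
            if anchor is None:
                continue
            t = next(m for m in models if m.transcript_id == anchor.transcript_id)
            rec = translate_anchored(t, anchor, seqs)
            start, length = brute_force_orf_scan(seqs[t.transcript_id])
            expected_aa = anchor.orf_length // 3 - (
                1 if rec.stop_status == "stop_found" else 0
            )
            assert rec.mode == "anchored" and len(rec.sequence) == expected_aa


class TestTranslateFallback:
    def test_hand_translation(self):
        t = make_tx([(0, 11)], tid="t1")
        rec = translate_fallback(t, {"t1": "GGATGAAATAG"})
        assert rec.sequence == "MK" and rec.mode == "fallback_longest_orf"

    def test_no_atg_is_untranslated(self):
        t = make_tx([(0, 8)], tid="t1")
        rec = translate_fallback(t, {"t1": "CCCCCCCC"})
        assert rec.mode == "untranslated" and rec.sequence == ""

    def test_run_off_end_flagged(self):
        t = make_tx([(0, 8)], tid="t1")
        rec = translate_fallback(t, {"t1": "ATGAAAAA"})
        assert rec.sequence == "MK" and rec.stop_status == "ran_off_end"


class TestDigest:
    def test_cleavage_rules_hand_example(self):
        assert digest_trypsin("MKAYLDRPQSTVKLMNPR") == ["AYLDRPQSTVK"]

    def test_no_cleavage_sites_keeps_whole_protein(self):
        assert digest_trypsin("MAYLDQSTV") == ["MAYLDQSTV"]

    def test_proline_blocks_every_cut(self):
        assert digest_trypsin("KPKPKPKPKP") == ["KPKPKPKPKP"]

    def test_min_length_filter(self):
        assert digest_trypsin("MKAYLDRPQSTVK", min_len=12) == []

    def test_nonstandard_residue_warns_and_is_retained(self):
        with pytest.warns(UserWarning, match="non-standard"):
            frags = digest_trypsin("MXAYLDKTTTTTTT", min_len=1)
        assert "".join(frags) == "MXAYLDKTTTTTTT"

    @settings(max_examples=100, derandomize=True)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_fragments_reconstruct_protein_and_respect_cleavage(self, seq):
        frags = digest_trypsin(seq, min_len=1)
        assert "".join(frags) == seq
        for frag in frags:
            for i, residue in enumerate(frag[:-1]):
                if residue in "KR":
                    assert frag[i + 1] == "P"


class TestPeptideIndex:
    def protein(self, tid, seq, gene="g1"):
        return ProteinRecord(tid, gene, seq, "anchored", "stop_found")

    def test_identical_proteins_have_zero_unique_peptides(self):
        p = "MKAYLDRPQSTVKLMNPRAAAA"
        idx = build_peptide_index([self.protein("t1", p), self.protein("t2", p)])
        assert idx.summary["unique_peptides"] == 0
        assert idx.summary["total_peptides"] > 0

    def test_differing_region_yields_unique_peptides(self):
        shared = "AYLDQSTVHHHH"
        idx = build_peptide_index(
            [
                self.protein("t1", "MK" + shared + "WWWWWWWW"),
                self.protein("t2", "MK" + shared + "YYYYYYYY"),
            ]
        )
        uniques = [p for p in idx.peptides if idx.is_unique(p)]
        assert len(uniques) == 2  # the two differing C-terminal fragments
        assert idx.summary["transcripts_with_unique_peptide"] == 2

    def test_unique_fraction_arithmetic(self):
        idx = build_peptide_index(
            [self.protein("t1", "MKAYLDRPQSTVK"), self.protein("t2", "MKAYLDRPQSTVK", gene="g2")]
        )
        s = idx.summary
        assert s["unique_fraction"] == s["unique_peptides"] / s["total_peptides"]
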