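import pytest

from rtdkit.core import Transcriptome, intron_chain_key, introns_of
from rtdkit.io import read_genome, write_fasta
from rtdkit.quasi import (
    build_quasi,
    build_trimmed,
    extract_sequences,
    pad_gene,
    transcript_sequence,
    trim_gene,
)

from .helpers import make_tx


@pytest.fixture()
def genome(tmp_path):
    import numpy as np

    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    write_fasta({"chr1": seq}, tmp_path / "g.fa")
    return read_genome(tmp_path / "g.fa")


class TestPad:
    def test_spans_unified_to_widest(self, genome):
        a = make_tx([(100, 200), (300, 900)], tid="a")
        b = make_tx([(150, 200), (300, 850)], tid="b")
        out, log = pad_gene([a, b], genome)
        assert all((t.exons[0].start, t.exons[-1].end) == (100, 900) for t in out)
        assert {(x.transcript_id, x.delta_5p, x.delta_3p) for x in log} == {
            ("a", 0, 0), ("b", 50, 50),
        }

    def test_single_transcript_gene_unchanged(self, genome):
        a = make_tx([(100, 200), (300, 900)], tid="a")
        out, _ = pad_gene([a], genome)
        assert [(e.start, e.end) for e in out[0].exons] == [(100, 200), (300, 900)]

    def test_padding_through_terminal_intron_gives_retention_like_end(self, genome):
        # b ends inside a's 3'-UTR intron; padding extends b's last exon
        # straight through that intron without creating a junction
        a = make_tx([(100, 200), (300, 400), (500, 900)], tid="a")
        b = make_tx([(100, 200), (300, 420)], tid="b")
        out, _ = pad_gene([a, b], genome)
        padded_b = next(t for t in out if t.transcript_id == "b")
        assert (padded_b.exons[-1].start, padded_b.exons[-1].end) == (300, 900)
        assert intron_chain_key(padded_b) == intron_chain_key(b)

    def test_original_sequence_is_contiguous_substring(self, genome):
        a = make_tx([(100, 200), (300, 900)], tid="a")
        b = make_tx([(150, 200), (300, 850)], tid="b", strand="+")
        before = transcript_sequence(b, genome)
        out, _ = pad_gene([a, b], genome)
        after = transcript_sequence(next(t for t in out if t.transcript_id == "b"), genome)
        assert before in after and len(after) >= len(before)

    def test_minus_strand_deltas_are_strand_oriented(self, genome):
        a = make_tx([(100, 900)], strand="-", tid="a")
        b = make_tx([(150, 900)], strand="-", tid="b")
        _, log = pad_gene([a, b], genome)
        rec = next(x for x in log if x.transcript_id == "b")
        # the genomic-left extension is the 3' end on the minus strand
        assert (rec.delta_5p, rec.delta_3p) == (0, 50)

    def test_pad_beyond_chromosome_errors(self, genome):
        a = make_tx([(100, 5000)], tid="a")
        with pytest.raises(ValueError):
            pad_gene([a, make_tx([(100, 200)], tid="b")], genome)


class TestTrim:
    def test_spans_clipped_to_narrowest(self):
        a = make_tx([(100, 200), (300, 900)], tid="a")
        b = make_tx([(150, 200), (300, 850)], tid="b")
        out, _ = trim_gene([a, b])
        assert all((t.exons[0].start, t.exons[-1].end) == (150, 850) for t in out)

    def test_trim_point_inside_utr_intron_drops_outside_exons(self):
        # b starts inside a's first intron: a loses exon 1 and is truncated
        # at its next exon boundary
        a = make_tx([(100, 200), (300, 400), (500, 900)], tid="a")
        b = make_tx([(230, 400), (500, 880)], tid="b")
        out, _ = trim_gene([a, b])
        trimmed_a = next(t for t in out if t.transcript_id == "a")
        assert [(e.start, e.end) for e in trimmed_a.exons] == [(300, 400), (500, 880)]

    def test_empty_window_skips_gene_with_warning(self):
        a = make_tx([(100, 200)], tid="a")
        b = make_tx([(300, 400)], tid="b")
        with pytest.warns(UserWarning, match="empty trim window"):
            out, log = trim_gene([a, b])
        assert out == [] and log == []

    def test_trimmed_sequence_is_substring(self, genome):
        a = make_tx([(100, 200), (300, 900)], tid="a")
        b = make_tx([(150, 200), (300, 850)], tid="b")
        before = {t.transcript_id: transcript_sequence(t, genome) for t in (a, b)}
        out, _ = trim_gene([a, b])
        for t in out:
            assert transcript_sequence(t, genome) in before[t.transcript_id]


class TestBuildVariants:
    def tx(self):
        tx = Transcriptome("toy")
        tx.add(make_tx([(100, 200), (300, 900)], tid="a", gene="g1"))
        tx.add(make_tx([(150, 200), (300, 850)], tid="b", gene="g1"))
        tx.add(make_tx([(1200, 1300)], tid="c", gene="g2"))
        return tx

    def test_quasi_gives_per_gene_uniform_spans(self, genome):
        out, _ = build_quasi(self.tx(), genome)
        for _, models in out.genes():
            spans = {(t.exons[0].start, t.exons[-1].end) for t in models}
            assert len(spans) == 1

    def test_quasi_is_idempotent(self, genome):
        once, _ = build_quasi(self.tx(), genome)
        twice, log = build_quasi(once, genome)
        assert all(x.delta_5p == 0 and x.delta_3p == 0 for x in log)
        assert {
            t.transcript_id: [(e.start, e.end) for e in t.exons] for t in twice
        } == {t.transcript_id: [(e.start, e.end) for e in t.exons] for t in once}

    def test_pad_after_trim_is_identity_on_single_isoform_genes(self, genome):
        tx = Transcriptome("toy")
        tx.add(make_tx([(100, 200), (300, 900)], tid="a", gene="g1"))
        trimmed, _ = build_trimmed(tx)
        padded, _ = build_quasi(trimmed, genome)
        assert [(e.start, e.end) for e in padded.get("a").exons] == [
            (100, 200), (300, 900),
        ]

    def test_total_exonic_length_monotonicity(self, genome, fixture_assembly):
        padded, _ = build_quasi(fixture_assembly, genome=None)
        trimmed, _ = build_trimmed(fixture_assembly)
        for t in fixture_assembly:
            assert padded.get(t.transcript_id).exonic_length >= t.exonic_length
            if t.transcript_id in trimmed.transcripts:
                assert trimmed.get(t.transcript_id).exonic_length <= t.exonic_length

    def test_interior_intron_chains_preserved_by_trim(self):
        a = make_tx([(0, 50), (100, 150), (200, 250), (300, 350)], tid="a")
        b = make_tx([(60, 150), (200, 260)], tid="b")
        out, _ = trim_gene([a, b])
        trimmed_a = next(t for t in out if t.transcript_id == "a")
        inner = [(i.start, i.end) for i in introns_of(trimmed_a)]
        assert (150, 200) in inner


class TestExtractSequences:
    @pytest.fixture()
    def tiny_genome(self, tmp_path):
        write_fasta({"chr1": "ACGTTTGCA"}, tmp_path / "t.fa")
        return read_genome(tmp_path / "t.fa")

    def test_plus_strand_splice(self, tiny_genome):
        t = make_tx([(0, 3), (6, 9)], tid="t")
        assert transcript_sequence(t, tiny_genome) == "ACGGCA"

    def test_minus_strand_reverse_complement(self, tiny_genome):
        t = make_tx([(0, 3), (6, 9)], strand="-", tid="t")
        assert transcript_sequence(t, tiny_genome) == "TGCCGT"

    def test_mono_exonic_plain_substring(self, tiny_genome):
        t = make_tx([(2, 7)], tid="t")
        assert transcript_sequence(t, tiny_genome) == "GTTTG"

    def test_extract_all(self, tiny_genome):
        tx = Transcriptome("toy")
        tx.add(make_tx([(0, 3)], tid="x"))
        seqs = extract_sequences(tx, tiny_genome)
        assert seqs == {"x": "ACG"}
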