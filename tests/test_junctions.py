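import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtdkit.io import JunctionRecord, read_genome, write_fasta
from rtdkit.junctions import (
    ScoreThresholds,
    build_pwm,
    classify_intron_type,
    classify_motif,
    consensus_sequence,
    passing_junction_set,
    pool_junctions,
    score_splice_site,
    support_filter,
    JunctionSupport,
)

from .helpers import brute_force_score, brute_force_support


def rec(chrom, start, end, strand, unique, sample):
    from rtdkit.core import GenomicInterval

    interval = GenomicInterval(chrom, start, end, strand) if strand else None
    return JunctionRecord(interval, chrom, start, end, strand, unique, 0, sample)


class TestMotif:
    @pytest.mark.parametrize("donor,acceptor", [("GT", "AG"), ("GC", "AG"), ("AT", "AC")])
    def test_canonical_pairs(self, donor, acceptor):
        assert classify_motif(donor, acceptor) == "canonical"
        assert classify_motif(donor.lower(), acceptor.lower()) == "canonical"

    @pytest.mark.parametrize("donor,acceptor", [("CT", "AC"), ("GT", "AC"), ("NN", "AG")])
    def test_non_canonical_pairs(self, donor, acceptor):
        assert classify_motif(donor, acceptor) == "non_canonical"

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            classify_motif("GX", "AG")


class TestPooling:
    def test_same_junction_two_samples_collects_counts(self):
        pooled = pool_junctions(
            [[rec("chr1", 100, 200, "+", 12, "s1")], [rec("chr1", 100, 200, "+", 8, "s2")]]
        )
        assert len(pooled) == 1
        assert pooled[0].counts == {"s1": 12, "s2": 8}

    def test_duplicate_aligner_counts_take_maximum_not_sum(self):
        pooled = pool_junctions(
            [[rec("chr1", 100, 200, "+", 12, "s1")], [rec("chr1", 100, 200, "+", 9, "s1")]]
        )
        assert pooled[0].counts == {"s1": 12}

    def test_disjoint_junctions_concatenate(self):
        pooled = pool_junctions(
            [[rec("chr1", 100, 200, "+", 5, "s1")], [rec("chr2", 10, 90, "-", 7, "s1")]]
        )
        assert len(pooled) == 2


class TestSupportFilter:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"s1": 12, "s2": 11, "s3": 10, "s4": 0}, True),
            ({"s1": 12, "s2": 12, "s3": 9}, False),
            ({}, False),
        ],
    )
    def test_threshold_examples(self, counts, expected):
        j = JunctionSupport("chr1", 0, 50, "+", counts)
        assert support_filter(j, min_reads=10, min_samples=3) is expected

    @settings(max_examples=100, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.sampled_from([f"s{i}" for i in range(8)]), st.integers(0, 40)
        ),
        min_reads=st.integers(1, 20),
        min_samples=st.integers(1, 6),
    )
    def test_agrees_with_brute_force_count(self, counts, min_reads, min_samples):
        j = JunctionSupport("chr1", 0, 50, "+", counts)
        assert support_filter(j, min_reads, min_samples) == brute_force_support(
            counts, min_reads, min_samples
        )


class TestPassingSet:
    @pytest.fixture()
    def genome(self, tmp_path):
        # chr1: intron [10,30) with GT..AG; intron [40,60) with CT..AC
        seq = list("A" * 80)
        seq[10:12] = "GT"
        seq[28:30] = "AG"
        seq[40:42] = "CT"
        seq[58:60] = "AC"
        write_fasta({"chr1": "".join(seq)}, tmp_path / "g.fa")
        return read_genome(tmp_path / "g.fa")

    def good_counts(self):
        return {"s1": 15, "s2": 15, "s3": 15}

    def test_canonical_and_supported_passes(self, genome):
        j = JunctionSupport("chr1", 10, 30, "+", self.good_counts())
        assert j.key in passing_junction_set([j], genome)

    def test_canonical_but_unsupported_excluded(self, genome):
        j = JunctionSupport("chr1", 10, 30, "+", {"s1": 15, "s2": 15})
        assert passing_junction_set([j], genome) == set()

    def test_non_canonical_excluded_despite_heavy_support(self, genome):
        j = JunctionSupport("chr1", 40, 60, "+", {f"s{i}": 500 for i in range(6)})
        assert passing_junction_set([j], genome) == set()

    def test_undetermined_strand_never_passes(self, genome):
        j = JunctionSupport("chr1", 10, 30, None, self.good_counts())
        assert passing_junction_set([j], genome) == set()

    def test_monotone_in_thresholds(self, genome):
        js = [
            JunctionSupport("chr1", 10, 30, "+", {"s1": 15, "s2": 12, "s3": 10}),
            JunctionSupport("chr1", 40, 60, "+", self.good_counts()),
        ]
        loose = passing_junction_set(js, genome, min_reads=5, min_samples=1)
        tight = passing_junction_set(js, genome, min_reads=12, min_samples=3)
        assert tight <= loose

    def test_junction_beyond_chromosome_end_errors(self, genome):
        j = JunctionSupport("chr1", 10, 9999, "+", self.good_counts())
        with pytest.raises(ValueError):
            passing_junction_set([j], genome)


class TestPwm:
    def test_single_sequence_no_pseudocount_gives_indicators(self):
        m = build_pwm(["GTAAGTATCCTTT"], pseudocount=0.0)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert m[0, 2] == 1.0  # G at position 1

    def test_uniform_training_set_approaches_quarter(self):
        rng = np.random.default_rng(0)
        sites = ["".join(rng.choice(list("ACGT"), 13)) for _ in range(4000)]
        m = build_pwm(sites, pseudocount=0.5)
        assert np.allclose(m, 0.25, atol=0.03)

    def test_pseudocount_keeps_entries_positive(self):
        m = build_pwm(["A" * 13], pseudocount=0.5)
        assert (m > 0).all()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT"])

    @staticmethod
    def donor_matrix():
        sites = ["GTAAGTATCCTTT", "GTAAGAATCCTAT", "GTGAGTATACTTT", "GTAAGTTTCCTGT"]
        return build_pwm(sites, pseudocount=0.5)

    def test_consensus_scores_100_anticonsensus_0(self):
        matrix = self.donor_matrix()
        consensus = consensus_sequence(matrix)
        anti = "".join("ACGT"[i] for i in matrix.argmin(axis=1))
        assert score_splice_site(consensus, matrix) == pytest.approx(100.0)
        assert score_splice_site(anti, matrix) == pytest.approx(0.0)

    @settings(max_examples=60, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=13, max_size=13))
    def test_score_matches_brute_force_and_bounds(self, seq):
        matrix = self.donor_matrix()
        score = score_splice_site(seq, matrix)
        assert 0.0 <= score <= 100.0
        assert score == pytest.approx(brute_force_score(seq, matrix))

    def test_n_in_sequence_gives_undefined_sentinel(self):
        assert math.isnan(score_splice_site("GTAAGTATCCTNT", self.donor_matrix()))


class TestIntronTypeClassification:
    def test_u12_thresholds(self):
        assert classify_intron_type(80, 70, 50, 50) == "U12"

    def test_u2_thresholds_when_u12_below_cut(self):
        assert classify_intron_type(50, 50, 62, 61) == "U2"

    def test_unclassified_when_all_low(self):
        assert classify_intron_type(50, 50, 50, 50) == "unclassified"

    def test_u12_takes_precedence_over_u2(self):
        assert classify_intron_type(80, 70, 95, 95) == "U12"

    def test_thresholds_are_strict_inequalities(self):
        thr = ScoreThresholds()
        assert classify_intron_type(75, 70, 50, 50, thr) == "unclassified"
        assert classify_intron_type(50, 50, 60, 60, thr) == "unclassified"
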