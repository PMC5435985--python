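"""Splice-junction quality control and U2/U12 splice-site scoring.

Two concerns live here.  First, the junction filter used to clean assembled
transcriptomes: junctions must carry a canonical intron-terminal dinucleotide
pair (GT..AG, GC..AG or AT..AC, read in transcript orientation) and be
supported by sufficient unique reads in sufficiently many samples.  Second,
position-weight-matrix scoring of 13-nt splice-site windows against U2-type
(major spliceosome) and U12-type (minor spliceosome) signature models, on a
0-100 scale where 100 is the matrix consensus and 0 its anti-consensus.

Window layout, 5'->3' in transcript orientation:

* donor (5' splice site): 3 exonic + 10 intronic nucleotides;
* acceptor (3' splice site): 10 intronic + 3 exonic nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .io import GenomeAccessor, JunctionRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WINDOW_LENGTH = 13
DONOR_EXONIC = 3  # donor window: 3 exonic then 10 intronic nt
ACCEPTOR_EXONIC = 3  # acceptor window: 10 intronic then 3 exonic nt

CANONICAL_MOTIFS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}

#: Score that marks a window containing N (or otherwise unscorable).
UNDEFINED_SCORE = float("nan")

JunctionKey = Tuple[str, str, int, int]  # (chrom, strand, start, end)


@dataclass
class JunctionSupport:
    """A pooled junction with per-sample unique-read counts and its motif."""

    chrom: str
    start: int
    end: int
    strand: Optional[str]  # None = undetermined
    counts: Dict[str, int] = field(default_factory=dict)
    motif: Optional[Tuple[str, str]] = None

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.strand or ".", self.start, self.end)


def classify_motif(donor2: str, acceptor2: str) -> str:
    """Classify an intron-terminal dinucleotide pair.

    Returns ``"canonical"`` for GT..AG, GC..AG or AT..AC (case-insensitive),
    else ``"non_canonical"``.  An N anywhere makes the pair non-canonical;
    letters outside {A, C, G, T, N} are an error.
    """
    donor2, acceptor2 = donor2.upper(), acceptor2.upper()
    if len(donor2) != 2 or len(acceptor2) != 2:
        raise ValueError("motif dinucleotides must be 2 letters each")
    for base in donor2 + acceptor2:
        if base not in "ACGTN":
            raise ValueError(f"invalid base {base!r} in splice motif")
    if "N" in donor2 or "N" in acceptor2:
        return "non_canonical"
    return "canonical" if (donor2, acceptor2) in CANONICAL_MOTIFS else "non_canonical"


def intron_motif(genome: GenomeAccessor, chrom: str, start: int, end: int, strand: str) -> Tuple[str, str]:
    """First and last two intronic bases, in transcript orientation."""
    if strand == "+":
        return genome.fetch(chrom, start, start + 2, "+"), genome.fetch(chrom, end - 2, end, "+")
    return genome.fetch(chrom, end - 2, end, "-"), genome.fetch(chrom, start, start + 2, "-")


def pool_junctions(tables: Iterable[List[JunctionRecord]]) -> List[JunctionSupport]:
    """Pool junction records from several aligner tables.

    One JunctionSupport per distinct (chrom, strand, start, end).  When two
    tables report the same (junction, sample) — the typical case of two
    aligners mapping the same library — the per-sample count is the maximum,
    not the sum: the same reads seen twice are not independent evidence.
    """
    pooled: Dict[JunctionKey, JunctionSupport] = {}
    for table in tables:
        for rec in table:
            key = (rec.chrom, rec.strand or ".", rec.start, rec.end)
            entry = pooled.get(key)
            if entry is None:
                entry = JunctionSupport(rec.chrom, rec.start, rec.end, rec.strand)
                pooled[key] = entry
            previous = entry.counts.get(rec.sample_id, 0)
            entry.counts[rec.sample_id] = max(previous, rec.unique_reads)
    return [pooled[k] for k in sorted(pooled, key=lambda k: (k[0], k[2], k[3], k[1]))]


def support_filter(j: JunctionSupport, min_reads: int = 10, min_samples: int = 3) -> bool:
    """True iff >= ``min_samples`` samples each have >= ``min_reads`` unique reads."""
    if min_reads < 1 or min_samples < 1:
        raise ValueError("thresholds must be >= 1")
    qualifying = sum(1 for c in j.counts.values() if c >= min_reads)
    return qualifying >= min_samples


def passing_junction_set(
    junctions: Iterable[JunctionSupport],
    genome: GenomeAccessor,
    min_reads: int = 10,
    min_samples: int = 3,
) -> Set[JunctionKey]:
    """Junction keys passing BOTH the canonical-motif and read-support filters.

    Undetermined-strand junctions can never be canonical (the motif test
    requires an orientation) and are therefore always excluded.
    """
    passing: Set[JunctionKey] = set()
    for j in junctions:
        if not support_filter(j, min_reads, min_samples):
            continue
        if j.strand is None:
            continue
        if j.end > genome.chrom_length(j.chrom):
            raise ValueError(
                f"junction [{j.start},{j.end}) beyond end of {j.chrom}"
            )
        donor2, acceptor2 = intron_motif(genome, j.chrom, j.start, j.end, j.strand)
        if j.motif is None:
            j.motif = (donor2, acceptor2)
        if classify_motif(donor2, acceptor2) == "canonical":
            passing.add(j.key)
    return passing


# ---------------------------------------------------------------------------
# Position weight matrices


@dataclass
class SpliceSiteModel:
    """Positional probability matrices for one intron class.

    ``donor`` and ``acceptor`` are 13 x 4 matrices of per-position base
    probabilities (rows sum to 1), trained from aligned splice-site windows
    with a pseudocount so every entry is positive.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    intron_class: str  # "U2", "U12_GTAG" or "U12_ATAC"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        for name, m in (("donor", self.donor), ("acceptor", self.acceptor)):
            if m.shape != (WINDOW_LENGTH, 4):
                raise ValueError(f"{name} matrix must be {WINDOW_LENGTH} x 4")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"{name} matrix rows must sum to 1")


@dataclass(frozen=True)
class ScoreThresholds:
    """Classification cutoffs on the 0-100 score scale."""

    u12_donor_min: float = 75.0
    u12_acceptor_min: float = 65.0
    u2_min: float = 60.0


def build_pwm(training_sites: Sequence[str], pseudocount: float = 0.5) -> np.ndarray:
    """Position frequency matrix (13 x 4, rows normalised) from 13-mers."""
    if not training_sites:
        raise ValueError("need at least one training sequence")
    counts = np.zeros((WINDOW_LENGTH, 4), dtype=float)
    for seq in training_sites:
        seq = seq.upper()
        if len(seq) != WINDOW_LENGTH or any(b not in BASE_INDEX for b in seq):
            raise ValueError(f"training site must be a {WINDOW_LENGTH}-mer over ACGT: {seq!r}")
        for pos, base in enumerate(seq):
            counts[pos, BASE_INDEX[base]] += 1
    counts += pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def score_splice_site(seq: str, matrix: np.ndarray) -> float:
    """Score a 13-mer against a PWM on the 0-100 scale.

    The raw score is the log-odds sum ``sum_i log2(P[i, seq_i] / 0.25)``,
    min-max scaled so that the best attainable 13-mer (column-wise argmax)
    scores 100 and the worst scores 0.  Sequences containing N get NaN.
    """
    seq = seq.upper()
    if len(seq) != WINDOW_LENGTH:
        raise ValueError(f"splice-site window must be {WINDOW_LENGTH} nt, got {len(seq)}")
    if "N" in seq:
        return UNDEFINED_SCORE
    if any(b not in BASE_INDEX for b in seq):
        raise ValueError(f"invalid base in splice-site window {seq!r}")
    logodds = np.log2(matrix / 0.25)
    raw = sum(logodds[pos, BASE_INDEX[b]] for pos, b in enumerate(seq))
    raw_min = logodds.min(axis=1).sum()
    raw_max = logodds.max(axis=1).sum()
    if math.isclose(raw_max, raw_min):
        return 100.0  # degenerate uniform matrix: every sequence is consensus
    return 100.0 * (raw - raw_min) / (raw_max - raw_min)


def consensus_sequence(matrix: np.ndarray) -> str:
    """The column-argmax 13-mer (scores exactly 100)."""
    return "".join(BASES[i] for i in matrix.argmax(axis=1))


def classify_intron_type(
    u12_donor: float,
    u12_acceptor: float,
    u2_donor: float,
    u2_acceptor: float,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> str:
    """Assign an intron to U12, U2 or unclassified.

    U12 takes precedence: an intron is U12 only if its 5' site scores above
    the U12 donor cutoff AND its 3' site above the U12 acceptor cutoff.
    Otherwise it is U2 if both sites score above the U2 cutoff.  NaN scores
    never satisfy a cutoff.
    """
    if u12_donor > thresholds.u12_donor_min and u12_acceptor > thresholds.u12_acceptor_min:
        return "U12"
    if u2_donor > thresholds.u2_min and u2_acceptor > thresholds.u2_min:
        return "U2"
    return "unclassified"


def splice_site_windows(
    genome: GenomeAccessor, intron: GenomicInterval
) -> Tuple[str, str]:
    """Extract the 13-nt donor and acceptor windows around an intron.

    Returns (donor_window, acceptor_window) in transcript orientation.
    Windows truncated by a chromosome edge raise ValueError.
    """
    c, s, e = intron.chrom, intron.start, intron.end
    if intron.strand == "+":
        donor = genome.fetch(c, s - DONOR_EXONIC, s + WINDOW_LENGTH - DONOR_EXONIC, "+")
        acceptor = genome.fetch(c, e - WINDOW_LENGTH + ACCEPTOR_EXONIC, e + ACCEPTOR_EXONIC, "+")
    else:
        donor = genome.fetch(c, e - WINDOW_LENGTH + DONOR_EXONIC, e + DONOR_EXONIC, "-")
        acceptor = genome.fetch(c, s - ACCEPTOR_EXONIC, s + WINDOW_LENGTH - ACCEPTOR_EXONIC, "-")
    return donor, acceptor


# ---------------------------------------------------------------------------
# Matrix serialisation (headered TSV: position, A, C, G, T)


def write_pwm(matrix: np.ndarray, path) -> None:
    df = pd.DataFrame(matrix, columns=list(BASES))
    df.insert(0, "position", range(1, WINDOW_LENGTH + 1))
    df.to_csv(path, sep="\t", index=False)


def read_pwm(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["position"] + list(BASES):
        raise ValueError(f"{path}: expected header position, A, C, G, T")
    matrix = df[list(BASES)].to_numpy(dtype=float)
    if matrix.shape != (WINDOW_LENGTH, 4):
        raise ValueError(f"{path}: matrix must be {WINDOW_LENGTH} x 4")
    return matrix
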