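"""Fixed-AUG translation and in-silico tryptic peptide database.

Translating every isoform of a gene from the same start codon is what makes
the predicted consequences of an alternative-splicing event interpretable:
a longest-ORF call per transcript would silently re-initiate downstream of
a premature termination codon.  The anchor AUG of a gene is the start of
the longest ATG-initiated ORF over all its transcripts; every other
transcript is translated from that same genomic AUG when its three bases
are exonic and contiguous in the transcript's mRNA, and by its own longest
ORF otherwise (fallback).

Proteins are then digested with standard trypsin rules (cleave after every
K or R not followed by P, no missed cleavages), peptides shorter than seven
residues are discarded, and the remainder are indexed by the transcript set
they map to, flagging peptides unique to a single isoform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .core import TranscriptModel, Transcriptome

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Coordinate maps between mRNA offsets and genomic positions


def mrna_to_genomic(t: TranscriptModel, offset: int) -> int:
    """Genomic position (0-based) of mRNA base ``offset`` (0-based, 5'->3')."""
    if offset < 0 or offset >= t.exonic_length:
        raise IndexError(f"mRNA offset {offset} outside {t.transcript_id}")
    if t.strand == "+":
        remaining = offset
        for e in t.exons:
            if remaining < len(e):
                return e.start + remaining
            remaining -= len(e)
    else:
        remaining = offset
        for e in reversed(t.exons):
            if remaining < len(e):
                return e.end - 1 - remaining
            remaining -= len(e)
    raise AssertionError("unreachable")


def genomic_to_mrna(t: TranscriptModel, pos: int) -> Optional[int]:
    """mRNA offset of genomic position ``pos``, or None if not exonic in t."""
    if t.strand == "+":
        offset = 0
        for e in t.exons:
            if e.start <= pos < e.end:
                return offset + (pos - e.start)
            offset += len(e)
    else:
        offset = 0
        for e in reversed(t.exons):
            if e.start <= pos < e.end:
                return offset + (e.end - 1 - pos)
            offset += len(e)
    return None


# ---------------------------------------------------------------------------
# ORF scanning


def orf_length_at(seq: str, start: int) -> int:
    """Length in nt of the ORF starting at ``start`` (ATG through stop codon,
    or to the last complete codon when no stop occurs)."""
    n = len(seq)
    pos = start
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        pos += 3
        if codon in ("TAA", "TAG", "TGA"):
            return pos - start
    return pos - start


def longest_orf(seq: str) -> Optional[Tuple[int, int]]:
    """(start offset, length nt) of the longest ATG-initiated ORF.

    Ties go to the 5'-most ATG.  None when the sequence has no ATG that
    starts at least one full codon.
    """
    seq = seq.upper()
    best: Optional[Tuple[int, int]] = None
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        length = orf_length_at(seq, start)
        if length >= 3 and (best is None or length > best[1]):
            best = (start, length)
    return best


# ---------------------------------------------------------------------------
# Anchors and translation


@dataclass(frozen=True)
class GeneAnchor:
    """The gene-wide translation start: the AUG of the longest ORF."""

    gene_id: str
    transcript_id: str
    genomic_position: int  # first (5'-most in transcript orientation) AUG base
    orf_length: int  # nt, start codon through stop (or transcript end)
    codon_positions: Tuple[int, int, int] = ()  # genomic positions of A, U, G

    def __post_init__(self) -> None:
        if self.orf_length % 3 != 0:
            raise ValueError("anchor ORF length must be a codon multiple")


@dataclass
class ProteinRecord:
    transcript_id: str
    gene_id: str
    sequence: str  # amino acids, no terminal stop symbol
    mode: str  # anchored | fallback_longest_orf | untranslated
    stop_status: str  # stop_found | ran_off_end | none

    def __post_init__(self) -> None:
        if self.mode in ("anchored", "fallback_longest_orf"):
            if not self.sequence or not self.sequence.startswith("M"):
                raise ValueError(
                    f"{self.transcript_id}: translated protein must start with M"
                )


def select_anchor(
    transcripts: Sequence[TranscriptModel], sequences: Dict[str, str]
) -> Optional[GeneAnchor]:
    """Pick the gene anchor AUG from the transcript with the longest ORF.

    Ties across transcripts are broken by lexicographic transcript id (the
    5'-most AUG within a transcript is already preferred by longest_orf).
    Returns None when no transcript contains an ATG (gene untranslatable).
    """
    best: Optional[Tuple[int, str, int]] = None  # (-orf_len, tid, start)
    for t in sorted(transcripts, key=lambda m: m.transcript_id):
        hit = longest_orf(sequences[t.transcript_id])
        if hit is None:
            continue
        start, length = hit
        candidate = (-length, t.transcript_id, start)
        if best is None or candidate < best:
            best = candidate
    if best is None:
        return None
    neg_len, tid, start = best
    winner = next(t for t in transcripts if t.transcript_id == tid)
    codon = tuple(mrna_to_genomic(winner, start + k) for k in range(3))
    return GeneAnchor(
        gene_id=winner.gene_id,
        transcript_id=tid,
        genomic_position=codon[0],
        orf_length=-neg_len,
        codon_positions=codon,  # type: ignore[arg-type]
    )


def _translate_from(seq: str, offset: int, transcript_id: str, gene_id: str, mode: str) -> ProteinRecord:
    coding = seq[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    if "*" in aa:
        protein, status = aa[: aa.index("*")], "stop_found"
    else:
        protein, status = aa, "ran_off_end"
    return ProteinRecord(transcript_id, gene_id, protein, mode, status)


def translate_anchored(
    t: TranscriptModel, anchor: Optional[GeneAnchor], sequences: Dict[str, str]
) -> ProteinRecord:
    """Translate ``t`` from the gene anchor AUG, if it maps into ``t``.

    The anchor applies only when all three AUG bases are exonic in ``t``,
    appear in order at consecutive mRNA offsets, and read ATG.  Otherwise a
    sentinel record with mode ``"requires_fallback"`` is returned (a defined
    outcome, not an error: the typical cause is an AS event removing the
    anchor exon, or a shorter transcript starting downstream).
    """
    if anchor is None:
        return ProteinRecord(t.transcript_id, t.gene_id, "", "requires_fallback", "none")
    offsets = [genomic_to_mrna(t, pos) for pos in anchor.codon_positions]
    seq = sequences[t.transcript_id].upper()
    usable = (
        all(o is not None for o in offsets)
        and offsets[1] == offsets[0] + 1  # type: ignore[operator]
        and offsets[2] == offsets[0] + 2  # type: ignore[operator]
        and seq[offsets[0] : offsets[0] + 3] == "ATG"
    )
    if not usable:
        return ProteinRecord(t.transcript_id, t.gene_id, "", "requires_fallback", "none")
    return _translate_from(seq, offsets[0], t.transcript_id, t.gene_id, "anchored")


def translate_fallback(t: TranscriptModel, sequences: Dict[str, str]) -> ProteinRecord:
    """Translate ``t`` by its own longest ATG-initiated ORF."""
    seq = sequences[t.transcript_id].upper()
    hit = longest_orf(seq)
    if hit is None:
        return ProteinRecord(t.transcript_id, t.gene_id, "", "untranslated", "none")
    return _translate_from(seq, hit[0], t.transcript_id, t.gene_id, "fallback_longest_orf")


def translate_transcriptome(
    tx: Transcriptome, sequences: Dict[str, str]
) -> Tuple[List[ProteinRecord], Dict[str, Optional[GeneAnchor]]]:
    """Anchor every gene, translate every transcript (anchored, else fallback)."""
    proteins: List[ProteinRecord] = []
    anchors: Dict[str, Optional[GeneAnchor]] = {}
    for gene_id, models in tx.genes():
        anchor = select_anchor(models, sequences)
        anchors[gene_id] = anchor
        for t in models:
            rec = translate_anchored(t, anchor, sequences)
            if rec.mode == "requires_fallback":
                rec = translate_fallback(t, sequences)
            proteins.append(rec)
    return proteins, anchors


# ---------------------------------------------------------------------------
# Tryptic digestion and peptide index


def digest_trypsin(sequence: str, min_len: int = 7) -> List[str]:
    """Tryptic fragments of a protein, length-filtered.

    Cleaves after every K or R except when the next residue is P; no missed
    cleavages.  Residues outside the 20 standard amino acids are retained
    (never a cleavage site) with a warning.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    nonstandard = set(sequence) - STANDARD_AA
    if nonstandard:
        warnings.warn(
            f"non-standard residues {sorted(nonstandard)} retained, not cleaved"
        )
    fragments: List[str] = []
    start = 0
    for i, residue in enumerate(sequence):
        next_is_p = i + 1 < len(sequence) and sequence[i + 1] == "P"
        if residue in "KR" and not next_is_p:
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])
    return [f for f in fragments if len(f) >= min_len]


@dataclass
class PeptideIndex:
    """Global peptide -> {(gene_id, transcript_id)} map with uniqueness flags."""

    peptides: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)

    def is_unique(self, peptide: str) -> bool:
        return len({tid for _, tid in self.peptides[peptide]}) == 1

    @property
    def summary(self) -> Dict[str, float]:
        total = len(self.peptides)
        unique = [p for p in self.peptides if self.is_unique(p)]
        tids = {tid for p in unique for _, tid in self.peptides[p]}
        gids = {gid for p in unique for gid, _ in self.peptides[p]}
        return {
            "total_peptides": total,
            "unique_peptides": len(unique),
            "unique_fraction": (len(unique) / total) if total else 0.0,
            "transcripts_with_unique_peptide": len(tids),
            "genes_with_unique_peptide": len(gids),
        }


def build_peptide_index(
    proteins: Sequence[ProteinRecord], min_len: int = 7
) -> PeptideIndex:
    """Digest every translated protein and index peptides globally."""
    index = PeptideIndex()
    for rec in proteins:
        if rec.mode == "untranslated" or not rec.sequence:
            continue
        for peptide in digest_trypsin(rec.sequence, min_len=min_len):
            index.peptides.setdefault(peptide, set()).add(
                (rec.gene_id, rec.transcript_id)
            )
    return index
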