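"""Padded (QUASI) and trimmed transcriptome variants.

Transcripts of one gene often differ only in how far their terminal exons
extend (UTR length variation), which degrades isoform quantification.  Two
end-uniforming transforms address this:

* **padding** extends every transcript of a gene to the coordinates of the
  transcript covering the longest region, by growing the terminal exons with
  cognate genomic sequence (no new introns appear; an extension through
  another isoform's terminal intron yields an intron-retention-like end).
  The padded transcriptome is the QUASI variant.
* **trimming** clips every transcript to the coordinates of the transcript
  covering the shortest region; exons outside the window are dropped, and a
  trim boundary falling inside an intron truncates the transcript at the
  last complete exon edge inside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import GenomicInterval, Transcriptome, TranscriptModel, genomic_span
from .io import GenomeAccessor


@dataclass
class EndAdjustment:
    """Record of one transcript's end change, in gene-strand orientation."""

    transcript_id: str
    mode: str  # "pad" or "trim"
    old_span: Tuple[int, int]
    new_span: Tuple[int, int]
    delta_5p: int  # nucleotides added (pad) or removed (trim) at the 5' end
    delta_3p: int

    def __post_init__(self) -> None:
        if self.mode not in ("pad", "trim"):
            raise ValueError(f"mode must be pad or trim, got {self.mode!r}")
        if self.delta_5p < 0 or self.delta_3p < 0:
            raise ValueError("end deltas are magnitudes and must be >= 0")


def _deltas(old: Tuple[int, int], new: Tuple[int, int], strand: str) -> Tuple[int, int]:
    """(5' delta, 3' delta) magnitudes between two spans, strand-oriented."""
    left = abs(new[0] - old[0])
    right = abs(new[1] - old[1])
    return (right, left) if strand == "-" else (left, right)


def pad_gene(
    transcripts: Sequence[TranscriptModel],
    genome: Optional[GenomeAccessor] = None,
) -> Tuple[List[TranscriptModel], List[EndAdjustment]]:
    """Extend every transcript to the gene's widest span.

    Only the first exon's start and last exon's end move; intron chains are
    untouched.  ``genome`` (when given) is used to check chromosome bounds —
    the extension itself is pure coordinate arithmetic, with sequence
    realised later by extract_sequences.
    """
    if not transcripts:
        return [], []
    chrom, strand = transcripts[0].chrom, transcripts[0].strand
    lo = min(t.exons[0].start for t in transcripts)
    hi = max(t.exons[-1].end for t in transcripts)
    if genome is not None and hi > genome.chrom_length(chrom):
        raise ValueError(f"padded span [{lo},{hi}) exceeds {chrom} bounds")
    adjusted: List[TranscriptModel] = []
    log: List[EndAdjustment] = []
    for t in transcripts:
        exons = list(t.exons)
        old = (exons[0].start, exons[-1].end)
        exons[0] = GenomicInterval(chrom, lo, exons[0].end, strand)
        exons[-1] = GenomicInterval(chrom, exons[-1].start, hi, strand)
        if len(exons) == 1:
            exons = [GenomicInterval(chrom, lo, hi, strand)]
        adjusted.append(TranscriptModel(t.transcript_id, t.gene_id, exons))
        d5, d3 = _deltas(old, (lo, hi), strand)
        log.append(EndAdjustment(t.transcript_id, "pad", old, (lo, hi), d5, d3))
    return adjusted, log


def trim_gene(
    transcripts: Sequence[TranscriptModel],
) -> Tuple[List[TranscriptModel], List[EndAdjustment]]:
    """Clip every transcript to the gene's narrowest span.

    The window is [max start, min end) over the gene's transcripts.  An empty
    window (no shared region) skips the gene with a warning.  Transcripts
    left without any exon inside the window are dropped with a warning.
    """
    if not transcripts:
        return [], []
    chrom, strand = transcripts[0].chrom, transcripts[0].strand
    lo = max(t.exons[0].start for t in transcripts)
    hi = min(t.exons[-1].end for t in transcripts)
    if lo >= hi:
        warnings.warn(
            f"gene {transcripts[0].gene_id}: empty trim window "
            f"[{lo},{hi}); gene skipped"
        )
        return [], []
    adjusted: List[TranscriptModel] = []
    log: List[EndAdjustment] = []
    for t in transcripts:
        old = (t.exons[0].start, t.exons[-1].end)
        exons = []
        for e in t.exons:
            s, x = max(e.start, lo), min(e.end, hi)
            if s < x:
                exons.append(GenomicInterval(chrom, s, x, strand))
        if not exons:
            warnings.warn(
                f"{t.transcript_id}: no exonic sequence inside trim window; dropped"
            )
            continue
        new = (exons[0].start, exons[-1].end)
        adjusted.append(TranscriptModel(t.transcript_id, t.gene_id, exons))
        d5, d3 = _deltas(old, new, strand)
        log.append(EndAdjustment(t.transcript_id, "trim", old, new, d5, d3))
    return adjusted, log


def _apply_per_gene(tx: Transcriptome, fn, name: str) -> Tuple[Transcriptome, List[EndAdjustment]]:
    out = Transcriptome(name)
    log: List[EndAdjustment] = []
    for _, models in tx.genes():
        adjusted, gene_log = fn(models)
        for t in adjusted:
            out.add(t)
        log.extend(gene_log)
    return out, log


def build_quasi(
    tx: Transcriptome, genome: Optional[GenomeAccessor] = None
) -> Tuple[Transcriptome, List[EndAdjustment]]:
    """Pad every gene: the QUASI transcriptome (per-gene uniform spans)."""
    return _apply_per_gene(tx, lambda ms: pad_gene(ms, genome), tx.name + "-QUASI")


def build_trimmed(tx: Transcriptome) -> Tuple[Transcriptome, List[EndAdjustment]]:
    """Trim every gene to its shared window."""
    return _apply_per_gene(tx, trim_gene, tx.name + "-trimmed")


def transcript_sequence(t: TranscriptModel, genome: GenomeAccessor) -> str:
    """Spliced mRNA sequence, 5'->3' (minus strand reverse-complemented)."""
    parts = [genome.fetch(e.chrom, e.start, e.end, "+") for e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        from .io import reverse_complement

        seq = reverse_complement(seq)
    return seq


def extract_sequences(tx: Transcriptome, genome: GenomeAccessor) -> Dict[str, str]:
    """transcript_id -> spliced sequence for the whole transcriptome."""
    return {t.transcript_id: transcript_sequence(t, genome) for t in tx}


def adjustments_frame(log: Sequence[EndAdjustment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "mode": a.mode,
                "old_start": a.old_span[0],
                "old_end": a.old_span[1],
                "new_start": a.new_span[0],
                "new_end": a.new_span[1],
                "delta_5p": a.delta_5p,
                "delta_3p": a.delta_3p,
            }
            for a in log
        ]
    )
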