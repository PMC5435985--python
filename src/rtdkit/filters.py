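"""Transcript-level quality filters applied to assembled transcriptomes.

Four filters, applied after junction QC: removal of transcripts with
unsupported or non-canonical introns, of antisense transcripts fully
contained within an annotated gene, of transcripts from unknown genes, and
of transcripts with no or very low expression (TPM > 1 in fewer than three
samples).  Each filter returns a FilterReport recording the fate of every
input transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd
from intervaltree import IntervalTree

from .core import Transcriptome, genomic_span, introns_of
from .junctions import JunctionKey

REASONS = (
    "unsupported_junction",
    "non_canonical_junction",
    "antisense_contained",
    "unknown_gene",
    "low_expression",
)


@dataclass
class FilterReport:
    """Partition of the input transcript ids into kept and removed (+reason)."""

    kept: List[str] = field(default_factory=list)
    removed: Dict[str, str] = field(default_factory=dict)
    reassigned: Dict[str, str] = field(default_factory=dict)  # tid -> new gene_id

    def apply(self, tx: Transcriptome, name: Optional[str] = None) -> Transcriptome:
        return tx.subset(self.kept, name=name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"transcript_id": tid, "fate": "kept", "reason": ""} for tid in self.kept]
        rows += [
            {"transcript_id": tid, "fate": "removed", "reason": reason}
            for tid, reason in self.removed.items()
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "fate", "reason"]).sort_values(
            "transcript_id", ignore_index=True
        )


def filter_by_junctions(
    tx: Transcriptome,
    passing: Set[JunctionKey],
    non_canonical: Optional[Set[JunctionKey]] = None,
) -> FilterReport:
    """Keep multi-exon transcripts whose introns ALL pass junction QC.

    Mono-exonic transcripts pass vacuously.  When ``non_canonical`` is given,
    a failing transcript whose first failing intron is in that set is
    recorded as ``non_canonical_junction`` instead of ``unsupported_junction``.
    """
    report = FilterReport()
    for t in tx:
        failing = [
            i for i in introns_of(t)
            if (i.chrom, i.strand, i.start, i.end) not in passing
        ]
        if not failing:
            report.kept.append(t.transcript_id)
            continue
        reason = "unsupported_junction"
        if non_canonical is not None:
            keys = {(i.chrom, i.strand, i.start, i.end) for i in failing}
            if keys & non_canonical:
                reason = "non_canonical_junction"
        report.removed[t.transcript_id] = reason
    return report


def _gene_span_trees(reference: Transcriptome) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for gene_id in reference.gene_index:
        span = reference.gene_span(gene_id)
        trees.setdefault(span.chrom, IntervalTree()).addi(
            span.start, span.end, (gene_id, span.strand)
        )
    return trees


def filter_antisense(tx: Transcriptome, reference: Transcriptome) -> FilterReport:
    """Remove transcripts completely contained, antisense, in a reference gene.

    The containing region is the reference gene's genomic span (min exon start
    to max exon end over all its transcripts).  Transcripts that merely
    overlap, or that extend beyond the gene span, are kept.
    """
    trees = _gene_span_trees(reference)
    report = FilterReport()
    for t in tx:
        span = genomic_span(t)
        contained_antisense = any(
            hit.begin <= span.start and span.end <= hit.end and hit.data[1] != span.strand
            for hit in trees.get(span.chrom, IntervalTree()).overlap(span.start, span.end)
        )
        if contained_antisense:
            report.removed[t.transcript_id] = "antisense_contained"
        else:
            report.kept.append(t.transcript_id)
    return report


def _exon_trees(reference: Transcriptome) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for t in reference:
        for e in t.exons:
            trees.setdefault(e.chrom, IntervalTree()).addi(
                e.start, e.end, (t.gene_id, e.strand)
            )
    return trees


def filter_unknown_genes(
    tx: Transcriptome,
    known_gene_ids: Set[str],
    reference: Optional[Transcriptome] = None,
) -> FilterReport:
    """Remove transcripts from unknown genes.

    A transcript whose gene_id is in ``known_gene_ids`` is kept.  Otherwise,
    if a reference transcriptome is supplied and the transcript has >= 1 bp of
    same-strand exonic overlap with a known gene, it is rescued: re-assigned
    to that gene (recorded in ``reassigned``) and kept.  Remaining novel
    transcripts are removed.
    """
    trees = _exon_trees(reference) if reference is not None else {}
    report = FilterReport()
    for t in tx:
        if t.gene_id in known_gene_ids:
            report.kept.append(t.transcript_id)
            continue
        overlapping_genes = sorted(
            {
                hit.data[0]
                for e in t.exons
                for hit in trees.get(e.chrom, IntervalTree()).overlap(e.start, e.end)
                if hit.data[1] == e.strand and hit.data[0] in known_gene_ids
            }
        )
        if overlapping_genes:
            report.reassigned[t.transcript_id] = overlapping_genes[0]
            report.kept.append(t.transcript_id)
        else:
            report.removed[t.transcript_id] = "unknown_gene"
    return report


def apply_reassignments(tx: Transcriptome, report: FilterReport) -> Transcriptome:
    """Return a copy of ``tx`` with the report's gene re-assignments applied."""
    from dataclasses import replace

    out = Transcriptome(tx.name)
    for t in tx:
        new_gene = report.reassigned.get(t.transcript_id)
        out.add(replace(t, gene_id=new_gene) if new_gene else t)
    return out


def filter_low_expression(
    tx: Transcriptome,
    quant: pd.DataFrame,
    min_tpm: float = 1.0,
    min_samples: int = 3,
) -> FilterReport:
    """Keep transcripts with TPM strictly above ``min_tpm`` in >= ``min_samples`` samples.

    Transcripts missing from the quant table are treated as all-zero (hence
    removed) with a warning.
    """
    report = FilterReport()
    missing = [t.transcript_id for t in tx if t.transcript_id not in quant.index]
    if missing:
        warnings.warn(
            f"{len(missing)} transcripts absent from quant table; treated as TPM 0"
        )
    for t in tx:
        tid = t.transcript_id
        if tid in quant.index:
            qualifying = int((quant.loc[tid] > min_tpm).sum())
        else:
            qualifying = 0
        if qualifying >= min_samples:
            report.kept.append(tid)
        else:
            report.removed[tid] = "low_expression"
    return report
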