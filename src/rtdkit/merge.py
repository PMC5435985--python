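"""Step-wise merging of filtered transcriptomes into one non-redundant RTD.

Redundancy is defined by the intron chain: within a gene, two multi-exon
transcripts with identical intron coordinates are the same underlying model
with different UTR extents, and only one representative is retained — the
one covering the longest genomic span (ties broken by lexicographically
smallest transcript id).  Mono-exonic transcripts are redundant only when
their spans are exactly identical.

Merging folds transcriptomes left to right: gene ids of incoming transcripts
are reconciled to the base by same-strand exon overlap, then redundancy is
removed with the base representative preferred unless the incoming one
covers a longer span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .core import (
    Transcriptome,
    TranscriptModel,
    genomic_span,
    intron_chain_key,
)


@dataclass
class MergePlan:
    """Ordered inputs for a step-wise merge."""

    inputs: List[Tuple[Transcriptome, str]]
    apply_redundancy: bool = True

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("merge plan needs >= 1 input transcriptome")
        labels = [label for _, label in self.inputs]
        if len(set(labels)) != len(labels):
            raise ValueError("merge plan labels must be unique")


def _redundancy_groups(models: Sequence[TranscriptModel]):
    """Group a gene's transcripts into redundancy classes.

    Multi-exon: by intron chain key.  Mono-exonic: by exact span.
    """
    groups: Dict[object, List[TranscriptModel]] = {}
    for t in models:
        if len(t.exons) > 1:
            key: object = ("chain", intron_chain_key(t))
        else:
            s = genomic_span(t)
            key = ("span", s.chrom, s.strand, s.start, s.end)
        groups.setdefault(key, []).append(t)
    return groups


def _representative(
    candidates: Sequence[TranscriptModel], priority: Optional[Dict[str, int]] = None
) -> TranscriptModel:
    """Longest genomic span wins; ties: lower priority rank, then smallest id."""

    def sort_key(t: TranscriptModel):
        rank = priority.get(t.transcript_id, 0) if priority else 0
        return (-len(genomic_span(t)), rank, t.transcript_id)

    return min(candidates, key=sort_key)


def remove_redundant(
    tx: Transcriptome, priority: Optional[Dict[str, int]] = None
) -> Transcriptome:
    """Drop redundant transcripts gene by gene.

    ``priority`` maps transcript_id -> rank used only to break exact span
    ties (lower rank preferred); merge_step uses it to prefer base-side
    representatives.
    """
    out = Transcriptome(tx.name)
    for _, models in tx.genes():
        for group in _redundancy_groups(models).values():
            out.add(_representative(group, priority))
    return out


def _reconcile_gene_ids(
    base: Transcriptome, incoming: Transcriptome
) -> Tuple[Transcriptome, List[str]]:
    """Re-assign incoming gene ids by same-strand exon overlap with base genes.

    A transcript overlapping exactly one base gene adopts its id; one
    overlapping several base genes keeps its own id and is flagged for the
    report; no overlap keeps its own id (a novel locus).
    """
    trees: Dict[str, IntervalTree] = {}
    for t in base:
        for e in t.exons:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, (t.gene_id, e.strand))

    flagged: List[str] = []
    out = Transcriptome(incoming.name)
    for t in incoming:
        hits = sorted(
            {
                hit.data[0]
                for e in t.exons
                for hit in trees.get(e.chrom, IntervalTree()).overlap(e.start, e.end)
                if hit.data[1] == e.strand
            }
        )
        if len(hits) == 1 and hits[0] != t.gene_id:
            t = replace(t, gene_id=hits[0])
        elif len(hits) > 1:
            flagged.append(t.transcript_id)
        out.add(t)
    return out, flagged


@dataclass
class MergeStepReport:
    label: str = ""
    added: int = 0
    dropped: int = 0
    flagged_multi_gene: List[str] = field(default_factory=list)


def merge_step(
    base: Transcriptome, incoming: Transcriptome, label: str = ""
) -> Tuple[Transcriptome, MergeStepReport]:
    """Union the two transcriptomes, then remove redundancy.

    When base and incoming contain the same intron chain (or identical
    mono-exon span), the base representative is kept unless the incoming one
    covers a strictly longer genomic span.
    """
    incoming, flagged = _reconcile_gene_ids(base, incoming)
    merged = Transcriptome(base.name or "merged")
    priority: Dict[str, int] = {}
    for t in base:
        priority[t.transcript_id] = 0
        merged.add(t)
    for t in incoming:
        if t.transcript_id in merged.transcripts:
            raise ValueError(
                f"transcript id {t.transcript_id!r} present in both merge inputs"
            )
        priority[t.transcript_id] = 1
        merged.add(t)
    result = remove_redundant(merged, priority)
    report = MergeStepReport(
        label=label,
        added=len(result) - len(base),
        dropped=len(merged) - len(result),
        flagged_multi_gene=flagged,
    )
    return result, report


def run_merge_plan(plan: MergePlan) -> Tuple[Transcriptome, pd.DataFrame]:
    """Left fold of merge_step over the plan's inputs, with a per-step report."""
    first_tx, first_label = plan.inputs[0]
    current = remove_redundant(first_tx) if plan.apply_redundancy else first_tx
    rows = [
        {
            "step": first_label,
            "added": len(current),
            "dropped": len(first_tx) - len(current),
            "total": len(current),
            "flagged": "",
        }
    ]
    for tx, label in plan.inputs[1:]:
        current, rep = merge_step(current, tx, label)
        rows.append(
            {
                "step": label,
                "added": rep.added,
                "dropped": rep.dropped,
                "total": len(current),
                "flagged": ",".join(rep.flagged_multi_gene),
            }
        )
    return current, pd.DataFrame(rows)
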