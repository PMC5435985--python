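"""Pairwise alternative-splicing events and AS/FS splicing ratios.

The classifier compares the intron chains of two isoforms of one gene
inside their shared genomic window and labels each local difference:

* **IR** — an intron of one isoform is fully exonic in the other
  (intron retention; the retaining isoform is the AS form);
* **Alt5 / Alt3** — two introns share one boundary; the moving boundary is
  the donor (Alt5) or acceptor (Alt3), judged strand-aware; the isoform
  with the shorter intron (more included sequence) is the AS form;
* **ES** — an exon flanked by two introns of one isoform is absent from the
  other, which joins the outer boundaries in a single intron (the skipping
  isoform is the AS form).

Splicing ratios are AS/FS abundance quotients: summed TPMs of the AS
transcript set over summed TPMs of the event's fully spliced (FS) set, or
the peak-area equivalent from high-resolution RT-PCR.  The FS form is
structural — designated at event construction — never abundance-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .core import GenomicInterval, TranscriptModel, introns_of

EVENT_TYPES = ("IR", "Alt5", "Alt3", "ES", "unclassified")


@dataclass
class ASEvent:
    event_id: str
    gene_id: str
    etype: str
    intervals: List[Tuple[int, int]]
    as_ids: List[str]
    fs_ids: List[str]

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if not self.as_ids or not self.fs_ids:
            raise ValueError("AS and FS transcript sets must be non-empty")
        if set(self.as_ids) & set(self.fs_ids):
            raise ValueError("AS and FS sets must be disjoint")


@dataclass
class SplicingRatio:
    event_id: str
    sample_id: str
    ratio: float
    source: str  # "rnaseq" | "hr_rtpcr"
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and (self.ratio < 0 or math.isnan(self.ratio)):
            raise ValueError("defined splicing ratios must be >= 0")


def _donor_acceptor(intron: Tuple[int, int], strand: str) -> Tuple[int, int]:
    """(donor boundary, acceptor boundary) genomic coordinates of an intron."""
    start, end = intron
    return (start, end) if strand == "+" else (end, start)


def detect_events_pairwise(
    t_a: TranscriptModel, t_b: TranscriptModel, event_prefix: str = "ev"
) -> List[ASEvent]:
    """Classify local structural differences between two isoforms of a gene."""
    if t_a.gene_id != t_b.gene_id:
        raise ValueError(
            f"transcripts from different genes: {t_a.gene_id} vs {t_b.gene_id}"
        )
    strand = t_a.strand
    window = (
        max(t_a.exons[0].start, t_b.exons[0].start),
        min(t_a.exons[-1].end, t_b.exons[-1].end),
    )
    if window[0] >= window[1]:
        return []

    def in_window(iv: Tuple[int, int]) -> bool:
        return window[0] <= iv[0] and iv[1] <= window[1]

    introns = {
        "a": [(i.start, i.end) for i in introns_of(t_a) if in_window((i.start, i.end))],
        "b": [(i.start, i.end) for i in introns_of(t_b) if in_window((i.start, i.end))],
    }
    models = {"a": t_a, "b": t_b}
    shared = set(introns["a"]) & set(introns["b"])
    only = {k: [iv for iv in introns[k] if iv not in shared] for k in ("a", "b")}

    events: List[ASEvent] = []
    explained = {"a": set(), "b": set()}
    counter = 0

    def add(etype: str, intervals: List[Tuple[int, int]], as_side: str) -> None:
        nonlocal counter
        fs_side = "b" if as_side == "a" else "a"
        counter += 1
        events.append(
            ASEvent(
                event_id=f"{event_prefix}{counter}",
                gene_id=t_a.gene_id,
                etype=etype,
                intervals=intervals,
                as_ids=[models[as_side].transcript_id],
                fs_ids=[models[fs_side].transcript_id],
            )
        )

    def exon_containing(side: str, iv: Tuple[int, int]) -> bool:
        return any(e.start <= iv[0] and iv[1] <= e.end for e in models[side].exons)

    # Exon skipping: one intron of `long_side` spans two introns plus the
    # intervening exon of the other isoform.
    for long_side, short_side in (("a", "b"), ("b", "a")):
        for iv in only[long_side]:
            inner = [
                jv
                for jv in only[short_side]
                if iv[0] <= jv[0] and jv[1] <= iv[1]
            ]
            if len(inner) == 2 and inner[0][0] == iv[0] and inner[1][1] == iv[1]:
                skipped = (inner[0][1], inner[1][0])
                if any(
                    e.start == skipped[0] and e.end == skipped[1]
                    for e in models[short_side].exons
                ):
                    add("ES", [skipped], as_side=long_side)
                    explained[long_side].add(iv)
                    explained[short_side].update(inner)

    # Intron retention: an unshared intron fully inside one exon of the other.
    for side, other in (("a", "b"), ("b", "a")):
        for iv in only[side]:
            if iv in explained[side]:
                continue
            if exon_containing(other, iv):
                add("IR", [iv], as_side=other)
                explained[side].add(iv)

    # Alternative donor / acceptor: intron pairs sharing exactly one boundary.
    for iv in only["a"]:
        if iv in explained["a"]:
            continue
        for jv in only["b"]:
            if jv in explained["b"]:
                continue
            same_start, same_end = iv[0] == jv[0], iv[1] == jv[1]
            if same_start == same_end:  # both or neither shared
                continue
            d_a, a_a = _donor_acceptor(iv, strand)
            d_b, a_b = _donor_acceptor(jv, strand)
            etype = "Alt5" if a_a == a_b else "Alt3"
            diff = (min(iv[0], jv[0]), max(iv[0], jv[0])) if not same_start else (
                min(iv[1], jv[1]),
                max(iv[1], jv[1]),
            )
            shorter_side = "a" if (iv[1] - iv[0]) < (jv[1] - jv[0]) else "b"
            add(etype, [diff], as_side=shorter_side)
            explained["a"].add(iv)
            explained["b"].add(jv)
            break

    # Anything left is a structural difference this classifier does not name.
    for side, other in (("a", "b"), ("b", "a")):
        for iv in only[side]:
            if iv not in explained[side]:
                add("unclassified", [iv], as_side=side)
                explained[side].add(iv)
    return events


# ---------------------------------------------------------------------------
# Splicing ratios


def splicing_ratio_from_tpm(
    event: ASEvent, quant: pd.DataFrame, sample_id: str
) -> SplicingRatio:
    """AS/FS ratio from a TPM matrix (transcripts x samples)."""
    missing = [t for t in event.as_ids + event.fs_ids if t not in quant.index]
    if missing:
        raise KeyError(f"event {event.event_id}: transcripts missing from quant: {missing}")
    as_total = float(quant.loc[event.as_ids, sample_id].sum())
    fs_total = float(quant.loc[event.fs_ids, sample_id].sum())
    if fs_total == 0:
        return SplicingRatio(event.event_id, sample_id, float("nan"), "rnaseq", defined=False)
    return SplicingRatio(event.event_id, sample_id, as_total / fs_total, "rnaseq")


def splicing_ratio_from_peaks(
    peaks: pd.DataFrame, event_id: str, sample_id: str
) -> List[SplicingRatio]:
    """AS/FS ratios from HR RT-PCR peak areas; one record per AS product."""
    rows = peaks[(peaks["event_id"] == event_id) & (peaks["sample_id"] == sample_id)]
    fs_rows = rows[rows["product_label"] == "FS"]
    if len(fs_rows) != 1:
        raise ValueError(
            f"event {event_id}, sample {sample_id}: expected exactly one FS row"
        )
    fs_area = float(fs_rows["peak_area"].iloc[0])
    out: List[SplicingRatio] = []
    for _, row in rows[rows["product_label"] != "FS"].iterrows():
        if fs_area == 0:
            out.append(
                SplicingRatio(event_id, sample_id, float("nan"), "hr_rtpcr", defined=False)
            )
        else:
            out.append(
                SplicingRatio(event_id, sample_id, float(row["peak_area"]) / fs_area, "hr_rtpcr")
            )
    return out


def concordance(
    rnaseq: Sequence[SplicingRatio], rtpcr: Sequence[SplicingRatio]
) -> Tuple[float, float, int]:
    """Pearson r and Spearman rho between paired RNA-seq and RT-PCR ratios.

    Records are paired on (event_id, sample_id); pairs where either side is
    undefined are excluded.  All events x samples are pooled into one vector
    pair.  Fewer than 3 usable pairs is an error.
    """
    left = {(r.event_id, r.sample_id): r for r in rnaseq}
    right = {(r.event_id, r.sample_id): r for r in rtpcr}
    x: List[float] = []
    y: List[float] = []
    for key in sorted(left.keys() & right.keys()):
        a, b = left[key], right[key]
        if a.defined and b.defined:
            x.append(a.ratio)
            y.append(b.ratio)
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired defined ratios, have {len(x)}")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return pearson, spearman, len(x)


# ---------------------------------------------------------------------------
# Event table serialisation (TSV: event_id, gene_id, type, as_ids, fs_ids)


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "type": e.etype,
                "as_ids": ",".join(e.as_ids),
                "fs_ids": ",".join(e.fs_ids),
            }
            for e in events
        ],
        columns=["event_id", "gene_id", "type", "as_ids", "fs_ids"],
    )


def events_from_frame(df: pd.DataFrame) -> List[ASEvent]:
    return [
        ASEvent(
            event_id=row["event_id"],
            gene_id=row["gene_id"],
            etype=row["type"],
            intervals=[],
            as_ids=row["as_ids"].split(","),
            fs_ids=row["fs_ids"].split(","),
        )
        for _, row in df.iterrows()
    ]
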