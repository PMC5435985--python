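"""Strand-aware genomic data model shared by every pipeline stage.

Coordinates are 0-based half-open throughout the package; GTF input/output
converts to and from the 1-based inclusive convention at the file boundary.
Minus-strand transcripts store exons in genomic order (sorted by start); the
biological 5' end of a minus-strand transcript is its highest genomic
coordinate, and strand is interpreted at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

Strand = str  # "+" or "-"

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp on the same chromosome.

        Strand is deliberately ignored here; callers that care about strand
        (antisense containment, gene reassignment) test it explicitly.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


# An intron chain key identifies the intron structure of a transcript:
# (chrom, strand, ((start, end), ...)).  Mono-exonic transcripts share the
# empty chain; their redundancy is resolved separately by exact span identity.
IntronChainKey = Tuple[str, Strand, Tuple[Tuple[int, int], ...]]


@dataclass
class TranscriptModel:
    """One transcript: an ordered chain of disjoint exons on one strand.

    Exons are stored sorted by genomic start with a gap of at least 1 bp
    between consecutive exons (the gaps are the introns).
    """

    transcript_id: str
    gene_id: str
    exons: List[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or touch "
                    f"([{a.start},{a.end}) then [{b.start},{b.end}))"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> Strand:
        return self.exons[0].strand

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


def introns_of(t: TranscriptModel) -> List[GenomicInterval]:
    """Gaps between consecutive exons, in genomic order; [] if mono-exonic."""
    return [
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def genomic_span(t: TranscriptModel) -> GenomicInterval:
    """The interval from the first exon's start to the last exon's end."""
    return GenomicInterval(t.chrom, t.exons[0].start, t.exons[-1].end, t.strand)


def intron_chain_key(t: TranscriptModel) -> IntronChainKey:
    """Identity key for redundancy removal.

    Two transcripts get equal keys iff they sit on the same chromosome and
    strand and have identical intron coordinates — regardless of how far
    their terminal exons (UTRs) extend.
    """
    return (
        t.chrom,
        t.strand,
        tuple((i.start, i.end) for i in introns_of(t)),
    )


@dataclass
class Transcriptome:
    """A named collection of transcripts with a gene index."""

    name: str
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
        self.transcripts[t.transcript_id] = t

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    @property
    def gene_index(self) -> Dict[str, List[str]]:
        """gene_id -> sorted transcript_ids (rebuilt on access)."""
        index: Dict[str, List[str]] = {}
        for t in self:
            index.setdefault(t.gene_id, []).append(t.transcript_id)
        for ids in index.values():
            ids.sort()
        return index

    def genes(self) -> Iterator[Tuple[str, List[TranscriptModel]]]:
        """Iterate (gene_id, transcripts) in sorted gene order."""
        for gene_id, tids in sorted(self.gene_index.items()):
            yield gene_id, [self.transcripts[tid] for tid in tids]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Min exon start to max exon end over all transcripts of the gene."""
        models = [self.transcripts[tid] for tid in self.gene_index[gene_id]]
        return GenomicInterval(
            models[0].chrom,
            min(t.exons[0].start for t in models),
            max(t.exons[-1].end for t in models),
            models[0].strand,
        )

    def subset(self, transcript_ids: Iterable[str], name: Optional[str] = None) -> "Transcriptome":
        out = Transcriptome(name or self.name)
        for tid in transcript_ids:
            out.add(self.transcripts[tid])
        return out
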