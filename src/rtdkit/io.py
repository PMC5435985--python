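"""Readers and writers for the standard files the pipeline touches.

Dialects supported: GTF exon features (gene_id / transcript_id attributes),
FASTA genomes, STAR-style ``SJ.out.tab`` junction tables, Salmon-style
``quant.sf`` abundance tables, and headered peak-area TSVs from
high-resolution RT-PCR.  All coordinate conversion between the 1-based
inclusive file conventions and the package's 0-based half-open convention
happens here and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from gffutils.feature import feature_from_line
from pyfaidx import Fasta

from .core import GenomicInterval, Transcriptome, TranscriptModel, introns_of

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: PathLike) -> Transcriptome:
    """Read exon features from a GTF file into a Transcriptome.

    Features other than ``exon`` are ignored.  1-based inclusive coordinates
    become 0-based half-open.  Malformed lines raise a ValueError naming the
    line number.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    genes: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise ValueError(
                    f"{path}:{lineno}: exon line missing {exc} attribute"
                ) from None
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: exon of {tid} lacks an explicit strand"
                )
            interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons.setdefault(tid, []).append(interval)
            genes[tid] = gid
    tx = Transcriptome(name=str(path))
    for tid in sorted(exons):
        tx.add(TranscriptModel(tid, genes[tid], exons[tid]))
    return tx


def write_gtf(tx: Transcriptome, path: PathLike, source: str = "rtdkit") -> None:
    """Write exon (and transcript) features; round-trips through read_gtf."""
    with open(path, "w") as fh:
        for gene_id, models in tx.genes():
            for t in models:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                span = (t.exons[0].start + 1, t.exons[-1].end)
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{span[0]}\t{span[1]}"
                    f"\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{e.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Splice-junction tables (SJ.out.tab dialect)


@dataclass
class JunctionRecord:
    """One intron observed in one sample, with read support."""

    interval: Optional[GenomicInterval]  # None when strand is undetermined
    chrom: str
    start: int  # 0-based half-open intron coordinates
    end: int
    strand: Optional[str]  # None = undetermined (strand code 0)
    unique_reads: int
    multi_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ValueError("read counts must be non-negative")


_SJ_STRAND = {0: None, 1: "+", 2: "-"}


def read_sj_tab(path: PathLike, sample_id: str) -> List[JunctionRecord]:
    """Read a 9-column SJ.out.tab file.

    Columns: chrom, intron first base (1-based), intron last base (1-based),
    strand code (0 undetermined / 1 '+' / 2 '-'), motif code, annotated flag,
    unique-read count, multi-read count, max overhang.
    """
    records: List[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start = int(fields[1]) - 1  # 1-based first base -> half-open start
            end = int(fields[2])  # 1-based last base == half-open end
            strand = _SJ_STRAND[int(fields[3])]
            unique, multi = int(fields[6]), int(fields[7])
            interval = (
                GenomicInterval(chrom, start, end, strand) if strand else None
            )
            records.append(
                JunctionRecord(interval, chrom, start, end, strand, unique, multi, sample_id)
            )
    return records


# ---------------------------------------------------------------------------
# Quantification tables (quant.sf dialect)

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


def read_quant(paths: Sequence[PathLike], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Read per-sample quant.sf files into a TPM matrix.

    Returns a DataFrame indexed by transcript_id with one column per sample.
    Transcripts absent from a sample are filled with TPM 0 (with a warning).
    """
    if len(paths) != len(sample_ids):
        raise ValueError("paths and sample_ids must have equal length")
    columns: Dict[str, pd.Series] = {}
    for path, sample in zip(paths, sample_ids):
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != QUANT_COLUMNS:
            raise ValueError(
                f"{path}: expected header {QUANT_COLUMNS}, got {list(df.columns)}"
            )
        if (df["TPM"] < 0).any():
            raise ValueError(f"{path}: negative TPM value")
        columns[sample] = df.set_index("Name")["TPM"]
    matrix = pd.DataFrame(columns)
    if matrix.isna().any().any():
        missing = int(matrix.isna().any(axis=1).sum())
        warnings.warn(
            f"{missing} transcripts missing from some samples; TPM filled with 0"
        )
        matrix = matrix.fillna(0.0)
    matrix.index.name = "transcript_id"
    return matrix


def write_quant(tpm: pd.Series, lengths: pd.Series, path: PathLike) -> None:
    """Write one sample's TPMs in the 5-column quant.sf dialect."""
    df = pd.DataFrame(
        {
            "Name": tpm.index,
            "Length": lengths.reindex(tpm.index).astype(int).values,
            "EffectiveLength": lengths.reindex(tpm.index).astype(float).values,
            "TPM": tpm.values,
            "NumReads": tpm.values,  # placeholder read counts proportional to TPM
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peak-area tables (HR RT-PCR)

PEAK_COLUMNS = ["gene_id", "event_id", "product_label", "sample_id", "peak_area"]


def read_peak_areas(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PEAK_COLUMNS:
        raise ValueError(f"{path}: expected header {PEAK_COLUMNS}")
    if (df["peak_area"] < 0).any():
        raise ValueError(f"{path}: negative peak area")
    fs = df[df["product_label"] == "FS"].groupby(["event_id", "sample_id"]).size()
    if (fs != 1).any():
        raise ValueError(f"{path}: each (event_id, sample_id) needs exactly one FS row")
    return df


# ---------------------------------------------------------------------------
# Genome FASTA


class GenomeAccessor:
    """Random-access, strand-aware sequence fetch over an indexed FASTA."""

    def __init__(self, path: PathLike):
        self.path = Path(path)
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def chroms(self) -> List[str]:
        return list(self._fasta.keys())

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Fetch [start, end) in uppercase; reverse-complemented on '-'."""
        if chrom not in self._fasta:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._fasta[chrom]) or start >= end:
            raise ValueError(
                f"[{start}, {end}) out of range for {chrom} "
                f"(length {len(self._fasta[chrom])})"
            )
        seq = str(self._fasta[chrom][start:end])
        return reverse_complement(seq) if strand == "-" else seq


def read_genome(path: PathLike) -> GenomeAccessor:
    return GenomeAccessor(path)


def write_fasta(records: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
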