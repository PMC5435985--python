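"""End-to-end orchestration: junction QC -> transcript filters -> merge ->
QUASI padding -> fixed-AUG translation -> tryptic digestion.

The configuration carries every threshold with its standard default
(min_reads 10, min_samples 3, min_tpm 1.0, tpm_min_samples 3,
peptide_min_len 7, U12 donor/acceptor cutoffs 75/65, U2 cutoff 60); each is
overridable.  Translation runs on the merged RTD (not the padded variant):
padding exists to equalise ends for quantification, and extending 5' UTRs
with neighbouring genomic sequence would perturb start-codon choice.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from . import filters, io, junctions, merge, proteome, quasi
from .core import Transcriptome

logger = logging.getLogger("rtdkit")


@dataclass
class PipelineConfig:
    genome: Path
    assemblies: List[Tuple[Path, str]]  # (gtf path, label), merge order
    reference: Path
    sj_tables: List[Tuple[Path, str]]  # (path, sample_id); aligner dupes OK
    quant_paths: List[Path]
    sample_ids: List[str]
    outdir: Path
    min_reads: int = 10
    min_samples: int = 3
    min_tpm: float = 1.0
    tpm_min_samples: int = 3
    peptide_min_len: int = 7
    u12_donor_min: float = 75.0
    u12_acceptor_min: float = 65.0
    u2_min: float = 60.0
    do_pad: bool = True
    do_trim: bool = False
    do_translate: bool = True

    def __post_init__(self) -> None:
        for p in [self.genome, self.reference] + [p for p, _ in self.assemblies]:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")


@dataclass
class PipelineResult:
    rtd: Transcriptome
    quasi_tx: Optional[Transcriptome]
    passing_junctions: Set[junctions.JunctionKey]
    non_canonical_junctions: Set[junctions.JunctionKey]
    filter_reports: Dict[str, Dict[str, filters.FilterReport]]
    merge_report: pd.DataFrame
    anchors: Dict[str, Optional[proteome.GeneAnchor]]
    proteins: List[proteome.ProteinRecord]
    peptide_index: Optional[proteome.PeptideIndex]
    summary: Dict[str, object] = field(default_factory=dict)


def classify_junctions(
    pooled: Sequence[junctions.JunctionSupport],
    genome: io.GenomeAccessor,
    min_reads: int,
    min_samples: int,
) -> Tuple[Set[junctions.JunctionKey], Set[junctions.JunctionKey]]:
    """(passing, supported-but-non-canonical) junction key sets."""
    passing = junctions.passing_junction_set(pooled, genome, min_reads, min_samples)
    non_canonical: Set[junctions.JunctionKey] = set()
    for j in pooled:
        if j.key in passing or j.strand is None:
            continue
        if junctions.support_filter(j, min_reads, min_samples):
            donor2, acceptor2 = junctions.intron_motif(
                genome, j.chrom, j.start, j.end, j.strand
            )
            if junctions.classify_motif(donor2, acceptor2) == "non_canonical":
                non_canonical.add(j.key)
    return passing, non_canonical


def filter_assembly(
    tx: Transcriptome,
    reference: Transcriptome,
    passing: Set[junctions.JunctionKey],
    non_canonical: Set[junctions.JunctionKey],
    quant: pd.DataFrame,
    config: PipelineConfig,
) -> Tuple[Transcriptome, Dict[str, filters.FilterReport]]:
    """Apply the four transcript filters in order, tracking every fate."""
    reports: Dict[str, filters.FilterReport] = {}

    rep = filters.filter_by_junctions(tx, passing, non_canonical)
    reports["junctions"] = rep
    tx = rep.apply(tx)

    rep = filters.filter_antisense(tx, reference)
    reports["antisense"] = rep
    tx = rep.apply(tx)

    rep = filters.filter_unknown_genes(tx, set(reference.gene_index), reference)
    reports["unknown"] = rep
    tx = filters.apply_reassignments(rep.apply(tx), rep)

    rep = filters.filter_low_expression(tx, quant, config.min_tpm, config.tpm_min_samples)
    reports["expression"] = rep
    tx = rep.apply(tx)
    return tx, reports


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = io.read_genome(config.genome)
    reference = io.read_gtf(config.reference)

    # --- junction QC
    tables = [io.read_sj_tab(path, sample) for path, sample in config.sj_tables]
    pooled = junctions.pool_junctions(tables)
    passing, non_canonical = classify_junctions(
        pooled, genome, config.min_reads, config.min_samples
    )
    logger.info(
        "junction QC: %d pooled, %d passing, %d supported-but-non-canonical (%.1fs)",
        len(pooled), len(passing), len(non_canonical), time.time() - t0,
    )

    quant = io.read_quant(config.quant_paths, config.sample_ids)

    # --- per-assembly transcript filters
    filtered: List[Tuple[Transcriptome, str]] = []
    all_reports: Dict[str, Dict[str, filters.FilterReport]] = {}
    for path, label in config.assemblies:
        tx = io.read_gtf(path)
        kept, reports = filter_assembly(
            tx, reference, passing, non_canonical, quant, config
        )
        all_reports[label] = reports
        filtered.append((kept, label))
        frames = [
            rep.to_frame().assign(stage=stage) for stage, rep in reports.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"filter_report_{label}.tsv", sep="\t", index=False
        )

    # --- step-wise merge with redundancy removal
    rtd, merge_report = merge.run_merge_plan(merge.MergePlan(filtered))
    rtd.name = "rtd"
    io.write_gtf(rtd, outdir / "rtd.gtf")
    merge_report.to_csv(outdir / "merge_report.tsv", sep="\t", index=False)

    # --- QUASI padding (and optional trimming)
    quasi_tx = None
    if config.do_pad:
        quasi_tx, pad_log = quasi.build_quasi(rtd, genome)
        io.write_gtf(quasi_tx, outdir / "rtd_quasi.gtf")
        io.write_fasta(
            quasi.extract_sequences(quasi_tx, genome), outdir / "rtd_quasi.fa"
        )
        quasi.adjustments_frame(pad_log).to_csv(
            outdir / "pad_report.tsv", sep="\t", index=False
        )
    if config.do_trim:
        trimmed, trim_log = quasi.build_trimmed(rtd)
        io.write_gtf(trimmed, outdir / "rtd_trimmed.gtf")
        quasi.adjustments_frame(trim_log).to_csv(
            outdir / "trim_report.tsv", sep="\t", index=False
        )

    # --- translation + digestion on the (unpadded) RTD
    anchors: Dict[str, Optional[proteome.GeneAnchor]] = {}
    proteins: List[proteome.ProteinRecord] = []
    index: Optional[proteome.PeptideIndex] = None
    if config.do_translate:
        sequences = quasi.extract_sequences(rtd, genome)
        proteins, anchors = proteome.translate_transcriptome(rtd, sequences)
        io.write_fasta(
            {p.transcript_id: p.sequence for p in proteins if p.sequence},
            outdir / "rtd_proteins.fa",
        )
        index = proteome.build_peptide_index(proteins, config.peptide_min_len)
        pd.DataFrame(
            [
                {"transcript_id": p.transcript_id, "gene_id": p.gene_id,
                 "mode": p.mode, "stop_status": p.stop_status,
                 "length_aa": len(p.sequence)}
                for p in proteins
            ]
        ).to_csv(outdir / "translation_report.tsv", sep="\t", index=False)

    n_translated = sum(1 for p in proteins if p.mode != "untranslated")
    summary: Dict[str, object] = {
        "pooled_junctions": len(pooled),
        "passing_junctions": len(passing),
        "rtd_transcripts": len(rtd),
        "rtd_genes": len(rtd.gene_index),
        "translated_transcripts": n_translated,
        "anchored_transcripts": sum(1 for p in proteins if p.mode == "anchored"),
    }
    if index is not None:
        summary.update(index.summary)
    pd.Series(summary).to_json(outdir / "run_summary.json", indent=2)
    logger.info("pipeline done in %.1fs: %s", time.time() - t0, summary)
    return PipelineResult(
        rtd=rtd,
        quasi_tx=quasi_tx,
        passing_junctions=passing,
        non_canonical_junctions=non_canonical,
        filter_reports=all_reports,
        merge_report=merge_report,
        anchors=anchors,
        proteins=proteins,
        peptide_index=index,
        summary=summary,
    )


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
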