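"""Deterministic synthetic fixtures with known ground truth.

The generator emits a toy genome, a multi-isoform gene annotation, junction
support tables, per-sample quantification tables and a peak-area table, all
mutually consistent, together with the ground truth every pipeline stage
should recover:

* genes carry a fully spliced (FS) isoform with canonical GT..AG (sometimes
  GC..AG or AT..AC) introns and a designed ATG-initiated ORF;
* variant isoforms realise intron retention, alternative donor/acceptor use
  and exon skipping against the FS form; a configurable fraction of the
  variant-private junctions is made non-canonical (scrambled motif) or
  under-supported (too few samples with enough unique reads);
* assembly artifacts are planted: antisense fragments contained in a gene,
  intergenic transcripts from unknown genes, low-expression isoforms, and
  redundant UTR-length duplicates of the FS isoform;
* TPM tables are exactly consistent with the designed AS/FS ratios, and the
  peak-area table is the designed ratio times a multiplicative log-normal
  noise with configurable dispersion.

The same seed always yields byte-identical files: each file type draws from
its own pseudo-random stream spawned from the master seed, so adding a new
file type never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomicInterval, Transcriptome, TranscriptModel
from .io import reverse_complement, write_fasta, write_gtf

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 30
    n_samples: int = 6
    n_chroms: int = 2
    exon_count_range: Tuple[int, int] = (2, 5)
    exon_len_range: Tuple[int, int] = (60, 120)
    intron_len_range: Tuple[int, int] = (60, 100)
    utr5_len_range: Tuple[int, int] = (8, 16)
    utr3_len_range: Tuple[int, int] = (20, 40)
    frac_ir: float = 0.5
    frac_alt5: float = 0.35
    frac_alt3: float = 0.35
    frac_es: float = 0.35
    frac_atac_intron: float = 0.2  # genes given one AT..AC (U12-like) intron
    frac_deep_atg: float = 0.2  # ATG in exon 2 (an ES event can remove it)
    frac_straddle_atg: float = 0.15  # ATG across the first splice junction
    frac_noncanonical: float = 0.15  # of Alt-variant private junctions
    frac_unsupported: float = 0.15  # of variant private junctions
    frac_low_expression: float = 0.15  # of otherwise-clean variant isoforms
    frac_redundant: float = 0.25  # genes with a UTR-shortened FS duplicate
    n_antisense: int = 2
    n_unknown: int = 2
    n_rescued: int = 2
    min_reads: int = 10
    min_samples: int = 3
    intergenic_gap: int = 160
    peak_noise_sigma: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "frac_ir", "frac_alt5", "frac_alt3", "frac_es", "frac_atac_intron",
            "frac_noncanonical", "frac_unsupported", "frac_low_expression",
            "frac_redundant",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exon_len_range[0] < 30:
            raise ValueError("exons must be >= 30 nt (room for UTRs and motifs)")
        if self.intron_len_range[0] < 40:
            raise ValueError("introns must be >= 40 nt (room for alt splice sites)")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("need >= 1 gene and >= 1 sample")

    @property
    def sample_ids(self) -> List[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """What every pipeline stage should recover from the emitted files."""

    # (chrom, strand, start, end) -> (canonical, supported)
    junction_flags: Dict[Tuple[str, str, int, int], Tuple[bool, bool]]
    # transcript_id -> kept | unsupported_junction | non_canonical_junction |
    #   antisense_contained | unknown_gene | low_expression | removed_redundant
    transcript_fates: Dict[str, str]
    reassigned: Dict[str, str]  # rescued tid -> host gene_id
    anchors: Dict[str, Optional[int]]  # gene_id -> genomic AUG position
    events: pd.DataFrame  # event_id, gene_id, type, as_id, fs_id, surviving
    true_ratios: Dict[Tuple[str, str], float]  # (event_id, sample_id) -> AS/FS
    paths: Dict[str, object] = field(default_factory=dict)

    @property
    def final_kept(self) -> List[str]:
        return sorted(t for t, f in self.transcript_fates.items() if f == "kept")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    out: List[str] = []
    while len(out) < n:
        codon = _rand_seq(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _splice(chrom_seq: List[str], exons: Sequence[Tuple[int, int]], strand: str) -> str:
    seq = "".join("".join(chrom_seq[s:e]) for s, e in exons)
    return reverse_complement(seq) if strand == "-" else seq


def _offset_to_genomic(exons: Sequence[Tuple[int, int]], strand: str, offset: int) -> int:
    # Independent of the package's coordinate map on purpose: ground truth
    # must not inherit its bugs.
    if strand == "+":
        for s, e in exons:
            if offset < e - s:
                return s + offset
            offset -= e - s
    else:
        for s, e in reversed(exons):
            if offset < e - s:
                return e - 1 - offset
            offset -= e - s
    raise IndexError("offset beyond transcript")


def _scan_orf_len(seq: str, start: int) -> int:
    pos = start
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        pos += 3
        if codon in _STOPS:
            break
    return pos - start


def _scan_anchor(
    isoforms: Sequence[Tuple[str, Sequence[Tuple[int, int]], str, str]]
) -> Optional[int]:
    """Exhaustive all-ATG scan over a gene's isoforms -> genomic AUG position.

    ``isoforms`` rows: (transcript_id, exons, strand, mRNA).  Mirrors the
    anchor selection contract: longest ORF wins, ties to the 5'-most ATG
    within a transcript, then to the smallest transcript id.
    """
    best: Optional[Tuple[int, str, int]] = None
    for tid, exons, strand, seq in sorted(isoforms, key=lambda r: r[0]):
        for start in range(len(seq) - 2):
            if seq[start : start + 3] != "ATG":
                continue
            length = _scan_orf_len(seq, start)
            if length < 3:
                continue
            cand = (-length, tid, start)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    _, tid, start = best
    exons, strand = next((e, s) for t, e, s, _ in isoforms if t == tid)
    return _offset_to_genomic(exons, strand, start)


@dataclass
class _Isoform:
    tid: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    role: str  # fs | variant | redundant | rescued | antisense | unknown
    etype: Optional[str] = None  # IR / Alt5 / Alt3 / ES for variants
    designation: str = "ok"  # ok | noncanonical | unsupported | low_expression
    event_id: Optional[str] = None


def _write_motif(chrom_seq: List[str], pos: int, bases: str) -> None:
    chrom_seq[pos : pos + len(bases)] = list(bases)


def _place_intron_motif(
    chrom_seq: List[str], start: int, end: int, strand: str, donor2: str, acceptor2: str
) -> None:
    """Write a transcript-orientation (donor, acceptor) pair into the genome."""
    if strand == "+":
        _write_motif(chrom_seq, start, donor2)
        _write_motif(chrom_seq, end - 2, acceptor2)
    else:
        _write_motif(chrom_seq, end - 2, reverse_complement(donor2))
        _write_motif(chrom_seq, start, reverse_complement(acceptor2))


def generate(spec: FixtureSpec, outdir) -> GroundTruth:
    """Write the full fixture set into ``outdir`` and return its ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    rng_struct = np.random.default_rng(streams[0])
    rng_genome = np.random.default_rng(streams[1])
    rng_support = np.random.default_rng(streams[2])
    rng_expr = np.random.default_rng(streams[3])
    rng_peaks = np.random.default_rng(streams[4])

    chrom_seqs: Dict[str, List[str]] = {
        f"chr{i + 1}": [] for i in range(spec.n_chroms)
    }
    isoforms: List[_Isoform] = []
    gene_records: Dict[str, Dict[str, object]] = {}
    # junction key -> (canonical, support designation ok/unsupported)
    junction_meta: Dict[Tuple[str, str, int, int], Tuple[bool, str]] = {}
    events_rows: List[Dict[str, object]] = []
    unknown_placed = 0
    rescued_placed = 0
    antisense_placed = 0

    for g in range(spec.n_genes):
        chrom = f"chr{(g % spec.n_chroms) + 1}"
        seq = chrom_seqs[chrom]
        strand = "+" if rng_struct.random() < 0.5 else "-"
        gene_id = f"G{g + 1:03d}"

        gap = spec.intergenic_gap + int(rng_struct.integers(0, 50))
        gap_start = len(seq)
        seq.extend(_rand_seq(rng_genome, gap))
        if unknown_placed < spec.n_unknown and g >= 1:
            # intergenic transcript from an unknown gene, planted in the gap
            u_start = gap_start + 25
            u_end = min(u_start + 70, gap_start + gap - 25)
            if u_end - u_start >= 40:
                unknown_placed += 1
                isoforms.append(
                    _Isoform(
                        tid=f"NOVELU{unknown_placed}.1",
                        gene_id=f"NOVELU{unknown_placed}",
                        chrom=chrom,
                        strand="+",
                        exons=[(u_start, u_end)],
                        role="unknown",
                    )
                )

        n_exons = int(rng_struct.integers(*spec.exon_count_range, endpoint=True))
        exon_lens = [
            int(rng_struct.integers(*spec.exon_len_range, endpoint=True))
            for _ in range(n_exons)
        ]
        intron_lens = [
            int(rng_struct.integers(*spec.intron_len_range, endpoint=True))
            for _ in range(n_exons - 1)
        ]
        exons: List[Tuple[int, int]] = []
        cursor = len(seq)
        gene_start = cursor
        for k, el in enumerate(exon_lens):
            exons.append((cursor, cursor + el))
            cursor += el
            if k < n_exons - 1:
                cursor += intron_lens[k]
        seq.extend(_rand_seq(rng_genome, cursor - gene_start))
        introns = [(exons[k][1], exons[k + 1][0]) for k in range(n_exons - 1)]

        # designed mRNA: pyrimidine 5'UTR (no A, hence no upstream ATG),
        # ATG + stop-free codons + stop codon, random 3'UTR
        total = sum(exon_lens)
        utr5 = int(rng_struct.integers(*spec.utr5_len_range, endpoint=True))
        # occasionally place the start codon deeper so AS events can remove
        # or split it, exercising fallback translation downstream
        mode_u = rng_struct.random()
        if n_exons >= 3:
            deep = exon_lens[0] + int(rng_struct.integers(4, 11))
            straddle = exon_lens[0] - int(rng_struct.integers(1, 3))
            budget = total - spec.utr3_len_range[1] - 2
            if mode_u < spec.frac_deep_atg and budget - deep >= 45:
                utr5 = deep
            elif (mode_u < spec.frac_deep_atg + spec.frac_straddle_atg
                  and budget - straddle >= 45):
                utr5 = straddle
        utr3 = int(rng_struct.integers(*spec.utr3_len_range, endpoint=True))
        utr3 += (total - utr5 - utr3) % 3
        coding = total - utr5 - utr3
        mrna = (
            "".join("CT"[i] for i in rng_genome.integers(0, 2, utr5))
            + "ATG"
            + _rand_codons(rng_genome, coding // 3 - 2)
            + _STOPS[rng_genome.integers(0, 3)]
            + _rand_seq(rng_genome, utr3)
        )
        genomic_mrna = mrna if strand == "+" else reverse_complement(mrna)
        pos = 0
        for s, e in exons:
            seq[s:e] = list(genomic_mrna[pos : pos + (e - s)])
            pos += e - s

        # intron motifs (transcript orientation), one optional AT..AC intron
        motifs: List[Tuple[str, str]] = []
        atac_idx = -1
        if introns and rng_struct.random() < spec.frac_atac_intron:
            atac_idx = int(rng_struct.integers(0, len(introns)))
        for k, (s, e) in enumerate(introns):
            if k == atac_idx:
                pair = ("AT", "AC")
            else:
                pair = ("GC", "AG") if rng_struct.random() < 0.15 else ("GT", "AG")
            motifs.append(pair)
            _place_intron_motif(seq, s, e, strand, *pair)
            junction_meta[(chrom, strand, s, e)] = (True, "ok")

        fs_tid = f"{gene_id}.1"
        isoforms.append(_Isoform(fs_tid, gene_id, chrom, strand, list(exons), "fs"))
        gene_records[gene_id] = {"chrom": chrom, "strand": strand, "fs": fs_tid,
                                 "exons": exons, "introns": introns}

        # ---- variant isoforms against the FS form
        next_iso = 2
        n_events = 0

        def add_variant(etype: str, var_exons: List[Tuple[int, int]],
                        designation: str) -> _Isoform:
            nonlocal next_iso, n_events
            tid = f"{gene_id}.{next_iso}"
            next_iso += 1
            n_events += 1
            ev = f"{gene_id}:{etype}:{n_events}"
            iso = _Isoform(tid, gene_id, chrom, strand, var_exons, "variant",
                           etype=etype, designation=designation, event_id=ev)
            isoforms.append(iso)
            events_rows.append({"event_id": ev, "gene_id": gene_id, "type": etype,
                                "as_id": tid, "fs_id": fs_tid})
            return iso

        if introns and rng_struct.random() < spec.frac_ir:
            j = int(rng_struct.integers(0, len(introns)))
            var = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2:]
            # IR adds no private junction, so only expression can spoil it
            d = ("low_expression"
                 if rng_struct.random() < spec.frac_low_expression else "ok")
            add_variant("IR", var, d)

        if n_exons >= 3 and rng_struct.random() < spec.frac_es:
            candidates = [
                k for k in range(1, n_exons - 1)
                if (strand == "+" and (motifs[k - 1][0], motifs[k][1]) in
                    {("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
                or (strand == "-" and (motifs[k][0], motifs[k - 1][1]) in
                    {("GT", "AG"), ("GC", "AG"), ("AT", "AC")})
            ]
            if candidates:
                k = candidates[int(rng_struct.integers(0, len(candidates)))]
                var = exons[:k] + exons[k + 1:]
                private = (introns[k - 1][0], introns[k][1])
                # the skip junction reuses canonical FS motifs, so it can be
                # under-supported or low-expressed but never non-canonical
                if rng_struct.random() < spec.frac_unsupported:
                    d = "unsupported"
                elif rng_struct.random() < spec.frac_low_expression:
                    d = "low_expression"
                else:
                    d = "ok"
                add_variant("ES", var, d)
                supported = "unsupported" if d == "unsupported" else "ok"
                junction_meta[(chrom, strand, *private)] = (True, supported)

        for etype, frac in (("Alt5", spec.frac_alt5), ("Alt3", spec.frac_alt3)):
            if not introns or rng_struct.random() >= frac:
                continue
            usable = [k for k in range(len(introns))
                      if k != atac_idx and introns[k][1] - introns[k][0] >= 40]
            if not usable:
                continue
            j = usable[int(rng_struct.integers(0, len(usable)))]
            s, e = introns[j]
            d_shift = int(rng_struct.integers(6, min(16, e - s - 20)))
            u = rng_struct.random()
            if u < spec.frac_noncanonical:
                designation = "noncanonical"
            elif u < spec.frac_noncanonical + spec.frac_unsupported:
                designation = "unsupported"
            elif rng_struct.random() < spec.frac_low_expression:
                designation = "low_expression"
            else:
                designation = "ok"
            # genomic operation realising the transcript-level event type
            shift_start = (etype == "Alt5") == (strand == "+")
            var = [list(x) for x in exons]
            if shift_start:
                new_intron = (s + d_shift, e)
                var[j][1] = s + d_shift  # left exon extends into the intron
                motif_pos, side = s + d_shift, "donor" if strand == "+" else "acceptor"
            else:
                new_intron = (s, e - d_shift)
                var[j + 1][0] = e - d_shift
                motif_pos, side = e - d_shift - 2, "acceptor" if strand == "+" else "donor"
            if designation == "noncanonical":
                written = "CC"
            elif side == "donor":
                written = "GT" if rng_struct.random() < 0.8 else "GC"
            else:
                written = "AG"
            # `written` is the transcript-orientation dinucleotide; the genome
            # stores its reverse complement on the minus strand
            _write_motif(
                seq, motif_pos,
                written if strand == "+" else reverse_complement(written),
            )
            canonical = designation != "noncanonical"
            supported = "unsupported" if designation == "unsupported" else "ok"
            junction_meta[(chrom, strand, *new_intron)] = (canonical, supported)
            add_variant(etype, [tuple(x) for x in var], designation)

        # ---- redundant FS duplicate with shorter UTR extents
        if rng_struct.random() < spec.frac_redundant:
            k = int(rng_struct.integers(5, 16))
            dup = [list(x) for x in exons]
            dup[0][0] += k
            dup[-1][1] -= k
            isoforms.append(
                _Isoform(f"{gene_id}.{next_iso}", gene_id, chrom, strand,
                         [tuple(x) for x in dup], "redundant")
            )
            next_iso += 1

        # ---- planted artifacts
        if rescued_placed < spec.n_rescued and g % 3 == 0:
            rescued_placed += 1
            first = exons[-1] if strand == "-" else exons[0]
            frag = (first[0] + 5, first[1] - 5)
            isoforms.append(
                _Isoform(f"NOVELG{rescued_placed}.1", f"NOVELG{rescued_placed}",
                         chrom, strand, [frag], "rescued")
            )
        if antisense_placed < spec.n_antisense and g % 3 == 1:
            antisense_placed += 1
            span = (gene_start + 10, min(gene_start + 90, cursor - 5))
            isoforms.append(
                _Isoform(f"NOVELAS{antisense_placed}.1", f"NOVELAS{antisense_placed}",
                         chrom, "-" if strand == "+" else "+",
                         [span], "antisense")
            )

    for chrom in chrom_seqs:
        chrom_seqs[chrom].extend(_rand_seq(rng_genome, spec.intergenic_gap))

    # ------------------------------------------------------------------
    # fates
    fates: Dict[str, str] = {}
    reassigned: Dict[str, str] = {}
    for iso in isoforms:
        if iso.role == "antisense":
            fates[iso.tid] = "antisense_contained"
        elif iso.role == "unknown":
            fates[iso.tid] = "unknown_gene"
        elif iso.role == "redundant":
            fates[iso.tid] = "removed_redundant"
        elif iso.designation == "noncanonical":
            fates[iso.tid] = "non_canonical_junction"
        elif iso.designation == "unsupported":
            fates[iso.tid] = "unsupported_junction"
        elif iso.designation == "low_expression":
            fates[iso.tid] = "low_expression"
        else:
            fates[iso.tid] = "kept"
            if iso.role == "rescued":
                host = next(
                    i.gene_id for i in isoforms
                    if i.role == "fs" and i.chrom == iso.chrom
                    and i.strand == iso.strand
                    and i.exons[0][0] <= iso.exons[0][0]
                    and iso.exons[-1][1] <= i.exons[-1][1]
                )
                reassigned[iso.tid] = host

    # ------------------------------------------------------------------
    # transcriptomes (assembly = everything; reference = FS isoforms only)
    assembly = Transcriptome("assembly")
    reference = Transcriptome("reference")
    for iso in sorted(isoforms, key=lambda i: i.tid):
        model = TranscriptModel(
            iso.tid, iso.gene_id,
            [GenomicInterval(iso.chrom, s, e, iso.strand) for s, e in iso.exons],
        )
        assembly.add(model)
        if iso.role == "fs":
            reference.add(
                TranscriptModel(
                    iso.tid, iso.gene_id,
                    [GenomicInterval(iso.chrom, s, e, iso.strand) for s, e in iso.exons],
                )
            )

    # ------------------------------------------------------------------
    # junction support tables (two aligner dialect tables per sample)
    samples = spec.sample_ids
    counts: Dict[Tuple[str, str, int, int], List[int]] = {}
    for key in sorted(junction_meta):
        _, supported = junction_meta[key]
        if supported == "ok":
            counts[key] = [int(rng_support.integers(spec.min_reads + 5, 61))
                          for _ in samples]
        else:
            qualifying = sorted(
                rng_support.choice(len(samples), size=spec.min_samples - 1,
                                   replace=False).tolist()
            )
            counts[key] = [
                int(rng_support.integers(spec.min_reads + 5, 41))
                if i in qualifying
                else int(rng_support.integers(0, spec.min_reads))
                for i in range(len(samples))
            ]

    sj_paths: Dict[str, List[Path]] = {"star": [], "tophat": []}
    strand_code = {"+": 1, "-": 2}
    for si, sample in enumerate(samples):
        for aligner, scale in (("star", 1.0), ("tophat", 0.8)):
            path = outdir / f"sj_{aligner}_{sample}.tab"
            with open(path, "w") as fh:
                for key in sorted(counts, key=lambda k: (k[0], k[2], k[3], k[1])):
                    chrom, strand, s, e = key
                    n = int(counts[key][si] * scale)
                    if n == 0:
                        continue
                    fh.write(
                        f"{chrom}\t{s + 1}\t{e}\t{strand_code[strand]}\t1\t0"
                        f"\t{n}\t{int(rng_support.integers(0, 4))}\t20\n"
                    )
            sj_paths[aligner].append(path)

    # ------------------------------------------------------------------
    # abundances exactly consistent with the designed AS/FS ratios
    true_ratios: Dict[Tuple[str, str], float] = {}
    surviving_events = set()
    base_abund: Dict[str, np.ndarray] = {}
    fs_abund: Dict[str, np.ndarray] = {}
    for gene_id in sorted(gene_records):
        fs_abund[gene_id] = rng_expr.uniform(20, 100, spec.n_samples)
    for iso in sorted(isoforms, key=lambda i: i.tid):
        if iso.role == "fs":
            base_abund[iso.tid] = fs_abund[iso.gene_id]
        elif iso.role == "variant":
            r0 = rng_expr.uniform(0.15, 0.85)
            mult = rng_expr.uniform(0.6, 1.4, spec.n_samples)
            ratios = r0 * mult
            base_abund[iso.tid] = ratios * fs_abund[iso.gene_id]
            if iso.designation == "ok":
                surviving_events.add(iso.event_id)
                for si, sample in enumerate(samples):
                    true_ratios[(iso.event_id, sample)] = float(ratios[si])
        elif iso.role == "redundant":
            base_abund[iso.tid] = 0.5 * fs_abund[iso.gene_id]
        else:
            base_abund[iso.tid] = rng_expr.uniform(10, 50, spec.n_samples)

    low_tids = sorted(
        iso.tid for iso in isoforms if iso.designation == "low_expression"
    )
    # target TPMs for low-expression isoforms: above 1 in exactly
    # (min_samples - 1) samples, well below 1 elsewhere
    low_targets: Dict[str, np.ndarray] = {}
    for tid in low_tids:
        high = sorted(
            rng_expr.choice(spec.n_samples, size=spec.min_samples - 1,
                            replace=False).tolist()
        )
        low_targets[tid] = np.array(
            [1.8 if i in high else 0.3 for i in range(spec.n_samples)]
        )

    tids = sorted(base_abund)
    abund = pd.DataFrame(
        {s: [base_abund[t][i] for t in tids] for i, s in enumerate(samples)},
        index=tids,
    )
    for si, sample in enumerate(samples):
        fixed = abund.loc[[t for t in tids if t not in low_tids], sample].sum()
        t_sum = sum(low_targets[t][si] for t in low_tids)
        s_total = fixed / (1.0 - t_sum / 1e6)
        for t in low_tids:
            abund.loc[t, sample] = low_targets[t][si] * s_total / 1e6
    tpm = abund / abund.sum(axis=0) * 1e6

    lengths = pd.Series(
        {t.transcript_id: t.exonic_length for t in assembly}, name="Length"
    )
    quant_paths = []
    for sample in samples:
        path = outdir / f"quant_{sample}.sf"
        df = pd.DataFrame(
            {
                "Name": tpm.index,
                "Length": lengths.reindex(tpm.index).values,
                "EffectiveLength": lengths.reindex(tpm.index).astype(float).values,
                "TPM": tpm[sample].values,
                "NumReads": (tpm[sample] * 10).values,
            }
        )
        df.to_csv(path, sep="\t", index=False)
        quant_paths.append(path)

    # ------------------------------------------------------------------
    # peak areas for surviving events: designed ratio x FS area x noise
    peak_rows = []
    for ev in sorted(surviving_events):
        for sample in samples:
            gene_id = ev.split(":")[0]
            fs_area = float(rng_peaks.uniform(2000, 8000))
            noise = float(np.exp(rng_peaks.normal(0.0, spec.peak_noise_sigma)))
            peak_rows.append(
                {"gene_id": gene_id, "event_id": ev, "product_label": "FS",
                 "sample_id": sample, "peak_area": fs_area}
            )
            peak_rows.append(
                {"gene_id": gene_id, "event_id": ev, "product_label": "AS_1",
                 "sample_id": sample,
                 "peak_area": true_ratios[(ev, sample)] * fs_area * noise}
            )
    peaks = pd.DataFrame(
        peak_rows,
        columns=["gene_id", "event_id", "product_label", "sample_id", "peak_area"],
    )
    peaks_path = outdir / "peak_areas.tsv"
    peaks.to_csv(peaks_path, sep="\t", index=False)

    # ------------------------------------------------------------------
    # anchors over the final kept isoforms of each gene
    kept = {t for t, f in fates.items() if f == "kept"}
    anchors: Dict[str, Optional[int]] = {}
    for gene_id in sorted(gene_records):
        rows = []
        for iso in isoforms:
            effective_gene = reassigned.get(iso.tid, iso.gene_id)
            if effective_gene != gene_id or iso.tid not in kept:
                continue
            mrna = _splice(chrom_seqs[iso.chrom], iso.exons, iso.strand)
            rows.append((iso.tid, iso.exons, iso.strand, mrna))
        anchors[gene_id] = _scan_anchor(rows)

    # ------------------------------------------------------------------
    # files: genome + annotations + ground truth tables
    genome_path = outdir / "genome.fa"
    write_fasta({c: "".join(s) for c, s in sorted(chrom_seqs.items())}, genome_path)
    assembly_path = outdir / "assembly.gtf"
    reference_path = outdir / "reference.gtf"
    write_gtf(assembly, assembly_path)
    write_gtf(reference, reference_path)

    events_df = pd.DataFrame(
        events_rows, columns=["event_id", "gene_id", "type", "as_id", "fs_id"]
    )
    if len(events_df):
        events_df["surviving"] = events_df["event_id"].isin(surviving_events)
    else:
        events_df["surviving"] = pd.Series(dtype=bool)

    truth = GroundTruth(
        junction_flags={
            k: (canonical, supported == "ok")
            for k, (canonical, supported) in junction_meta.items()
        },
        transcript_fates=fates,
        reassigned=reassigned,
        anchors=anchors,
        events=events_df,
        true_ratios=true_ratios,
        paths={
            "genome": genome_path,
            "assembly": assembly_path,
            "reference": reference_path,
            "sj": sj_paths,
            "quant": quant_paths,
            "samples": samples,
            "peaks": peaks_path,
        },
    )
    _write_truth_tables(truth, outdir)
    return truth


def _write_truth_tables(truth: GroundTruth, outdir: Path) -> None:
    pd.DataFrame(
        [
            {"chrom": c, "strand": s, "start": a, "end": b,
             "canonical": can, "supported": sup}
            for (c, s, a, b), (can, sup) in sorted(truth.junction_flags.items())
        ]
    ).to_csv(outdir / "truth_junctions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"transcript_id": t, "fate": f,
             "reassigned_to": truth.reassigned.get(t, "")}
            for t, f in sorted(truth.transcript_fates.items())
        ]
    ).to_csv(outdir / "truth_fates.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": g, "anchor_position": -1 if p is None else p}
            for g, p in sorted(truth.anchors.items())
        ]
    ).to_csv(outdir / "truth_anchors.tsv", sep="\t", index=False)
    truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"event_id": e, "sample_id": s, "ratio": r}
            for (e, s), r in sorted(truth.true_ratios.items())
        ]
    ).to_csv(outdir / "truth_ratios.tsv", sep="\t", index=False)
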