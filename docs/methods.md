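# Methods

## Overview

`rtdkit` implements the construction and analysis machinery for a
**reference transcript dataset (RTD)**: a non-redundant set of transcript
models assembled from short-read data, quality-filtered at the splice
junction and transcript level, and post-processed for isoform
quantification (QUASI padding), protein prediction (gene-fixed AUG
translation) and proteogenomics (tryptic peptide database).  All
coordinates are 0-based half-open internally; GTF input/output converts to
and from the 1-based inclusive convention at the file boundary.  Minus-strand
transcripts store exons in genomic order and strand is interpreted at the
point of use.

## Junction quality control

Splice junctions from one or more aligner tables (9-column `SJ.out.tab`
dialect) are pooled per distinct `(chrom, strand, start, end)` intron.
When two tables report the same junction for the same sample — two
aligners mapping one library — the per-sample unique-read count is the
**maximum**, not the sum: the same reads mapped twice are not independent
evidence.  A junction passes when

* its intron-terminal dinucleotides (read 5'→3' in transcript
  orientation) are canonical — `GT..AG`, `GC..AG` or `AT..AC` — and
* at least `min_samples` samples (default **3**) each contribute at least
  `min_reads` unique reads (default **10**).

Junctions whose strand the aligner could not determine are retained in the
pool but can never be canonical (the motif test needs an orientation), so
they never pass.  Passing is monotone in both thresholds.

## Splice-site scoring (U2/U12)

Each intron exposes two 13-nt windows: the donor window (3 exonic + 10
intronic nt) and the acceptor window (10 intronic + 3 exonic nt), both in
transcript orientation.  Windows are scored against position weight
matrices trained from aligned splice-site sets with a pseudocount (default
0.5) so all entries are positive.  The raw score of a window is the
log-odds sum `Σ_i log2(P[i, b_i] / 0.25)`; it is min-max scaled to 0–100
using the column-wise minimum and maximum attainable sums, so the matrix
consensus scores exactly 100 and the anti-consensus exactly 0.  This
bounded scaling is this package's own convention, chosen because the
classification cutoffs below live on a percentage-like scale; absolute
scores are therefore comparable only within one matrix set.

An intron is called **U12** only if its donor scores above 75 *and* its
acceptor above 65 in the U12 matrices; otherwise it is **U2** if both
sites score above 60 in the U2 matrices; otherwise unclassified.  U12
takes precedence because it is the restrictive special case.  All cutoffs
are strict inequalities.

## Transcript filters

Applied in order, each producing a kept/removed report with reasons:

1. **Junction support** — a multi-exon transcript is kept iff *every*
   intron is in the passing junction set; mono-exonic transcripts pass
   vacuously.
2. **Antisense containment** — removed iff the transcript's genomic span is
   completely contained, on the opposite strand, within a reference gene's
   span (min exon start to max exon end over the gene's transcripts).
3. **Unknown genes** — a transcript whose gene id is not in the reference
   is rescued if it has ≥ 1 bp of same-strand *exonic* overlap with a
   known gene (it is re-assigned to that gene); otherwise it is removed.
   Overlap with the gene's introns alone does not rescue.
4. **Low expression** — kept iff TPM is strictly greater than 1.0 in at
   least 3 samples (both overridable).  Transcripts absent from the
   quantification table count as all-zero and are removed with a warning.

## Redundancy removal and merging

Two multi-exon transcripts of one gene are redundant iff their **intron
chains** (ordered intron coordinate lists on one chrom/strand) are
identical — they are the same splicing structure with different UTR
extents.  The retained representative is the transcript covering the
longest genomic span (maximal UTR extent preserves the most sequence for
quantification); exact ties fall to the lexicographically smallest id.
Mono-exonic transcripts are redundant only when their spans are exactly
identical; containment-based fragment collapsing is deliberately not
applied, since it risks deleting genuine short genes.

Merging is a left fold over an ordered list of transcriptomes.  At each
step, incoming gene ids are reconciled to the base by same-strand exon
overlap (a transcript overlapping exactly one base gene adopts its id; one
overlapping several keeps its id and is flagged), the union is taken, and
redundancy is removed with base representatives preferred unless the
incoming transcript covers a strictly longer span.  The output chain set
equals the union of the input chain sets, and merging is idempotent on
chain sets.

## QUASI padding and trimming

Per gene, **padding** extends every transcript to `[min start, max end)`
over the gene's transcripts by growing the first exon's start and last
exon's end with cognate genomic sequence.  No new exons or junctions are
created; an extension running through another isoform's terminal intron
produces an intron-retention-like end, which is the intended behaviour for
quantification.  The padded transcriptome (the QUASI variant) has uniform
per-gene spans, every padded sequence contains the original as a
contiguous substring, and padding is idempotent.

**Trimming** clips every transcript to `[max start, min end)`.  Exons are
intersected with the window; when a trim boundary falls inside an intron
the transcript restarts at the next complete exon edge inside the window
(no partial introns survive).  An empty window (no shared region) skips
the gene with a warning.  Trimmed sequences are substrings of the
originals, and pad∘trim is the identity on single-isoform genes.

## Translation and peptide database

For each gene, the **anchor AUG** is found by scanning every ATG of every
transcript and taking the start of the longest ORF (ATG through the first
in-frame stop, or to the last complete codon when none occurs); ties go to
the 5'-most ATG within the winning transcript, then to the smallest
transcript id.  The anchor is stored as the genomic coordinates of its
three bases, so the "same AUG" test is splice-aware: a transcript is
translated from the anchor only when all three bases are exonic in it,
consecutive in its mRNA, and still read ATG.  Transcripts failing this —
typically because an AS event removed or split the anchor exon, or the
transcript starts downstream — fall back to their own longest ORF.
Transcripts with no ATG at all are reported untranslated.  Only the
standard genetic code is used; ORFs without an in-frame stop are flagged
`ran_off_end` rather than discarded.

Proteins are digested with standard trypsin rules: cleavage after every K
or R except when followed by P, no missed cleavages; fragments shorter
than 7 residues are discarded.  Non-standard residues are retained and
never act as cleavage sites.  Peptides are indexed globally; a peptide is
*unique* when it maps to exactly one transcript isoform.  Applying the
length filter before or after global deduplication does not change
uniqueness; it is applied per protein for determinism.

## AS events and splicing ratios

The pairwise event classifier compares two isoforms of one gene inside
their shared genomic window and labels local intron-chain differences:
intron retention (IR; the retaining isoform is the AS form), alternative
donor (Alt5) and acceptor (Alt3) — judged strand-aware, with the
shorter-intron isoform as the AS form — and exon skipping (ES; the
skipping isoform is the AS form).  Anything else is reported as
unclassified.  The full event algebra of combinatorial classifiers is out
of scope.

A splicing ratio is AS/FS: the summed abundance of the event's AS
transcript set over that of its fully spliced (FS) set, computed from TPMs
or from electrophoretic peak areas.  The FS set is **structural** — fixed
when the event is constructed — never chosen by abundance.  Ratios are
scale-invariant within a sample; a zero FS denominator yields a flagged
undefined record that is excluded pairwise from correlations.  Concordance
between RNA-seq and experimental ratios pools all events × samples into
one vector pair and reports Pearson r and Spearman rho (average ranks for
ties; at least 3 usable pairs required).

## Synthetic data generator

The generator emits a toy genome, annotation, junction tables, TPM tables
and a peak-area table whose ground truth is known by construction.  Genes
(default 30 for unit work; 200 × 8 samples in the acceptance suite; 150 in
the acceptance script) carry 2–5 exons of 60–120 nt and introns of 60–100
nt with embedded canonical motifs (mostly `GT..AG`, occasionally `GC..AG`,
and one `AT..AC` intron in ~20% of genes).  Each gene's fully spliced
isoform encodes a designed ORF: a pyrimidine-only 5' UTR (so no upstream
ATG), ATG, stop-free codons, a stop, and a random 3' UTR.  In a fraction
of genes the ATG is placed in exon 2 or across the first junction so that
exon skipping or intron retention removes/splits it and the fallback
translation path is exercised end to end.

Variant isoforms realise IR, Alt5, Alt3 and ES against the FS form (each
drawn per gene with probability ~0.35–0.5).  Variant-private junctions are
made non-canonical (scrambled motif, 15%) or under-supported (enough reads
in only 2 samples, 15%); otherwise variants may be designated
low-expression (15%), in which case their abundances are solved exactly so
that TPM exceeds 1 in exactly 2 samples.  Additional planted objects:
UTR-shortened duplicates of the FS isoform (redundancy victims, 25% of
genes), antisense fragments contained in a gene span, intergenic
unknown-gene transcripts, and novel-id transcripts that should be rescued
by exonic overlap.  TPM tables are exactly consistent with the designed
AS/FS ratios (abundances are normalised within samples, and ratios cancel
the normalisation); peak areas are the designed ratio × FS area × a
log-normal factor with σ = 0.15, which yields pooled concordance around
r ≈ 0.93–0.95 at the default scale.

Each file type draws from its own stream spawned from the master seed, so
outputs are byte-identical across runs and adding a file type never
perturbs the others.  The ground-truth anchor per gene is computed by a
generator-local exhaustive ATG scan that is coded independently of the
package's ORF machinery.

What the generator does **not** emulate: realistic base composition,
read-level noise, degradation fragments, overlapping or nested genes,
alternative TSS/poly(A) sites, branch points, and U12-realistic splice-site
window content beyond the terminal dinucleotides.  Passing tests therefore
demonstrate algorithmic correctness on well-formed inputs, not performance
on real libraries.

## Numerical and edge-case choices

* PWM scoring of a window containing `N` returns NaN (never satisfies a
  classification cutoff); a degenerate all-uniform matrix scores every
  window 100.
* TPM thresholds are strict (`> 1`), sample counts are of distinct
  samples.
* The pipeline translates the merged (unpadded) RTD: padding exists for
  quantification, and extending 5' UTRs with neighbouring genomic sequence
  could introduce spurious upstream AUGs.
* Padding does not cap extensions near neighbouring genes.
* Empty trim windows and transcripts emptied by trimming are dropped with
  warnings, not errors.
* Merge-time gene-id conflicts (one transcript overlapping two base
  genes) keep the transcript and flag it in the step report.

## Known limitations

* Scores from the 0–100 min-max scaling are matrix-set-relative; they are
  not comparable to scores from other scaling conventions.
* The pairwise event classifier does not compose events (e.g. a combined
  ES+Alt3 difference yields separate or unclassified calls) and does not
  call exitron-style intra-exonic events.
* Gene assignment by 1-bp exonic overlap is intentionally simple; loci
  with genuinely overlapping genes on one strand may be over-merged.
* Premature-termination-codon/NMD classification is not implemented.
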