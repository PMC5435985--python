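"""Shared test helpers: quick model builders and independent oracles."""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

from rtdkit.core import GenomicInterval, TranscriptModel


def make_tx(
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    tid: str = "t1",
    gene: str = "g1",
) -> TranscriptModel:
    return TranscriptModel(
        tid, gene, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )


# --- independent oracles (deliberately naive implementations) -------------

STOPS = ("TAA", "TAG", "TGA")


def brute_force_orf_scan(seq: str) -> Optional[Tuple[int, int]]:
    """All-ATG scan: (start, orf_len_nt) of the longest ORF, 5'-most on ties."""
    best = None
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            j += 3
            if seq[j - 3 : j] in STOPS:
                break
        length = j - i
        if length >= 3 and (best is None or length > best[1]):
            best = (i, length)
    return best


def brute_force_score(seq: str, matrix) -> float:
    """Independent log-odds + min-max scaling of a 13-mer PWM score."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    raw = 0.0
    lo = 0.0
    hi = 0.0
    for pos in range(13):
        col = [math.log2(matrix[pos][b] / 0.25) for b in range(4)]
        raw += col[idx[seq[pos]]]
        lo += min(col)
        hi += max(col)
    return 100.0 * (raw - lo) / (hi - lo)


def brute_force_support(counts: Dict[str, int], min_reads: int, min_samples: int) -> bool:
    n = 0
    for sample in counts:
        if counts[sample] >= min_reads:
            n += 1
    return n >= min_samples
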