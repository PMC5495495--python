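"""Reads-level QC: per-position quality, base composition and GC content.

Summaries are computed directly from FASTQ; Phred scores default to the
+33 encoding.  GC% is binned to the integers 0..100, with ambiguous bases
(N) excluded from both the numerator and the denominator.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: default cap on the number of reads summarized (speed; configurable)
DEFAULT_MAX_READS = 1_000_000

_BASES = ("A", "C", "G", "T", "N")


@dataclass
class ReadsQCSummary:
    """Per-position quality/composition plus the per-read GC histogram."""

    per_position_mean_quality: np.ndarray  # Phred units, length = max read length
    per_position_base_fraction: pd.DataFrame  # index position, columns A/C/G/T/N
    gc_histogram: np.ndarray  # 101 integer-percent bins
    n_reads: int

    def quality_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.per_position_mean_quality)),
                "mean_quality": self.per_position_mean_quality,
            }
        )

    def gc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gc_percent": np.arange(101), "n_reads": self.gc_histogram}
        )


def reads_level_qc(
    fastq_path: str | Path,
    max_reads: int | None = DEFAULT_MAX_READS,
    phred_offset: int = 33,
) -> ReadsQCSummary:
    """Summarize sequence quality, nucleotide composition and GC of reads.

    Reads are taken in file order up to *max_reads* (``None`` = all); the
    summary itself is invariant to read order.  Raises on a record whose
    quality string length differs from its sequence length.
    """
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open

    qual_sum: list[float] = []
    base_counts: list[dict[str, int]] = []
    coverage: list[int] = []
    gc_hist = np.zeros(101, dtype=np.int64)
    n_reads = 0

    with opener(path, "rt") as fh:
        records = FastqGeneralIterator(fh)
        idx = -1
        while True:
            idx += 1
            try:
                _, seq, qual = next(records)
            except StopIteration:
                break
            except ValueError as exc:  # malformed record (e.g. seq/qual length)
                raise ValueError(f"{path}: record {idx}: {exc}") from exc
            if max_reads is not None and n_reads >= max_reads:
                break
            seq = seq.upper()
            L = len(seq)
            while len(qual_sum) < L:
                qual_sum.append(0.0)
                coverage.append(0)
                base_counts.append({b: 0 for b in _BASES})
            for pos in range(L):
                qual_sum[pos] += ord(qual[pos]) - phred_offset
                coverage[pos] += 1
                base_counts[pos][seq[pos] if seq[pos] in _BASES else "N"] += 1
            gc = seq.count("G") + seq.count("C")
            at = seq.count("A") + seq.count("T")
            denom = gc + at
            pct = int(round(100.0 * gc / denom)) if denom else 0
            gc_hist[pct] += 1
            n_reads += 1

    if n_reads == 0:
        return ReadsQCSummary(
            np.zeros(0), pd.DataFrame(columns=list(_BASES)), gc_hist, 0
        )

    cov = np.asarray(coverage, dtype=float)
    mean_q = np.asarray(qual_sum) / cov
    frac = pd.DataFrame(base_counts, columns=list(_BASES)).to_numpy(dtype=float)
    frac /= cov[:, None]
    frac_df = pd.DataFrame(frac, columns=list(_BASES))
    frac_df.index.name = "position"
    return ReadsQCSummary(mean_q, frac_df, gc_hist, n_reads)
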