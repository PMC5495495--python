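"""Individual-cell level QC.

A "single cell" is a unique barcode.  The per-cell peak number — the
count of distinct combined peaks occupied by that cell's reads — is the
cell's information-content metric; occupancy means at least one
fragment sharing at least one base with the peak (half-open intervals).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from ._intervals import PeakIndex
from .sc_io import BarcodedFragment, PeakSet


@dataclass
class CellStats:
    """Per-barcode read and peak-occupancy counts."""

    stats: dict[str, dict[str, int]] = field(default_factory=dict)

    def __getitem__(self, barcode: str) -> dict[str, int]:
        return self.stats[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.stats

    def __len__(self) -> int:
        return len(self.stats)

    def barcodes(self) -> list[str]:
        return sorted(self.stats)

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.stats, orient="index").sort_index()
        df.index.name = "barcode"
        return df


def reads_per_cell(fragments: Iterable[BarcodedFragment]) -> dict[str, int]:
    """Number of reads assigned to each barcode; counts sum to the input size."""
    return dict(Counter(f.barcode for f in fragments))


def peaks_per_cell(
    fragments: Iterable[BarcodedFragment],
    peaks: PeakSet,
    min_fragments_per_peak: int = 1,
) -> CellStats:
    """Per-cell in-peak read counts and distinct occupied-peak counts.

    A peak is occupied by a cell iff at least ``min_fragments_per_peak``
    of the cell's fragments overlap it (default 1 — the minimal reading
    of occupancy).
    """
    if len(peaks) == 0:
        raise ValueError("peaks_per_cell requires a non-empty peak set")
    index = PeakIndex(peaks)
    n_reads: Counter[str] = Counter()
    in_peak: Counter[str] = Counter()
    per_peak: dict[str, Counter[int]] = {}
    for f in fragments:
        n_reads[f.barcode] += 1
        hits = index.overlapping(f.chrom, f.start, f.end)
        if hits:
            in_peak[f.barcode] += 1
            counter = per_peak.setdefault(f.barcode, Counter())
            for j in hits:
                counter[j] += 1
    stats = {
        bc: {
            "n_reads": n_reads[bc],
            "n_reads_in_peaks": in_peak.get(bc, 0),
            "n_peaks_covered": sum(
                1
                for c in per_peak.get(bc, Counter()).values()
                if c >= min_fragments_per_peak
            ),
        }
        for bc in n_reads
    }
    return CellStats(stats)


def filter_informative_cells(
    stats: CellStats, min_reads: int = 0, min_peaks: int = 0
) -> set[str]:
    """Barcodes meeting both thresholds; the defaults retain every cell.

    This gate is optional — the pipeline's only hard filter is the
    cluster-level minimum-size rule.
    """
    if min_reads < 0 or min_peaks < 0:
        raise ValueError("cell-filter thresholds must be non-negative")
    return {
        bc
        for bc, s in stats.stats.items()
        if s["n_reads"] >= min_reads and s["n_peaks_covered"] >= min_peaks
    }
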