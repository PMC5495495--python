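"""The combined-peaks axis: a pileup-threshold caller and peak annotation.

"Combined peaks" are called from all cells' fragments pooled as a
pseudo-bulk sample; they define the coordinate axis for every per-cell
statistic downstream.  The caller is a transparent pileup-threshold
procedure: maximal intervals whose per-bp fragment depth reaches
``min_pileup``, with sub-threshold gaps up to ``merge_gap`` closed and
intervals narrower than ``min_width`` dropped.  An externally called
peak BED (read via :func:`scepiqc.sc_io.read_peaks`) can be used
instead wherever a PeakSet is accepted.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .sc_io import BarcodedFragment, GeneModel, GenomeTable, Peak, PeakSet

FEATURE_LABELS = ("promoter", "exon", "intron", "downstream", "distal intergenic")


def call_combined_peaks(
    fragments: Iterable[BarcodedFragment],
    genome: GenomeTable,
    min_pileup: int = 5,
    merge_gap: int = 100,
    min_width: int = 100,
) -> PeakSet:
    """Call peaks from pooled fragments by per-bp pileup thresholding.

    Parameters
    ----------
    fragments
        Pooled fragments from all cells (barcodes are ignored here).
    min_pileup
        Minimum fragment depth for a base to sit inside a peak.
    merge_gap
        Sub-threshold gaps of at most this many bp between above-threshold
        runs are closed.
    min_width
        Final intervals narrower than this are discarded.

    The score of each peak is the maximum pileup inside it.  Output is
    independent of fragment input order.
    """
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    n = 0
    for f in fragments:
        s, e = by_chrom.setdefault(f.chrom, ([], []))
        s.append(f.start)
        e.append(min(f.end, genome[f.chrom]) if f.chrom in genome else f.end)
        n += 1
    if n == 0:
        raise ValueError("no reads for peak calling")

    peaks: list[Peak] = []
    for chrom in genome:
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        runs = _threshold_runs(np.asarray(starts), np.asarray(ends), min_pileup)
        for start, end, score in _merge_runs(runs, merge_gap):
            if end - start >= min_width:
                peaks.append(Peak(chrom, int(start), int(end), float(score)))
    return PeakSet(peaks, genome=genome)


def _threshold_runs(
    starts: np.ndarray, ends: np.ndarray, min_pileup: int
) -> list[tuple[int, int, int]]:
    """Maximal runs [start, end) where pileup >= min_pileup, with max depth.

    Sweep over the sorted set of breakpoints; depth is piecewise constant
    between consecutive breakpoints.
    """
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts), np.int64), -np.ones(len(ends), np.int64)])
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    # collapse equal positions
    uniq, inverse = np.unique(pos, return_inverse=True)
    net = np.zeros(len(uniq), dtype=np.int64)
    np.add.at(net, inverse, delta)
    depth = np.cumsum(net)  # depth on [uniq[i], uniq[i+1])

    runs: list[tuple[int, int, int]] = []
    run_start = None
    run_max = 0
    for i in range(len(uniq) - 1):
        if depth[i] >= min_pileup:
            if run_start is None:
                run_start = uniq[i]
                run_max = depth[i]
            else:
                run_max = max(run_max, depth[i])
        elif run_start is not None:
            runs.append((int(run_start), int(uniq[i]), int(run_max)))
            run_start = None
    if run_start is not None:
        runs.append((int(run_start), int(uniq[-1]), int(run_max)))
    return runs


def _merge_runs(
    runs: Sequence[tuple[int, int, int]], merge_gap: int
) -> list[tuple[int, int, int]]:
    merged: list[list[int]] = []
    for start, end, score in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
            merged[-1][2] = max(merged[-1][2], score)
        else:
            merged.append([start, end, score])
    return [(a, b, c) for a, b, c in merged]


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_span: int = 3000,
    downstream_span: int = 3000,
) -> list[str]:
    """Assign each peak a single genomic-feature label by its midpoint.

    Labels, in priority order: promoter (midpoint within ``promoter_span``
    of a strand-aware TSS), exon, intron (inside a gene body but not an
    exon), downstream (within ``downstream_span`` past the TTS), distal
    intergenic.  Returns one label per peak, aligned with peak order.
    """
    labels: list[str] = []
    for p in peaks:
        mid = (p.start + p.end) // 2
        labels.append(_classify_point(p.chrom, mid, genes, promoter_span, downstream_span))
    return labels


def _classify_point(
    chrom: str, pos: int, genes: Sequence[GeneModel], promoter_span: int,
    downstream_span: int,
) -> str:
    best = len(FEATURE_LABELS) - 1  # distal intergenic
    for g in genes:
        if g.chrom != chrom:
            continue
        if abs(pos - g.tss) <= promoter_span:
            return FEATURE_LABELS[0]
        if g.tx_start <= pos < g.tx_end:
            in_exon = any(s <= pos < e for s, e in g.exons)
            best = min(best, 1 if in_exon else 2)
            continue
        if g.strand == "+":
            downstream = g.tx_end <= pos < g.tx_end + downstream_span
        else:
            downstream = g.tx_start - downstream_span <= pos < g.tx_start
        if downstream:
            best = min(best, 3)
    return FEATURE_LABELS[best]
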