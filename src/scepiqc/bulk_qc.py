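"""Bulk-cell level QC on the pooled pseudo-bulk data.

Four summaries: chromosomal peak enrichment against the genome
background (exact one-sided binomial test), the peak-score
distribution, strand-aware average coverage profiles around TSS/TTS and
over a rescaled meta-gene, and the fragment-length distribution whose
periodicity reflects factor occupancy and nucleosome positioning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sc_io import BarcodedFragment, GeneModel, GenomeTable, PeakSet

#: virtual meta-gene length in bp (axis labelling only; bin values are means)
METAGENE_VIRTUAL_LENGTH = 5000


def chrom_enrichment(
    peaks: PeakSet,
    genome: GenomeTable,
    background: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome peak enrichment vs. the genome background.

    For a chromosome carrying k of the n peaks and holding background
    probability p = chrom length / genome length, the p-value is the
    exact upper binomial tail P(X >= k), X ~ Binomial(n, p) — one-sided,
    so only relative enrichment (not depletion) is scored.  *background*
    may substitute mappable lengths for raw chromosome lengths.

    Returns a DataFrame indexed by chromosome with columns
    ``background_fraction``, ``peak_fraction``, ``n_peaks``, ``p_value``.
    """
    if len(peaks) == 0:
        raise ValueError("chrom_enrichment requires a non-empty peak set")
    lengths = dict(genome.items()) if background is None else dict(background)
    total_len = sum(lengths.values())
    n = len(peaks)
    counts = Counter(p.chrom for p in peaks)
    rows = []
    for chrom in genome:
        if chrom not in lengths:
            continue
        p_bg = lengths[chrom] / total_len
        k = counts.get(chrom, 0)
        # P(X >= k) = sf(k - 1)
        pval = float(stats.binom.sf(k - 1, n, p_bg))
        rows.append(
            {
                "chrom": chrom,
                "background_fraction": p_bg,
                "peak_fraction": k / n,
                "n_peaks": k,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


def peak_score_distribution(peaks: PeakSet, n_bins: int = 50) -> pd.DataFrame:
    """Histogram of peak scores; counts sum to the number of peaks."""
    if len(peaks) == 0:
        raise ValueError("peak_score_distribution requires a non-empty peak set")
    scores = np.array([p.score for p in peaks], dtype=float)
    if scores.min() == scores.max():
        edges = np.linspace(scores.min() - 0.5, scores.max() + 0.5, n_bins + 1)
    else:
        edges = np.linspace(scores.min(), scores.max(), n_bins + 1)
    counts, edges = np.histogram(scores, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


@dataclass
class AverageProfile:
    """Mean per-bp fragment coverage per bin, averaged over genes."""

    mode: str  # TSS | TTS | metagene
    bin_edges: np.ndarray  # bp relative to anchor, or scaled units
    values: np.ndarray  # fragments/bp per bin
    n_genes: int
    n_genes_skipped: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean_coverage": self.values,
            }
        )


class _CoverageCache:
    """Per-chromosome fragment coverage as breakpoint/depth step functions."""

    def __init__(self, fragments: Iterable[BarcodedFragment]):
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for f in fragments:
            s, e = by_chrom.setdefault(f.chrom, ([], []))
            s.append(f.start)
            e.append(f.end)
        self._steps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in by_chrom.items():
            pos = np.concatenate([starts, ends])
            delta = np.concatenate(
                [np.ones(len(starts), np.int64), -np.ones(len(ends), np.int64)]
            )
            uniq, inverse = np.unique(pos, return_inverse=True)
            net = np.zeros(len(uniq), dtype=np.int64)
            np.add.at(net, inverse, delta)
            self._steps[chrom] = (uniq, np.cumsum(net))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp depth over [start, end) (positions may be out of range)."""
        width = end - start
        out = np.zeros(width, dtype=float)
        step = self._steps.get(chrom)
        if step is None or width <= 0:
            return out
        bp, depth = step
        grid = np.arange(start, end)
        idx = np.searchsorted(bp, grid, side="right") - 1
        valid = idx >= 0
        out[valid] = depth[idx[valid]]
        return out


def average_profile(
    fragments: Iterable[BarcodedFragment],
    genes: Sequence[GeneModel],
    mode: str,
    flank: int = 3000,
    bin_width: int = 50,
    metagene_bins: int = 100,
) -> AverageProfile:
    """Average fragment coverage around TSS/TTS or over a scaled meta-gene.

    TSS/TTS modes bin per-bp coverage in a +/- *flank* window around the
    strand-aware anchor; minus-strand genes are flipped so upstream is
    always on the left.  Metagene mode rescales each gene body to
    *metagene_bins* bins of a 5 kb virtual gene; genes shorter than one
    bp per bin are skipped and counted.
    """
    if mode not in {"TSS", "TTS", "metagene"}:
        raise ValueError(f"unknown profile mode {mode!r}")
    if not genes:
        raise ValueError("average_profile requires at least one gene")
    cache = _CoverageCache(fragments)

    if mode in {"TSS", "TTS"}:
        n_bins = (2 * flank) // bin_width
        acc = np.zeros(n_bins, dtype=float)
        for g in genes:
            anchor = g.tss if mode == "TSS" else g.tts
            cov = cache.window(g.chrom, anchor - flank, anchor + flank)
            if g.strand == "-":
                cov = cov[::-1]
            acc += cov[: n_bins * bin_width].reshape(n_bins, bin_width).mean(axis=1)
        edges = np.arange(-flank, flank + bin_width, bin_width, dtype=float)
        return AverageProfile(mode, edges, acc / len(genes), len(genes))

    acc = np.zeros(metagene_bins, dtype=float)
    used = 0
    skipped = 0
    for g in genes:
        body = cache.window(g.chrom, g.tx_start, g.tx_end)
        if len(body) < metagene_bins:
            skipped += 1
            continue
        if g.strand == "-":
            body = body[::-1]
        # mean depth within each of metagene_bins equal slices of the body
        cuts = np.linspace(0, len(body), metagene_bins + 1).astype(int)
        acc += np.array([body[a:b].mean() for a, b in zip(cuts[:-1], cuts[1:])])
        used += 1
    if used == 0:
        raise ValueError("no gene long enough for the requested meta-gene binning")
    edges = np.linspace(0, METAGENE_VIRTUAL_LENGTH, metagene_bins + 1)
    return AverageProfile("metagene", edges, acc / used, used, skipped)


def fragment_length_distribution(
    fragments: Iterable[BarcodedFragment],
) -> pd.Series:
    """Histogram of fragment lengths (end - start), index = length in bp."""
    counts = Counter(f.end - f.start for f in fragments)
    ser = pd.Series(counts, dtype=int).sort_index()
    ser.index.name = "length"
    ser.name = "count"
    return ser
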