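"""Shared interval machinery: fragment-vs-peak overlap lookup.

PeakSet intervals are sorted and pairwise non-overlapping, so overlap
queries reduce to a binary search on the per-chromosome end coordinates
followed by a short forward scan.  All intervals are half-open; an
overlap requires at least one shared base.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .sc_io import BarcodedFragment, PeakSet


class PeakIndex:
    """Per-chromosome sorted arrays over a PeakSet for overlap queries."""

    def __init__(self, peaks: PeakSet):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        idx: dict[str, list[int]] = {}
        for j, p in enumerate(peaks):
            starts.setdefault(p.chrom, []).append(p.start)
            ends.setdefault(p.chrom, []).append(p.end)
            idx.setdefault(p.chrom, []).append(j)
        for chrom in starts:
            s = np.asarray(starts[chrom], dtype=np.int64)
            e = np.asarray(ends[chrom], dtype=np.int64)
            i = np.asarray(idx[chrom], dtype=np.int64)
            order = np.argsort(s, kind="stable")
            self._by_chrom[chrom] = (s[order], e[order], i[order])

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Global indices of peaks sharing >= 1 bp with [start, end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        s, e, gi = entry
        # first peak whose end is strictly past the fragment start
        k = int(np.searchsorted(e, start, side="right"))
        out: list[int] = []
        while k < len(s) and s[k] < end:
            out.append(int(gi[k]))
            k += 1
        return out


    def overlapping_pairs(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized overlap: (query index, global peak index) pairs.

        Equivalent to calling :meth:`overlapping` per query; used on the
        large pooled-fragment arrays of the simulator.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None or len(starts) == 0:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        s, e, gi = entry
        cur = np.searchsorted(e, starts, side="right")
        q_out: list[np.ndarray] = []
        p_out: list[np.ndarray] = []
        active = np.flatnonzero((cur < len(s)) & (s[np.minimum(cur, len(s) - 1)] < ends))
        while len(active):
            q_out.append(active.copy())
            p_out.append(gi[cur[active]])
            cur[active] += 1
            active = active[cur[active] < len(s)]
            active = active[s[cur[active]] < ends[active]]
        if not q_out:
            return np.zeros(0, np.int64), np.zeros(0, np.int64)
        return np.concatenate(q_out), np.concatenate(p_out)


def iter_fragment_peak_hits(
    fragments: Iterable[BarcodedFragment], peaks: PeakSet | PeakIndex
) -> Iterator[tuple[BarcodedFragment, list[int]]]:
    """Yield each fragment with the indices of the peaks it overlaps."""
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks)
    for f in fragments:
        yield f, index.overlapping(f.chrom, f.start, f.end)
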