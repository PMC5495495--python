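"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — per-bp arrays, O(n^2) loops,
exhaustive enumeration — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_pileup(fragments, chrom: str, chrom_len: int) -> np.ndarray:
    """Per-bp fragment depth over one chromosome."""
    depth = np.zeros(chrom_len, dtype=int)
    for f in fragments:
        if f.chrom == chrom:
            depth[max(f.start, 0) : min(f.end, chrom_len)] += 1
    return depth


def brute_call_peaks(fragments, genome, min_pileup, merge_gap, min_width):
    """Reference pileup-threshold peak caller on per-bp arrays."""
    peaks = []
    for chrom in genome:
        depth = brute_pileup(fragments, chrom, genome[chrom])
        above = depth >= min_pileup
        runs = []
        i = 0
        while i < len(above):
            if above[i]:
                j = i
                while j < len(above) and above[j]:
                    j += 1
                runs.append([i, j])
                i = j
            else:
                i += 1
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_width:
                peaks.append((chrom, s, e, int(depth[s:e].max())))
    return peaks


def brute_peaks_per_cell(fragments, peaks):
    """O(cells x peaks x fragments) distinct-overlap scan.

    Returns {barcode: (n_reads, n_reads_in_peaks, n_peaks_covered)}.
    """
    cells = sorted({f.barcode for f in fragments})
    out = {}
    for bc in cells:
        mine = [f for f in fragments if f.barcode == bc]
        covered = set()
        in_peak = 0
        for f in mine:
            hit = False
            for j, p in enumerate(peaks):
                if p.chrom == f.chrom and f.start < p.end and p.start < f.end:
                    covered.add(j)
                    hit = True
            if hit:
                in_peak += 1
        out[bc] = (len(mine), in_peak, len(covered))
    return out


def brute_silhouette(D: np.ndarray, labels) -> np.ndarray:
    """Plain-loop silhouette widths from a square distance matrix."""
    labels = list(labels)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s[i] = 0.0
            continue
        a = sum(D[i][j] for j in own) / len(own)
        b = None
        for c in set(labels):
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            m = sum(D[i][j] for j in members) / len(members)
            b = m if b is None else min(b, m)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def lambda_error_reduction(table) -> float:
    """Goodman-Kruskal lambda as proportional reduction in prediction error.

    Errors guessing the modal type without clusters, minus errors
    guessing each cluster's modal type, over the former.
    """
    rows = [list(r) for r in np.asarray(table)]
    n = sum(sum(r) for r in rows)
    col_totals = [sum(r[j] for r in rows) for j in range(len(rows[0]))]
    e0 = n - max(col_totals)
    if e0 == 0:
        return 1.0
    e1 = sum(sum(r) - max(r) for r in rows)
    return (e0 - e1) / e0


def enumerate_tables(shape: tuple[int, int], max_total: int):
    """All non-empty contingency tables of a shape with total <= max_total."""
    n_cells = shape[0] * shape[1]
    for total in range(1, max_total + 1):
        for cuts in itertools.combinations(range(total + n_cells - 1), n_cells - 1):
            flat = []
            prev = -1
            for c in cuts:
                flat.append(c - prev - 1)
                prev = c
            flat.append(total + n_cells - 2 - prev)
            yield np.array(flat, dtype=int).reshape(shape)


def binomial_upper_tail_enumeration(n: int, k: int, p: Fraction) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by enumerating all 2^n outcomes."""
    total = Fraction(0)
    for outcome in itertools.product([0, 1], repeat=n):
        c = sum(outcome)
        if c >= k:
            total += p**c * (1 - p) ** (n - c)
    return float(total)
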