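"""Cell-clustering level QC.

Cells are clustered on their binary occupancy of combined peaks with
agglomerative hierarchical clustering (Jaccard distance, average
linkage by default).  Reads with no overlap with combined peaks are
discarded before this step; clusters containing fewer than 3 single
cells are discarded afterwards.  Silhouette scores validate cluster
consistency, and peaks covered by the pooled reads of exactly one
retained cluster are reported as that cluster's specific peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from ._intervals import PeakIndex
from .sc_io import BarcodedFragment, PeakSet

#: label assigned to cells excluded from downstream analysis
DISCARDED = "discarded"

METRICS = {"jaccard", "euclidean"}
LINKAGES = {"average", "complete", "ward"}


@dataclass
class OccupancyMatrix:
    """Binary cells x peaks incidence: M[i, j] = 1 iff cell i covers peak j.

    Built only from fragments overlapping combined peaks; cells whose
    rows are all-zero after that discard are kept (and flagged in
    ``empty_cells``) rather than silently dropped.
    """

    barcodes: list[str]
    peaks: PeakSet
    M: np.ndarray  # bool, shape (n_cells, n_peaks)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=bool)
        if self.M.shape != (len(self.barcodes), len(self.peaks)):
            raise ValueError("occupancy matrix shape disagrees with cells x peaks")

    @property
    def empty_cells(self) -> list[str]:
        row_sums = self.M.sum(axis=1)
        return [bc for bc, s in zip(self.barcodes, row_sums) if s == 0]

    def row(self, barcode: str) -> np.ndarray:
        return self.M[self.barcodes.index(barcode)]

    def table(self) -> pd.DataFrame:
        cols = [f"{p.chrom}:{p.start}-{p.end}" for p in self.peaks]
        return pd.DataFrame(self.M.astype(int), index=self.barcodes, columns=cols)


@dataclass
class ClusterResult:
    """Cluster labels plus the QC attached to them.

    ``labels`` maps each barcode to an integer cluster id or to
    :data:`DISCARDED`.  ``linkage`` is the scipy merge record of the
    cells that entered the tree (ordered as ``clustered_barcodes``).
    """

    labels: dict[str, int | str]
    n_clusters: int
    linkage: np.ndarray | None = None
    clustered_barcodes: list[str] = field(default_factory=list)
    silhouette_per_cell: dict[str, float] = field(default_factory=dict)
    silhouette_per_cluster: dict[int, float] = field(default_factory=dict)
    specific_peaks: dict[int, list[int]] = field(default_factory=dict)

    def members(self) -> dict[int, list[str]]:
        """Retained cluster id -> sorted member barcodes."""
        out: dict[int, list[str]] = {}
        for bc, lab in self.labels.items():
            if lab != DISCARDED:
                out.setdefault(int(lab), []).append(bc)
        return {c: sorted(bcs) for c, bcs in sorted(out.items())}

    def retained_barcodes(self) -> list[str]:
        return sorted(bc for bc, lab in self.labels.items() if lab != DISCARDED)

    def assignment_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"barcode": sorted(self.labels), "cluster": [self.labels[b] for b in sorted(self.labels)]}
        )
        return df


def build_occupancy(
    fragments: Iterable[BarcodedFragment],
    peaks: PeakSet,
    cells: Iterable[str] | None = None,
) -> OccupancyMatrix:
    """Build the binary peak-occupancy matrix.

    Fragments not overlapping any combined peak contribute nothing.  If
    *cells* is given, only those barcodes become rows (others' fragments
    are ignored); otherwise every barcode seen in the input gets a row.
    Rows are ordered by barcode.
    """
    if len(peaks) == 0:
        raise ValueError("build_occupancy requires a non-empty peak set")
    index = PeakIndex(peaks)
    fragments = list(fragments)
    if cells is None:
        barcode_list = sorted({f.barcode for f in fragments})
    else:
        barcode_list = sorted(set(cells))
    if not barcode_list:
        raise ValueError("build_occupancy requires at least one cell")
    row_of = {bc: i for i, bc in enumerate(barcode_list)}
    M = np.zeros((len(barcode_list), len(peaks)), dtype=bool)
    by_chrom: dict[str, tuple[list[int], list[int], list[int]]] = {}
    for f in fragments:
        i = row_of.get(f.barcode)
        if i is None:
            continue
        rows, starts, ends = by_chrom.setdefault(f.chrom, ([], [], []))
        rows.append(i)
        starts.append(f.start)
        ends.append(f.end)
    for chrom, (rows, starts, ends) in by_chrom.items():
        q, pj = index.overlapping_pairs(
            chrom, np.asarray(starts, np.int64), np.asarray(ends, np.int64)
        )
        M[np.asarray(rows, np.int64)[q], pj] = True
    return OccupancyMatrix(barcode_list, peaks, M)


def _distance_matrix(M: np.ndarray, metric: str) -> np.ndarray:
    X = M.astype(bool) if metric == "jaccard" else M.astype(float)
    return pdist(X, metric=metric)


def hcluster_cells(
    occupancy: OccupancyMatrix,
    metric: str = "jaccard",
    linkage: str = "average",
    k: int | str = "auto",
    k_max: int = 10,
) -> ClusterResult:
    """Hierarchically cluster cells on their peak occupancy (pre-filter).

    Cells with all-zero rows are excluded from the distance computation
    (Jaccard distance to an empty set is undefined) and labelled
    :data:`DISCARDED`.  With ``k="auto"`` the tree is cut at the k in
    [2, k_max] maximizing the mean silhouette (ties to the smallest k);
    an integer k cuts at exactly k clusters.  Cells are processed in
    sorted-barcode order, making the output invariant to input order.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(LINKAGES)}")
    if isinstance(k, int) and k < 2:
        raise ValueError("k must be >= 2 (silhouette requires >= 2 clusters)")

    order = np.argsort(np.asarray(occupancy.barcodes, dtype=object), kind="stable")
    barcodes = [occupancy.barcodes[i] for i in order]
    M = occupancy.M[order]

    nonzero = M.sum(axis=1) > 0
    labels: dict[str, int | str] = {
        bc: DISCARDED for bc, nz in zip(barcodes, nonzero) if not nz
    }
    active = [bc for bc, nz in zip(barcodes, nonzero) if nz]
    Ma = M[nonzero]
    if len(active) < 2:
        raise ValueError("clustering requires >= 2 cells with >= 1 occupied peak")

    D = _distance_matrix(Ma, metric)
    if np.all(D == 0):
        warnings.warn(
            "all occupancy rows identical; returning a single cluster "
            "(silhouette undefined)",
            stacklevel=2,
        )
        for bc in active:
            labels[bc] = 1
        return ClusterResult(labels, 1, None, active)

    method = "ward" if linkage == "ward" else linkage
    Z = hierarchy.linkage(D, method=method)

    if k == "auto":
        best_k, best_score, best_flat = None, -np.inf, None
        for kk in range(2, min(k_max, len(active) - 1) + 1):
            flat = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(flat)) < 2:
                continue
            per_cell, _ = _silhouette_arrays(squareform(D), flat)
            score = float(np.mean(per_cell))
            if score > best_score + 1e-12:
                best_k, best_score, best_flat = kk, score, flat
        if best_flat is None:
            raise ValueError("no tree cut with >= 2 clusters found")
        flat = best_flat
    else:
        flat = hierarchy.fcluster(Z, t=int(k), criterion="maxclust")

    # renumber clusters 1..k in order of first (lexicographic) member
    seen: dict[int, int] = {}
    for raw in flat:
        if raw not in seen:
            seen[raw] = len(seen) + 1
    for bc, raw in zip(active, flat):
        labels[bc] = seen[raw]
    return ClusterResult(labels, len(seen), Z, active)


def filter_clusters(result: ClusterResult, min_cells: int = 3) -> ClusterResult:
    """Discard clusters with fewer than *min_cells* cells.

    The discarded clusters' cells are labelled :data:`DISCARDED` and
    ignored by every downstream step.  Errors if no cluster survives.
    """
    sizes = {c: len(bcs) for c, bcs in result.members().items()}
    keep = {c for c, n in sizes.items() if n >= min_cells}
    if not keep:
        raise ValueError(f"no cluster with >= {min_cells} cells")
    labels: dict[str, int | str] = {
        bc: (lab if lab in keep else DISCARDED) for bc, lab in result.labels.items()
    }
    return replace(result, labels=labels, n_clusters=len(keep))


def _silhouette_arrays(
    D: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, dict[int, float]]:
    """Silhouette widths from a square distance matrix and integer labels.

    s(i) = (b - a) / max(a, b); cells in singleton clusters score 0, and
    0/0 is defined as 0.
    """
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    sums = np.zeros((n, len(uniq)))
    counts = np.zeros(len(uniq), dtype=int)
    for idx, c in enumerate(uniq):
        mask = labels == c
        counts[idx] = mask.sum()
        sums[:, idx] = D[:, mask].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        own = int(np.searchsorted(uniq, labels[i]))
        if counts[own] <= 1:
            s[i] = 0.0
            continue
        a = sums[i, own] / (counts[own] - 1)
        b = np.inf
        for idx in range(len(uniq)):
            if idx != own:
                b = min(b, sums[i, idx] / counts[idx])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_cluster = {
        int(c): float(s[labels == c].mean()) for c in uniq
    }
    return s, per_cluster


def silhouette(
    occupancy: OccupancyMatrix,
    labels: Mapping[str, int | str],
    metric: str = "jaccard",
) -> tuple[dict[str, float], dict[int, float]]:
    """Per-cell silhouette widths and per-cluster means for retained cells.

    Requires at least two retained clusters.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    retained = sorted(bc for bc, lab in labels.items() if lab != DISCARDED)
    lab_arr = np.array([int(labels[bc]) for bc in retained])
    if len(np.unique(lab_arr)) < 2:
        raise ValueError("silhouette requires >= 2 retained clusters")
    row_of = {bc: i for i, bc in enumerate(occupancy.barcodes)}
    rows = np.array([row_of[bc] for bc in retained])
    D = squareform(_distance_matrix(occupancy.M[rows], metric))
    s, per_cluster = _silhouette_arrays(D, lab_arr)
    return {bc: float(v) for bc, v in zip(retained, s)}, per_cluster


def specific_peaks(
    fragments: Iterable[BarcodedFragment],
    peaks: PeakSet,
    result: ClusterResult,
    min_reads: int = 1,
) -> dict[int, list[int]]:
    """Peaks covered by the pooled reads of exactly one retained cluster.

    Reads from all cells of a retained cluster are merged; a peak is
    covered in the cluster iff at least *min_reads* pooled fragments
    overlap it.  A peak covered in exactly one cluster is specific to
    that cluster.  Peak indices are returned in genomic order (the
    PeakSet order); the lists are pairwise disjoint by construction.
    """
    members = result.members()
    if len(members) < 2:
        raise ValueError("specific_peaks requires >= 2 retained clusters")
    cluster_of = {bc: c for c, bcs in members.items() for bc in bcs}
    index = PeakIndex(peaks)
    counts: dict[int, np.ndarray] = {
        c: np.zeros(len(peaks), dtype=np.int64) for c in members
    }
    for f in fragments:
        c = cluster_of.get(f.barcode)
        if c is None:
            continue
        for j in index.overlapping(f.chrom, f.start, f.end):
            counts[c][j] += 1
    covered = {c: counts[c] >= min_reads for c in members}
    coverage_count = np.sum([covered[c] for c in members], axis=0)
    out: dict[int, list[int]] = {}
    for c in members:
        mask = covered[c] & (coverage_count == 1)
        out[c] = [int(j) for j in np.flatnonzero(mask)]
    return out


def contingency(
    labels: Mapping[str, int | str], truth: Mapping[str, str]
) -> pd.DataFrame:
    """Cross-tabulate retained cluster labels against true cell types.

    Rows are clusters, columns are true types; only non-discarded cells
    are counted.  Errors if a retained barcode has no truth label or if
    the truth mentions a barcode the clustering never saw.
    """
    unknown = set(truth) - set(labels)
    if unknown:
        raise ValueError(f"truth contains unknown barcodes: {sorted(unknown)[:5]}")
    retained = [bc for bc, lab in labels.items() if lab != DISCARDED]
    missing = [bc for bc in retained if bc not in truth]
    if missing:
        raise ValueError(f"no truth label for retained barcodes: {missing[:5]}")
    df = pd.crosstab(
        pd.Series([int(labels[bc]) for bc in retained], name="cluster"),
        pd.Series([truth[bc] for bc in retained], name="true_type"),
    )
    return df.sort_index(axis=0).sort_index(axis=1)
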