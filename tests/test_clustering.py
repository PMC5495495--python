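from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from scepiqc import (
    GenomeTable,
    Peak,
    PeakSet,
    build_occupancy,
    contingency,
    filter_clusters,
    hcluster_cells,
    peaks_per_cell,
    silhouette,
    specific_peaks,
)
from scepiqc.clustering import DISCARDED, OccupancyMatrix, _silhouette_arrays

import oracles
from conftest import frag


def block_occupancy(n_per_block=5, n_peaks_per_block=6):
    """Two cell blocks occupying disjoint peak sets."""
    genome = GenomeTable({"chrA": 100_000})
    peaks = PeakSet(
        [Peak("chrA", i * 1000, i * 1000 + 500, 0) for i in range(2 * n_peaks_per_block)],
        genome=genome,
    )
    M = np.zeros((2 * n_per_block, 2 * n_peaks_per_block), dtype=bool)
    M[:n_per_block, :n_peaks_per_block] = True
    M[n_per_block:, n_peaks_per_block:] = True
    barcodes = [f"a{i}" for i in range(n_per_block)] + [f"b{i}" for i in range(n_per_block)]
    return OccupancyMatrix(barcodes, peaks, M)


class TestBuildOccupancy:
    def test_row_reflects_covered_peaks(self, toy_peaks):
        frags = [
            frag("chrA", 600, 620, barcode="A"),  # peak 1
            frag("chrB", 850, 860, barcode="A"),  # peak 3
        ]
        occ = build_occupancy(frags, toy_peaks)
        assert occ.row("A").tolist() == [False, True, False, True]

    def test_non_peak_fragments_contribute_nothing(self, toy_peaks):
        frags = [frag("chrA", 600, 620, barcode="A")]
        noise = [frag("chrA", 3000 + i, 3010 + i, barcode="A") for i in range(1000)]
        a = build_occupancy(frags, toy_peaks)
        b = build_occupancy(frags + noise, toy_peaks)
        assert np.array_equal(a.M, b.M)

    def test_zero_row_cells_retained_and_flagged(self, toy_peaks):
        frags = [
            frag("chrA", 600, 620, barcode="A"),
            frag("chrA", 9000, 9100, barcode="B"),
        ]
        occ = build_occupancy(frags, toy_peaks)
        assert set(occ.barcodes) == {"A", "B"}
        assert occ.empty_cells == ["B"]

    @pytest.mark.parametrize("seed", range(3))
    def test_row_sums_equal_peaks_per_cell(self, seed, toy_peaks):
        rng = np.random.default_rng(seed)
        frags = [
            frag("chrA", int(s), int(s) + 80, barcode=f"c{int(b)}")
            for s, b in zip(rng.integers(0, 9000, 400), rng.integers(0, 12, 400))
        ]
        occ = build_occupancy(frags, toy_peaks)
        stats = peaks_per_cell(frags, toy_peaks)
        for bc in occ.barcodes:
            assert occ.row(bc).sum() == stats[bc]["n_peaks_covered"]


class TestHcluster:
    def test_two_disjoint_blocks_recovered(self):
        occ = block_occupancy()
        # between-block Jaccard distance is 1 (disjoint sets), within-block 0
        D = squareform(pdist(occ.M, metric="jaccard"))
        assert D[0, 5] == 1.0 and D[0, 1] == 0.0
        res = hcluster_cells(occ, k=2)
        groups = res.members()
        assert sorted(sorted(v) for v in groups.values()) == [
            [f"a{i}" for i in range(5)],
            [f"b{i}" for i in range(5)],
        ]

    def test_auto_k_finds_two_blocks(self):
        res = hcluster_cells(block_occupancy(), k="auto")
        assert res.n_clusters == 2

    def test_invariant_to_cell_input_order(self):
        occ = block_occupancy()
        perm = np.random.default_rng(5).permutation(len(occ.barcodes))
        occ2 = OccupancyMatrix([occ.barcodes[i] for i in perm], occ.peaks, occ.M[perm])
        a = hcluster_cells(occ, k=2)
        b = hcluster_cells(occ2, k=2)
        assert sorted(map(sorted, a.members().values())) == sorted(
            map(sorted, b.members().values())
        )

    def test_k_below_two_is_config_error(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            hcluster_cells(block_occupancy(), k=1)

    def test_identical_rows_collapse_to_single_cluster_with_warning(self, toy_peaks):
        M = np.ones((4, 4), dtype=bool)
        occ = OccupancyMatrix(["a", "b", "c", "d"], toy_peaks, M)
        with pytest.warns(UserWarning, match="identical"):
            res = hcluster_cells(occ)
        assert res.n_clusters == 1

    def test_all_zero_rows_are_excluded_from_clustering(self):
        occ = block_occupancy()
        M = np.vstack([occ.M, np.zeros((1, occ.M.shape[1]), dtype=bool)])
        occ2 = OccupancyMatrix(occ.barcodes + ["zz"], occ.peaks, M)
        res = hcluster_cells(occ2, k=2)
        assert res.labels["zz"] == DISCARDED


class TestFilterClusters:
    def make_result(self, sizes):
        labels = {}
        i = 0
        for c, n in enumerate(sizes, start=1):
            for _ in range(n):
                labels[f"c{i:02d}"] = c
                i += 1
        from scepiqc.clustering import ClusterResult

        return ClusterResult(labels, len(sizes))

    def test_small_clusters_discarded(self):
        res = filter_clusters(self.make_result([5, 2, 3]))
        sizes = {c: len(v) for c, v in res.members().items()}
        assert sizes == {1: 5, 3: 3}
        assert sum(1 for v in res.labels.values() if v == DISCARDED) == 2

    def test_all_large_clusters_unchanged(self):
        res = filter_clusters(self.make_result([4, 4]))
        assert res.n_clusters == 2
        assert DISCARDED not in res.labels.values()

    def test_min_cells_one_is_identity(self):
        res = filter_clusters(self.make_result([1, 2]), min_cells=1)
        assert res.n_clusters == 2

    def test_error_when_everything_discarded(self):
        with pytest.raises(ValueError, match="no cluster"):
            filter_clusters(self.make_result([2, 2]))


class TestSilhouette:
    def test_two_tight_far_apart_groups(self):
        # 1-D points {0, 0.1} vs {10, 10.1}: a = 0.1, b ~ 10 for each point
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = squareform(pdist(pts))
        s, per_cluster = _silhouette_arrays(D, np.array([1, 1, 2, 2]))
        assert s[1] == pytest.approx((9.95 - 0.1) / 9.95)
        assert np.allclose(s, 0.99, atol=1e-3)
        assert per_cluster[1] == pytest.approx(s[:2].mean())

    def test_identical_points_across_clusters_score_zero(self):
        D = np.zeros((4, 4))
        s, _ = _silhouette_arrays(D, np.array([1, 1, 2, 2]))
        assert np.all(s == 0.0)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0], [0.2], [5.0]])
        D = squareform(pdist(pts))
        s, _ = _silhouette_arrays(D, np.array([1, 1, 2]))
        assert s[2] == 0.0

    def test_bounded_and_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            D = squareform(pdist(rng.random((n, 3))))
            labels = rng.integers(1, 4, n)
            s, _ = _silhouette_arrays(D, labels)
            assert np.all((s >= -1) & (s <= 1))
            assert np.allclose(s, oracles.brute_silhouette(D, labels), atol=1e-12)

    def test_agrees_with_sklearn_on_clean_instances(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(1)
        X = np.vstack([rng.random((10, 4)), rng.random((10, 4)) + 5])
        labels = np.array([1] * 10 + [2] * 10)
        D = squareform(pdist(X))
        s, _ = _silhouette_arrays(D, labels)
        assert np.allclose(s, silhouette_samples(X, labels, metric="euclidean"), atol=1e-10)

    def test_requires_two_retained_clusters(self):
        occ = block_occupancy()
        labels = {bc: 1 for bc in occ.barcodes}
        with pytest.raises(ValueError, match=">= 2"):
            silhouette(occ, labels)

    def test_public_surface_on_occupancy(self):
        occ = block_occupancy()
        labels = {bc: (1 if bc.startswith("a") else 2) for bc in occ.barcodes}
        per_cell, per_cluster = silhouette(occ, labels)
        # perfectly separated binary blocks: s = 1 for every cell
        assert all(v == pytest.approx(1.0) for v in per_cell.values())
        assert per_cluster == {1: pytest.approx(1.0), 2: pytest.approx(1.0)}


class TestSpecificPeaks:
    def setup_case(self, toy_genome):
        peaks = PeakSet(
            [Peak("chrA", i * 1000, i * 1000 + 500, 0) for i in range(3)],
            genome=toy_genome,
        )
        from scepiqc.clustering import ClusterResult

        labels = {"a0": 1, "a1": 1, "a2": 1, "b0": 2, "b1": 2, "b2": 2}
        result = ClusterResult(labels, 2)
        frags = (
            [frag("chrA", 100, 200, barcode=f"a{i}") for i in range(3)]  # peak 0: A only
            + [frag("chrA", 1100, 1200, barcode="a0"), frag("chrA", 1100, 1200, barcode="b0")]  # peak 1: both
            + [frag("chrA", 2100, 2200, barcode="b1")]  # peak 2: B only
        )
        return frags, peaks, result

    def test_unique_coverage_defines_specific_peaks(self, toy_genome):
        frags, peaks, result = self.setup_case(toy_genome)
        spec = specific_peaks(frags, peaks, result)
        assert spec == {1: [0], 2: [2]}

    def test_lists_are_disjoint_and_subset_of_covered(self, toy_genome):
        rng = np.random.default_rng(2)
        peaks = PeakSet(
            [Peak("chrA", i * 500, i * 500 + 300, 0) for i in range(15)],
            genome=toy_genome,
        )
        from scepiqc.clustering import ClusterResult

        labels = {f"c{i}": (i % 3) + 1 for i in range(12)}
        result = ClusterResult(labels, 3)
        frags = [
            frag("chrA", int(s), int(s) + 100, barcode=f"c{int(b)}")
            for s, b in zip(rng.integers(0, 7000, 200), rng.integers(0, 12, 200))
        ]
        spec = specific_peaks(frags, peaks, result)
        seen = []
        for idxs in spec.values():
            seen.extend(idxs)
        assert len(seen) == len(set(seen))

    def test_requires_two_clusters(self, toy_genome):
        frags, peaks, result = self.setup_case(toy_genome)
        result.labels = {bc: 1 for bc in result.labels}
        with pytest.raises(ValueError):
            specific_peaks(frags, peaks, result)


class TestContingency:
    def test_perfect_split_is_diagonal(self):
        labels = {f"x{i}": 1 for i in range(3)} | {f"y{i}": 2 for i in range(3)}
        truth = {f"x{i}": "T1" for i in range(3)} | {f"y{i}": "T2" for i in range(3)}
        tab = contingency(labels, truth)
        assert tab.values.tolist() == [[3, 0], [0, 3]]
        assert tab.values.sum() == 6

    def test_discarded_cells_excluded(self):
        labels = {"a": 1, "b": 1, "c": 1, "d": DISCARDED}
        truth = {"a": "T", "b": "T", "c": "T", "d": "T"}
        assert contingency(labels, truth).values.sum() == 3

    def test_unknown_barcode_in_truth_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            contingency({"a": 1}, {"a": "T", "zz": "T"})

    def test_missing_truth_for_retained_cell_errors(self):
        with pytest.raises(ValueError, match="no truth"):
            contingency({"a": 1, "b": 1}, {"a": "T"})
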