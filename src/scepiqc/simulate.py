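"""Parametric simulator of multi-cell-type scATAC-like fragment data and
the clustering-stability experiments built on it.

A scenario describes a genome, a set of cell types — each with its own
type-specific open regions plus regions shared by every type — a cell
composition, a per-cell read count and a signal fraction.  Each
fragment lands, with probability ``signal_fraction``, uniformly inside
a uniformly chosen accessible region of its cell's type, and otherwise
uniformly on the genome background; its length is drawn from a
two-component mixture (a short sub-nucleosomal mode and a
mono-nucleosome mode), emulating the periodic fragment-size structure
of Tn5-digested chromatin.

Clustering stability is scored with Goodman-Kruskal's lambda between
cluster labels and true cell types; stability curves report the mean
lambda and a 95% confidence interval over independent replicates as a
function of sequencing depth or of the target cell type's abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import build_occupancy, contingency, filter_clusters, hcluster_cells
from .peaks import call_combined_peaks
from .sc_io import BarcodedFragment, GenomeTable

#: shortest fragment the length model may emit (bp)
MIN_FRAGMENT_LENGTH = 20


@dataclass(frozen=True)
class FragmentLengthModel:
    """Two-Gaussian length mixture: sub-nucleosomal and mono-nucleosome modes."""

    means: tuple[float, float] = (80.0, 200.0)
    sds: tuple[float, float] = (15.0, 35.0)
    weights: tuple[float, float] = (0.6, 0.4)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.random(n) < self.weights[0] / sum(self.weights)
        lens = np.where(
            comp,
            rng.normal(self.means[0], self.sds[0], n),
            rng.normal(self.means[1], self.sds[1], n),
        )
        return np.maximum(np.rint(lens).astype(np.int64), MIN_FRAGMENT_LENGTH)


@dataclass(frozen=True)
class CellType:
    """One simulated cell type: its private and its shared open regions."""

    name: str
    open_regions: tuple[tuple[str, int, int], ...]  # type-specific
    shared_regions: tuple[tuple[str, int, int], ...]  # common to all types

    @property
    def accessible(self) -> tuple[tuple[str, int, int], ...]:
        return self.open_regions + self.shared_regions


@dataclass(frozen=True)
class SimScenario:
    """Generative description of a synthetic multi-cell-type dataset."""

    genome: GenomeTable
    cell_types: tuple[CellType, ...]
    composition: tuple[int, ...]
    reads_per_cell: int = 2000
    signal_fraction: float = 0.8
    fragment_length_model: FragmentLengthModel = FragmentLengthModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.composition) != len(self.cell_types):
            raise ValueError("composition length must match the number of cell types")
        if any(n <= 0 for n in self.composition):
            raise ValueError("composition entries must be positive")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in [0, 1]")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")
        for ct in self.cell_types:
            for chrom, start, end in ct.accessible:
                if chrom not in self.genome or not 0 <= start < end <= self.genome[chrom]:
                    raise ValueError(
                        f"region {chrom}:{start}-{end} of type {ct.name} "
                        "falls outside the genome"
                    )
                if end - start < MIN_FRAGMENT_LENGTH:
                    raise ValueError(
                        f"region {chrom}:{start}-{end} of type {ct.name} is "
                        f"shorter than the minimum fragment length "
                        f"({MIN_FRAGMENT_LENGTH} bp)"
                    )


def default_scenario(
    seed: int = 0,
    composition: Sequence[int] = (50, 50, 50),
    reads_per_cell: int = 2000,
    signal_fraction: float = 0.8,
    n_specific: int = 20,
    n_shared: int = 40,
    region_width: int = 1000,
    chrom_length: int = 10_000_000,
    n_chroms: int = 2,
) -> SimScenario:
    """Desk-scale default scenario: 3 cell types on a 2 x 10 Mb genome.

    Each type owns ``n_specific`` private open regions; ``n_shared``
    regions are accessible to every type.  Regions are laid out on a
    jittered grid so they are pairwise disjoint, deterministically from
    *seed*.
    """
    n_types = len(composition)
    genome = GenomeTable({f"chr{i + 1}": chrom_length for i in range(n_chroms)})
    total_regions = n_types * n_specific + n_shared
    chroms = list(genome)
    rng = np.random.default_rng(seed)

    # one slot per region across the concatenated genome, jittered
    spacing = genome.total_length // total_regions
    if spacing <= region_width:
        raise ValueError("genome too small for the requested region layout")
    regions: list[tuple[str, int, int]] = []
    for i in range(total_regions):
        g_start = i * spacing + int(rng.integers(0, spacing - region_width))
        # map the concatenated coordinate back onto a chromosome
        chrom_idx = min(g_start // chrom_length, n_chroms - 1)
        start = g_start - chrom_idx * chrom_length
        start = min(start, chrom_length - region_width)
        regions.append((chroms[chrom_idx], start, start + region_width))
    rng.shuffle(regions)

    shared = tuple(regions[:n_shared])
    cell_types = []
    for t in range(n_types):
        lo = n_shared + t * n_specific
        own = tuple(sorted(regions[lo : lo + n_specific]))
        cell_types.append(CellType(f"type{t + 1}", own, shared))
    return SimScenario(
        genome=genome,
        cell_types=tuple(cell_types),
        composition=tuple(composition),
        reads_per_cell=reads_per_cell,
        signal_fraction=signal_fraction,
        seed=seed,
    )


def generate_cells(
    scenario: SimScenario,
) -> tuple[list[BarcodedFragment], dict[str, str]]:
    """Generate fragments and truth labels for every cell of a scenario.

    Deterministic given ``scenario.seed``.  Returns the fragment list
    and a barcode -> true-type map.
    """
    rng = np.random.default_rng(scenario.seed)
    genome = scenario.genome
    chroms = list(genome)
    chrom_lens = np.array([genome[c] for c in chroms], dtype=np.int64)
    chrom_probs = chrom_lens / chrom_lens.sum()

    fragments: list[BarcodedFragment] = []
    truth: dict[str, str] = {}
    for ct, n_cells in zip(scenario.cell_types, scenario.composition):
        regions = ct.accessible
        reg_chrom = np.array([r[0] for r in regions])
        reg_start = np.array([r[1] for r in regions], dtype=np.int64)
        reg_end = np.array([r[2] for r in regions], dtype=np.int64)
        for c in range(n_cells):
            barcode = f"{ct.name}_c{c:03d}"
            truth[barcode] = ct.name
            n = scenario.reads_per_cell
            lens = scenario.fragment_length_model.sample(rng, n)
            in_signal = rng.random(n) < scenario.signal_fraction
            starts = np.empty(n, dtype=np.int64)
            frag_chrom = np.empty(n, dtype=object)

            n_sig = int(in_signal.sum())
            if n_sig:
                ridx = rng.integers(0, len(regions), n_sig)
                offs = rng.integers(0, reg_end[ridx] - reg_start[ridx])
                starts[in_signal] = reg_start[ridx] + offs
                frag_chrom[in_signal] = reg_chrom[ridx]
            n_bg = n - n_sig
            if n_bg:
                cidx = rng.choice(len(chroms), n_bg, p=chrom_probs)
                starts[~in_signal] = rng.integers(0, chrom_lens[cidx] - 1)
                frag_chrom[~in_signal] = np.array(chroms, dtype=object)[cidx]
            strands = np.where(rng.random(n) < 0.5, "+", "-")
            for i in range(n):
                chrom = frag_chrom[i]
                end = min(int(starts[i] + lens[i]), genome[chrom])
                fragments.append(
                    BarcodedFragment(chrom, int(starts[i]), end, str(strands[i]), barcode)
                )
    return fragments, truth


def subsample_depth(
    fragments: Sequence[BarcodedFragment],
    target_reads_per_cell: int,
    seed: int = 0,
    underfilled: str = "keep",
) -> list[BarcodedFragment]:
    """Uniformly subsample each cell to exactly *target_reads_per_cell* reads.

    Sampling is without replacement and per cell.  Cells already at or
    below the target are kept whole with a warning (``underfilled="keep"``,
    the default) or dropped entirely (``underfilled="drop"``).
    """
    if target_reads_per_cell <= 0:
        raise ValueError("target_reads_per_cell must be positive")
    if underfilled not in {"keep", "drop"}:
        raise ValueError("underfilled policy must be 'keep' or 'drop'")
    by_cell: dict[str, list[int]] = {}
    for i, f in enumerate(fragments):
        by_cell.setdefault(f.barcode, []).append(i)
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    n_under = 0
    for bc in sorted(by_cell):
        idx = by_cell[bc]
        if len(idx) <= target_reads_per_cell:
            n_under += 1
            if underfilled == "keep":
                keep_idx.extend(idx)
            continue
        chosen = rng.choice(len(idx), target_reads_per_cell, replace=False)
        keep_idx.extend(idx[j] for j in chosen)
    if n_under and underfilled == "keep":
        warnings.warn(
            f"{n_under} cells below the target depth were kept whole",
            stacklevel=2,
        )
    keep_idx.sort()
    return [fragments[i] for i in keep_idx]


def gk_lambda(
    table: pd.DataFrame | np.ndarray, direction: str = "type_from_cluster"
) -> float:
    """Goodman-Kruskal's lambda for a cluster x true-type contingency table.

    With the default direction the statistic measures the proportional
    reduction in error when predicting the true type from the cluster:

        lambda = (sum_c max_t n_ct - max_t n_+t) / (N - max_t n_+t)

    ``direction="cluster_from_type"`` transposes the roles.  When one
    column holds every observation the denominator vanishes and lambda
    is defined as 1.0.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.size == 0 or arr.sum() == 0:
        raise ValueError("empty contingency table")
    if np.any(arr < 0):
        raise ValueError("contingency counts must be non-negative")
    if direction == "cluster_from_type":
        arr = arr.T
    elif direction != "type_from_cluster":
        raise ValueError(f"unknown lambda direction {direction!r}")
    n = arr.sum()
    modal_overall = arr.sum(axis=0).max()
    if n == modal_overall:
        return 1.0
    return float((arr.max(axis=1).sum() - modal_overall) / (n - modal_overall))


@dataclass
class ReplicateOutcome:
    """Result of one simulate -> cluster -> evaluate run."""

    lambda_: float  # NaN if the replicate failed to cluster
    n_clusters: int
    n_peaks: int
    error: str = ""


def run_clustering_replicate(
    fragments: Sequence[BarcodedFragment],
    genome: GenomeTable,
    truth: Mapping[str, str],
    min_pileup: int = 5,
    merge_gap: int = 100,
    min_width: int = 100,
    metric: str = "jaccard",
    linkage: str = "average",
    k: int | str = "auto",
    min_cells: int = 3,
) -> ReplicateOutcome:
    """Full pipeline on one simulated dataset: peaks -> occupancy ->
    hierarchical clustering -> cluster-size filter -> lambda vs. truth.

    A replicate that fails to produce >= 2 retained clusters (or any
    peaks at all) is reported with lambda = NaN and the error message,
    never silently dropped.
    """
    try:
        peaks = call_combined_peaks(
            fragments, genome, min_pileup=min_pileup, merge_gap=merge_gap,
            min_width=min_width,
        )
        occ = build_occupancy(fragments, peaks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = hcluster_cells(occ, metric=metric, linkage=linkage, k=k)
        result = filter_clusters(result, min_cells=min_cells)
        table = contingency(result.labels, truth)
        return ReplicateOutcome(gk_lambda(table), result.n_clusters, len(peaks))
    except ValueError as exc:
        return ReplicateOutcome(float("nan"), 0, 0, error=str(exc))


@dataclass
class StabilityCurve:
    """Mean lambda with 95% CI over replicates along a scenario grid."""

    mode: str  # "depth" | "composition"
    x: list[int]  # reads per cell, or target-type cell count
    replicates: np.ndarray  # shape (len(x), n_reps); NaN = failed replicate
    n_failed: list[int]

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nanmean(self.replicates, axis=1)

    @property
    def ci_half_width(self) -> np.ndarray:
        """Normal-approximation 95% CI half-width: 1.96 * sd / sqrt(n)."""
        out = np.zeros(len(self.x))
        for i, row in enumerate(self.replicates):
            vals = row[~np.isnan(row)]
            if len(vals) > 1:
                out[i] = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
        return out

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.mode: self.x,
                "mean_lambda": self.mean,
                "ci95_half_width": self.ci_half_width,
                "n_replicates": [
                    int((~np.isnan(r)).sum()) for r in self.replicates
                ],
                "n_failed": self.n_failed,
            }
        )


def stability_vs_depth(
    scenario: SimScenario,
    depth_grid: Sequence[int],
    n_reps: int = 20,
    base_seed: int = 0,
    **pipeline_kwargs,
) -> StabilityCurve:
    """Lambda vs. reads-per-cell: per depth, *n_reps* independent
    simulate -> subsample -> cluster -> evaluate runs.

    Replicate r uses generation seed ``base_seed + r``; fragments are
    generated at ``scenario.reads_per_cell`` and subsampled to each grid
    depth.
    """
    if not depth_grid:
        raise ValueError("depth grid must be non-empty")
    reps = np.full((len(depth_grid), n_reps), np.nan)
    n_failed = [0] * len(depth_grid)
    for d_i, depth in enumerate(depth_grid):
        for r in range(n_reps):
            sc = replace(scenario, seed=base_seed + r)
            fragments, truth = generate_cells(sc)
            sub = subsample_depth(fragments, depth, seed=base_seed + r)
            out = run_clustering_replicate(sub, sc.genome, truth, **pipeline_kwargs)
            reps[d_i, r] = out.lambda_
            if np.isnan(out.lambda_):
                n_failed[d_i] += 1
    return StabilityCurve("depth", list(depth_grid), reps, n_failed)


#: the cell-mixture series: target-type count vs. the two regular types
DEFAULT_COMPOSITIONS: tuple[tuple[int, int, int], ...] = (
    (10, 70, 70),
    (15, 67, 67),
    (20, 65, 65),
    (25, 62, 62),
    (30, 60, 60),
    (35, 57, 57),
    (40, 55, 55),
    (45, 52, 52),
    (50, 50, 50),
)


def stability_vs_composition(
    scenario_base: SimScenario,
    compositions: Sequence[Sequence[int]] = DEFAULT_COMPOSITIONS,
    n_reps: int = 20,
    base_seed: int = 0,
    **pipeline_kwargs,
) -> StabilityCurve:
    """Lambda vs. target-cell-type abundance at fixed depth.

    The first composition entry is the target cell type's count (the
    x-axis); the remaining entries are the regular cell types.
    """
    if not compositions:
        raise ValueError("composition grid must be non-empty")
    reps = np.full((len(compositions), n_reps), np.nan)
    n_failed = [0] * len(compositions)
    for c_i, comp in enumerate(compositions):
        comp_t = tuple(int(x) for x in comp)
        for r in range(n_reps):
            sc = replace(scenario_base, composition=comp_t, seed=base_seed + r)
            fragments, truth = generate_cells(sc)
            out = run_clustering_replicate(fragments, sc.genome, truth, **pipeline_kwargs)
            reps[c_i, r] = out.lambda_
            if np.isnan(out.lambda_):
                n_failed[c_i] += 1
    return StabilityCurve("composition", [c[0] for c in compositions], reps, n_failed)
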