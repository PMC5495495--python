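# Methods

## Data model and conventions

All coordinates are 0-based, half-open `[start, end)` after ingestion;
SAM/BAM input (1-based) is converted once at the reader and never
again. A *cell* is a unique barcode string. Overlap between a fragment
and a peak requires at least one shared base; no fractional-overlap
rule is applied. Barcodes are located by a fixed precedence — explicit
BED column (default column 7), then an alignment tag (default `CB`),
then the read-name suffix after a delimiter — and a manifest mode
assigns the file stem as the barcode for one-file-per-cell datasets.
Readers tolerate up to 1% record-level errors (invalid interval,
missing barcode), counting and skipping them, and fail beyond that:
stray lines should not kill a run, but a substantially broken file
should not be silently eaten.

## Combined peaks

The shared coordinate axis for all per-cell analysis is a set of
"combined peaks" obtained from all cells pooled. Externally called
peaks (BED) are accepted and merged if overlapping (interval union,
max score), or the internal caller is used: maximal intervals where
per-bp fragment pileup ≥ `min_pileup` (default 5), with sub-threshold
gaps ≤ `merge_gap` (100 bp) closed and intervals < `min_width`
(100 bp) dropped; the peak score is the maximum pileup. This is a
deliberately transparent thresholding procedure, not a model-based
caller: no local background, no FDR. It exists so the pipeline is
self-contained and its downstream stages testable; for real data an
external peak caller's BED is the expected input.

Peak annotation assigns each peak one label by its midpoint with
priority promoter > exon > intron > downstream > distal intergenic,
where promoter = within 3,000 bp of a strand-aware TSS (symmetric) and
downstream = within 3,000 bp past the TTS. Midpoint-plus-priority is
chosen for determinism; peaks spanning feature boundaries get the
label of their midpoint's highest-priority feature.

## Bulk-cell QC

Chromosomal enrichment tests, per chromosome, whether more peaks land
on it than its share of the genome predicts: with k of n peaks on a
chromosome of background probability p = chromosome length / genome
length, the p-value is the exact upper binomial tail P(X ≥ k). The
test is one-sided because the quantity of interest is relative
enrichment of open regions; depletion is not scored. Raw chromosome
lengths stand in for mappable lengths by default; a mappable-length
table can be substituted through the `background` argument.

Average profiles report mean per-bp fragment coverage per bin,
averaged over genes, around the TSS and TTS (± 3,000 bp flank, 50 bp
bins) and over a meta-gene: each gene body rescaled to 100 bins
representing a 5 kb virtual gene. Minus-strand genes are flipped so
upstream is always left. Genes shorter than one bp per meta-gene bin
are skipped and counted. The fragment-length histogram is purely
descriptive; no nucleosome positions are called from its periodicity.

## Occupancy clustering

The occupancy matrix is binary: cell i occupies peak j iff ≥ 1 of its
fragments overlaps it. Binary (rather than count-weighted) occupancy
is used because presence/absence is the minimal reading of "occupied",
and per-cell counts at single-cell depth are dominated by sampling
noise. Fragments outside combined peaks are discarded from this step
onward. Cells whose rows become all-zero after that discard are
excluded from distance computation — Jaccard distance to an empty set
is undefined — and reported as discarded rather than silently dropped.

Distances are Jaccard on binary rows (Euclidean available), linkage is
average (complete and Ward available). Cells enter the tree in sorted
barcode order, which makes the output invariant to input order and
fixes tie-breaking deterministically. The tree is cut either at a
user-fixed k or, by default, at the k in [2, 10] maximizing the mean
silhouette width. Clusters with fewer than 3 cells are then discarded
along with their cells.

Silhouette widths s(i) = (b−a)/max(a,b) use the same metric as the
clustering; cells in singleton clusters score 0, and 0/0 is defined
as 0 (all-identical points carry no separation evidence either way).
The implementation is checked in the test suite against an independent
O(n²) brute-force recomputation and against scikit-learn on instances
where the conventions coincide.

Specific peaks: reads of each retained cluster are pooled; a peak is
covered in a cluster iff ≥ `min_reads` pooled fragments overlap it,
and is specific to a cluster iff covered there and nowhere else. The
default `min_reads` is 1 — the minimal reading of unique coverage.
Under the simulator's uniform background this default is too
permissive at realistic depth (each cluster's pool sprinkles roughly
one background read per peak, so nearly every peak is "covered"
everywhere); the stability experiments and the acceptance script
therefore use `min_reads = 10`, chosen from the background rate: the
expected background hits per peak per cluster pool are ~1.15 under the
default strong-signal scenario (Poisson tail P(≥ 10) ≈ 5·10⁻⁷), while
pooled signal coverage of a truly accessible peak is ~1,300 reads.
Any threshold in roughly 5–100 separates these regimes; 10 is used
throughout.

## Simulator

The generator is parametric rather than a resampler of real reads, so
every experiment runs self-contained. A scenario fixes a genome
(default 2 chromosomes × 10 Mb), three cell types each owning 20
type-specific 1 kb open regions plus 40 regions shared by all types
(regions laid out disjointly on a jittered grid), a composition
(default 50:50:50), a per-cell read count (default 2,000) and a signal
fraction (default 0.8). Each fragment falls, with probability equal to
the signal fraction, uniformly inside a uniformly chosen accessible
region of its cell's type, otherwise uniformly on the genome
(chromosomes weighted by length); its length is drawn from a
two-Gaussian mixture — a sub-nucleosomal mode (mean 80 bp, sd 15) and
a mono-nucleosome mode (mean 200 bp, sd 35), weights 0.6/0.4, floor
20 bp — and truncated at the chromosome end. Everything is
deterministic given the scenario seed.

What the simulator emulates: multi-cell-type accessibility structure,
shared housekeeping-like regions, depth limits, mixture imbalance, and
the bimodal fragment-length signature. What it does not: Tn5 sequence
bias, mappability structure, doublets, per-cell quality variation,
batch effects, or read-level sequences. Passing tests therefore
demonstrate the pipeline's statistical machinery and its behaviour
under depth and composition stress — not robustness to the technical
artefacts of real libraries.

## Stability experiments

Clustering accuracy is Goodman-Kruskal's λ on the retained-cell
contingency table, in the type-from-cluster direction (how much the
clustering reduces the error of guessing a cell's true type); the
opposite direction is exposed as an option. λ = 1 iff cluster identity
predicts type without error; λ = 0 when clusters never change the
modal guess. A table whose observations all share one true type has a
vanishing denominator and is scored 1 by convention.

Depth series: fragments are generated at the scenario depth and
subsampled per cell, uniformly without replacement, to each grid
value; cells at or below the target are kept whole (or dropped, by
policy). Composition series: the first type is the target whose
abundance varies (10:70:70 … 50:50:50) at fixed depth. Each grid point
aggregates 20 independent replicates (replicate r re-seeds generation
and subsampling with base seed + r; the region layout stays fixed by
the base scenario), reporting the mean and a normal-approximation 95%
CI (1.96·sd/√n). A replicate that fails to cluster (e.g. no peaks
survive calling at very low depth) is recorded as missing and counted,
never silently dropped.

Desk-scale defaults (150 cells, 2,000 reads/cell, 20 Mb genome) were
chosen so a full stability experiment completes in minutes on one
CPU while preserving the structure of the design; the depth grid used
by the bundled experiments is 100–2,000 reads/cell, and both the grid
and all scenario knobs are configurable. The moderate-signal scenario
used for the depth series sets the signal fraction to 0.3, placing the
lowest depth below the point where type-specific regions survive peak
calling — the measured curve rises from λ ≈ 0.02 at 100 reads/cell to
λ = 1.0 from 500 reads/cell upward.

## Numerical and degenerate-input choices

- Binomial tails use the exact survival function, not a normal
  approximation.
- GC% is binned to integers 0–100 with N bases excluded from numerator
  and denominator; reads of only N count as 0% GC.
- Histograms conserve totals by construction; a degenerate score
  distribution (all equal) occupies one bin of a widened range.
- All-identical occupancy rows yield a single cluster with a warning
  (silhouette is undefined there).
- Empty fragment streams, empty peak sets, and all-discarded
  clusterings raise immediately with stage-specific messages.

## Known limitations

- The internal peak caller is threshold-based and not suitable as a
  substitute for a model-based caller on real data.
- Feature annotation is midpoint-based; peaks spanning annotation
  boundaries receive a single label.
- No doublet handling, barcode error correction, or per-cell TSS
  enrichment scoring.
- The normal-approximation CI is slightly anti-conservative when
  replicate λ values pile up at 1; a bootstrap can be substituted
  downstream from the stored per-replicate values.
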