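"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are normalized on ingestion to the 0-based,
half-open convention ([start, end)); no downstream module performs any
further conversion.  Cell identity is a barcode string; for data shipped
as one file per cell a manifest mode assigns the file stem as barcode.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import pysam

STRANDS = {"+", "-", "."}


class BarcodedFragment(NamedTuple):
    """One mapped fragment with its cell barcode (the atomic input record)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    barcode: str

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeTable:
    """Ordered map of chromosome name -> length (bp).

    The insertion order defines the canonical chromosome order used when
    sorting peaks and laying out genome-wide plots.
    """

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for c, ln in items:
            if ln <= 0:
                raise ValueError(f"non-positive length for chromosome {c!r}")
        self._sizes: dict[str, int] = dict(items)
        self._order: dict[str, int] = {c: i for i, c in enumerate(names)}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and list(self.items()) == list(other.items())

    def items(self):
        return self._sizes.items()

    def order(self, chrom: str) -> int:
        """Rank of a chromosome in the canonical order."""
        return self._order[chrom]

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())


class Peak(NamedTuple):
    """A combined-peak interval with a unitless score."""

    chrom: str
    start: int
    end: int
    score: float


@dataclass
class PeakSet:
    """Ordered, pairwise non-overlapping peak intervals.

    Peaks are sorted by (chromosome order in the genome table, start) and
    serve as the shared coordinate axis of all per-cell analysis.
    """

    peaks: list[Peak]
    genome: GenomeTable | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=self._sort_key)
        prev: Peak | None = None
        for p in self.peaks:
            if p.start < 0 or p.start >= p.end:
                raise ValueError(f"invalid peak interval {p}")
            if prev is not None and prev.chrom == p.chrom and p.start < prev.end:
                raise ValueError(f"overlapping peaks {prev} and {p}; merge first")
            prev = p

    def _sort_key(self, p: Peak):
        if self.genome is not None and p.chrom in self.genome:
            return (0, self.genome.order(p.chrom), p.start)
        return (1, p.chrom, p.start)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    @classmethod
    def from_intervals(
        cls, peaks: Iterable[Peak], genome: GenomeTable | None = None
    ) -> tuple["PeakSet", int]:
        """Build a PeakSet, merging any overlapping input intervals.

        Overlaps are merged by interval union with score = max of the merged
        scores.  Returns the set and the number of merges performed.
        """
        ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        merged: list[Peak] = []
        n_merged = 0
        for p in ordered:
            if merged and merged[-1].chrom == p.chrom and p.start < merged[-1].end:
                last = merged[-1]
                merged[-1] = Peak(
                    last.chrom, last.start, max(last.end, p.end), max(last.score, p.score)
                )
                n_merged += 1
            else:
                merged.append(p)
        return cls(merged, genome=genome), n_merged


@dataclass
class GeneModel:
    """A transcript model: body span plus exon blocks, strand aware."""

    chrom: str
    strand: str
    tx_start: int  # 0-based
    tx_end: int  # exclusive
    exons: list[tuple[int, int]]
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(
                    f"exons of {self.name or self.chrom} must be sorted, "
                    "non-overlapping and contained in the transcript span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass
class BarcodePolicy:
    """Where to find the cell barcode in input records.

    Precedence: explicit column index (BED) > alignment tag (SAM/BAM) >
    read-name suffix after ``name_delimiter``.
    """

    bed_column: int = 6  # 0-based column index in BED-like input
    tag: str = "CB"
    name_delimiter: str = ":"


@dataclass
class FragmentReadReport:
    """Counters accumulated while reading fragments."""

    n_read: int = 0
    n_malformed: int = 0
    n_missing_barcode: int = 0
    n_unknown_chrom: int = 0

    @property
    def n_seen(self) -> int:
        return (
            self.n_read + self.n_malformed + self.n_missing_barcode + self.n_unknown_chrom
        )


DEFAULT_POLICY = BarcodePolicy()
#: record-level error rate above which reading aborts instead of skipping
MALFORMED_TOLERANCE = 0.01


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a two-column chrom.sizes TSV."""
    items: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                items.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad chromosome length") from exc
    return GenomeTable(items)


def _iter_bed_fragments(
    path: str | Path, policy: BarcodePolicy, genome: GenomeTable | None,
    report: FragmentReadReport, fixed_barcode: str | None = None,
) -> Iterator[BarcodedFragment]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            chrom = fields[0]
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            if start < 0 or start >= end:
                report.n_malformed += 1
                continue
            if fixed_barcode is not None:
                barcode = fixed_barcode
            else:
                barcode = (
                    fields[policy.bed_column]
                    if policy.bed_column < len(fields)
                    else ""
                )
            if not barcode or barcode == ".":
                report.n_missing_barcode += 1
                continue
            if genome is not None and chrom not in genome:
                report.n_unknown_chrom += 1
                continue
            report.n_read += 1
            yield BarcodedFragment(chrom, start, end, strand, barcode)


def _iter_alignment_fragments(
    path: str | Path, policy: BarcodePolicy, genome: GenomeTable | None,
    report: FragmentReadReport, fixed_barcode: str | None = None,
) -> Iterator[BarcodedFragment]:
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.reference_start is None:
                report.n_malformed += 1
                continue
            start = rec.reference_start  # pysam is already 0-based
            end = rec.reference_end
            if end is None or end <= start:
                report.n_malformed += 1
                continue
            barcode = fixed_barcode or ""
            if not barcode:
                if rec.has_tag(policy.tag):
                    barcode = str(rec.get_tag(policy.tag))
                elif policy.name_delimiter and rec.query_name and (
                    policy.name_delimiter in rec.query_name
                ):
                    barcode = rec.query_name.rsplit(policy.name_delimiter, 1)[1]
            if not barcode:
                report.n_missing_barcode += 1
                continue
            chrom = rec.reference_name
            if genome is not None and chrom not in genome:
                report.n_unknown_chrom += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            report.n_read += 1
            yield BarcodedFragment(chrom, start, end, strand, barcode)


def read_fragments(
    path: str | Path,
    genome: GenomeTable | None = None,
    policy: BarcodePolicy = DEFAULT_POLICY,
    barcode: str | None = None,
) -> tuple[list[BarcodedFragment], FragmentReadReport]:
    """Read barcoded fragments from BED-like TSV or SAM/BAM.

    Records on chromosomes absent from *genome* are dropped and counted;
    records violating the fragment invariants or lacking a barcode are
    skipped and counted.  If more than ``MALFORMED_TOLERANCE`` of the
    records are record-level errors the read fails.  When *barcode* is
    given (manifest mode) every record receives that barcode, overriding
    the policy.

    Returns the fragment list and the read report.
    """
    path = Path(path)
    report = FragmentReadReport()
    suffix = path.name.lower()
    if suffix.endswith((".sam", ".bam", ".sam.gz")):
        it = _iter_alignment_fragments(path, policy, genome, report, barcode)
    else:
        it = _iter_bed_fragments(path, policy, genome, report, barcode)
    frags = list(it)

    bad = report.n_malformed + report.n_missing_barcode
    if report.n_seen > 0 and bad / report.n_seen > MALFORMED_TOLERANCE:
        raise ValueError(
            f"{path}: {bad} of {report.n_seen} records malformed "
            f"(> {MALFORMED_TOLERANCE:.0%} tolerance)"
        )
    return frags, report


def read_fragments_manifest(
    paths: Sequence[str | Path],
    genome: GenomeTable | None = None,
    policy: BarcodePolicy = DEFAULT_POLICY,
) -> tuple[list[BarcodedFragment], FragmentReadReport]:
    """Read one-file-per-cell inputs, assigning each file stem as barcode."""
    all_frags: list[BarcodedFragment] = []
    total = FragmentReadReport()
    for p in paths:
        p = Path(p)
        stem = p.name
        for ext in (".gz", ".bed", ".sam", ".bam", ".tsv", ".txt"):
            if stem.lower().endswith(ext):
                stem = stem[: -len(ext)]
        frags, rep = read_fragments(p, genome=genome, policy=policy, barcode=stem)
        all_frags.extend(frags)
        total.n_read += rep.n_read
        total.n_malformed += rep.n_malformed
        total.n_missing_barcode += rep.n_missing_barcode
        total.n_unknown_chrom += rep.n_unknown_chrom
    return all_frags, total


def write_fragments(fragments: Iterable[BarcodedFragment], path: str | Path) -> None:
    """Write fragments as BED6+barcode (name '.', score 0)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t.\t0\t{f.strand}\t{f.barcode}\n")


def read_peaks(path: str | Path, genome: GenomeTable | None = None) -> PeakSet:
    """Read a BED3+ peak file (optional 5th-column score) into a PeakSet.

    Overlapping input intervals are merged (union, max score).
    """
    peaks: list[Peak] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
            peaks.append(Peak(fields[0], start, end, score))
    pset, _ = PeakSet.from_intervals(peaks, genome=genome)
    return pset


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write peaks as BED5 (name 'peak_<i>'); round-trips through read_peaks."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:g}\n")


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_genes(path: str | Path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or a refGene-style flat table.

    The refGene dialect accepts rows with or without the leading UCSC bin
    column.  The strand-aware TSS is tx_start for '+' genes and
    tx_end - 1 for '-' genes.
    """
    if dialect not in {"bed12", "refgene_flat"}:
        raise ValueError(f"unknown gene dialect {dialect!r}")
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed12":
                    genes.append(_parse_bed12(fields))
                else:
                    genes.append(_parse_refgene(fields))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_bed12(fields: list[str]) -> GeneModel:
    if len(fields) < 12:
        raise ValueError("BED12 requires 12 columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name, strand = fields[3], fields[5]
    n_blocks = int(fields[9])
    sizes = _parse_int_list(fields[10])
    starts = _parse_int_list(fields[11])
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError("block count disagrees with block lists")
    exons = [(start + s, start + s + z) for s, z in zip(starts, sizes)]
    if exons and exons[-1][1] != end:
        raise ValueError("block sums inconsistent with transcript end")
    return GeneModel(chrom, strand, start, end, exons, name=name)


def _parse_refgene(fields: list[str]) -> GeneModel:
    # UCSC refGene.txt carries a leading integer bin column; refFlat does not.
    off = 0
    if len(fields) >= 11 and fields[3] in {"+", "-"}:
        off = 1
    name, chrom, strand = fields[off], fields[off + 1], fields[off + 2]
    tx_start, tx_end = int(fields[off + 3]), int(fields[off + 4])
    exon_starts = _parse_int_list(fields[off + 8])
    exon_ends = _parse_int_list(fields[off + 9])
    if len(exon_starts) != len(exon_ends):
        raise ValueError("exonStarts/exonEnds length mismatch")
    exons = list(zip(exon_starts, exon_ends))
    return GeneModel(chrom, strand, tx_start, tx_end, exons, name=name)
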