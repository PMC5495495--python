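from __future__ import annotations

import pytest

from scepiqc import BarcodedFragment, GenomeTable, Peak, PeakSet


def frag(chrom="chr1", start=0, end=100, strand="+", barcode="A"):
    return BarcodedFragment(chrom, start, end, strand, barcode)


@pytest.fixture
def toy_genome():
    return GenomeTable({"chrA": 10_000, "chrB": 10_000})


@pytest.fixture
def toy_peaks(toy_genome):
    return PeakSet(
        [
            Peak("chrA", 100, 200, 1.0),
            Peak("chrA", 500, 700, 2.0),
            Peak("chrB", 200, 300, 3.0),
            Peak("chrB", 800, 900, 4.0),
        ],
        genome=toy_genome,
    )
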