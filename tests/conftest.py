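"""Shared fixtures: a small hand-built annotation and peak set."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from sepipe.core_model import GeneModel, GenomeAnnotation, GenomicInterval, Peak

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def iv(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


def peak(chrom, start, end, name="p", signal=1.0, summit=None) -> Peak:
    return Peak(iv(chrom, start, end), name, signal, summit)


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Three genes on chr1 (one minus-strand), one on chr2.

    gA: + strand [10000, 13000), exons at both ends -> TSS 10000
    gB: - strand [40000, 48000), one exon          -> TSS 47999
    gC: + strand [41000, 43000), nested in gB      -> TSS 41000
    gD: + strand [5000, 9000) on chr2              -> TSS 5000
    """
    return GenomeAnnotation(
        [
            GeneModel(
                "gA",
                "chr1",
                "+",
                iv("chr1", 10000, 13000),
                exons=(iv("chr1", 10000, 10500), iv("chr1", 12000, 13000)),
            ),
            GeneModel(
                "gB",
                "chr1",
                "-",
                iv("chr1", 40000, 48000),
                exons=(iv("chr1", 47000, 48000),),
            ),
            GeneModel("gC", "chr1", "+", iv("chr1", 41000, 43000)),
            GeneModel("gD", "chr2", "+", iv("chr2", 5000, 9000)),
        ]
    )
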