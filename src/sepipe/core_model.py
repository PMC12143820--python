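"""Genomic data model shared by every pipeline stage.

All coordinates are 0-based half-open (``[start, end)``), the native BED /
narrowPeak convention; GTF input (1-based closed) is converted at the reader
boundary in :mod:`sepipe.io_formats`.  Strand matters only for deriving a
gene's transcription start site: H3K27ac peaks themselves are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "GenomeAnnotation",
    "IncomparableIntervalsError",
    "overlaps",
    "gap",
    "tss",
]


class IncomparableIntervalsError(ValueError):
    """Two intervals on different chromosomes have no defined distance."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor), used as the peak's representative point."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq peak: an interval plus an enrichment signal.

    ``signal`` is in arbitrary enrichment units (narrowPeak signalValue, or a
    plain BED score).  ``summit_offset``, when present, is the offset of the
    point of highest pileup from ``interval.start``.
    """

    interval: GenomicInterval
    name: str
    signal: float
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name!r}: signal must be >= 0")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"peak {self.name!r}: summit offset {self.summit_offset} "
                f"outside [0, {self.interval.length})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def point(self) -> int:
        """Representative single-base position: summit if known, else midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """One gene with a single representative TSS.

    Exons are sorted, pairwise disjoint and contained in ``span``.  The TSS is
    ``span.start`` on the + strand and ``span.end - 1`` (last covered base) on
    the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.span.chrom != self.chrom:
            raise ValueError(f"gene {self.gene_id!r}: span chrom mismatch")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id!r}: exon chrom mismatch")
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(f"gene {self.gene_id!r}: exon outside span")
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exons must be sorted and disjoint"
                )
            prev_end = exon.end

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1


class GenomeAnnotation:
    """A collection of :class:`GeneModel` with per-chromosome sorted indexes.

    Gene ids must be unique.  Lookup structures (genes per chromosome, sorted
    by TSS) are built once at construction.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: tuple[GeneModel, ...] = tuple(genes)
        by_id: dict[str, GeneModel] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for gene in self.genes:
            if gene.gene_id in by_id:
                raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
            by_id[gene.gene_id] = gene
            by_chrom.setdefault(gene.chrom, []).append(gene)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: (g.tss, g.gene_id))
        self._by_id: Mapping[str, GeneModel] = by_id
        self._by_chrom: Mapping[str, list[GeneModel]] = by_chrom

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_chrom))

    def genes_on(self, chrom: str) -> Sequence[GeneModel]:
        """Genes on ``chrom``, sorted by (TSS, gene_id); empty if none."""
        return self._by_chrom.get(chrom, [])


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two same-chromosome intervals.

    Returns 0 when the intervals overlap or are adjacent; raises
    :class:`IncomparableIntervalsError` for different chromosomes.
    """
    if a.chrom != b.chrom:
        raise IncomparableIntervalsError(
            f"cannot measure gap between {a.chrom} and {b.chrom}"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def tss(gene: GeneModel) -> int:
    """Transcription start site: span.start (+) or span.end - 1 (-)."""
    return gene.tss
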