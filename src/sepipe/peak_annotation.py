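"""Genomic feature classification and gene association for peaks.

A peak is represented by a single point (its summit when known, otherwise its
midpoint) and assigned exactly one feature class with precedence
promoter > exon > intron > distal intergenic.  Nearest-gene lookup minimizes
the distance from the point to a gene TSS; best-peak-per-gene picks the
highest-signal peak near a TSS.  Both rules feed the ChIP/RNA integration.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import GeneModel, GenomeAnnotation, GenomicInterval, Peak

__all__ = [
    "FeatureClass",
    "classify_peak",
    "annotation_distribution",
    "annotate_peaks",
    "nearest_gene",
    "best_peak_for_gene",
]


class FeatureClass(str, Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    DISTAL_INTERGENIC = "distal_intergenic"


def classify_peak(
    peak: Peak,
    annotation: GenomeAnnotation,
    promoter_radius: int = 2000,
) -> FeatureClass:
    """Feature class of the peak's representative point.

    Promoter if the point falls in any ``[tss - r, tss + r + 1)`` window;
    else exon if inside an exon; else intron if inside a gene span; else
    distal intergenic.
    """
    point = peak.point
    genes = annotation.genes_on(peak.chrom)
    in_span = False
    in_exon = False
    for gene in genes:
        t = gene.tss
        if t - promoter_radius <= point < t + promoter_radius + 1:
            return FeatureClass.PROMOTER
        if gene.span.start <= point < gene.span.end:
            in_span = True
            if any(e.start <= point < e.end for e in gene.exons):
                in_exon = True
    if in_exon:
        return FeatureClass.EXON
    if in_span:
        return FeatureClass.INTRON
    return FeatureClass.DISTAL_INTERGENIC


def annotation_distribution(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    promoter_radius: int = 2000,
) -> tuple[Mapping[FeatureClass, float], Mapping[FeatureClass, int]]:
    """Fractions (and counts) of peaks per feature class; fractions sum to 1."""
    if not peaks:
        raise ValueError("cannot summarize an empty peak set")
    counts = {cls: 0 for cls in FeatureClass}
    for peak in peaks:
        counts[classify_peak(peak, annotation, promoter_radius)] += 1
    n = len(peaks)
    fractions = {cls: counts[cls] / n for cls in FeatureClass}
    return fractions, counts


def nearest_gene(
    interval: GenomicInterval, annotation: GenomeAnnotation
) -> tuple[str, int]:
    """Gene whose TSS is closest to the interval midpoint.

    Returns ``(gene_id, signed_distance)`` with distance = TSS - midpoint
    (negative when the TSS lies at lower coordinates than the midpoint).
    Ties are broken by lexicographic gene_id.  Raises if no genes exist on
    the interval's chromosome.
    """
    genes = annotation.genes_on(interval.chrom)
    if not genes:
        raise ValueError(
            f"no genes on {interval.chrom}: region {interval} is unassignable"
        )
    mid = interval.midpoint
    positions = np.array([g.tss for g in genes])
    dist = np.abs(positions - mid)
    best = dist.min()
    tied = [genes[i] for i in np.flatnonzero(dist == best)]
    gene = min(tied, key=lambda g: g.gene_id)
    return gene.gene_id, int(gene.tss - mid)


def best_peak_for_gene(
    gene: GeneModel,
    peaks: Sequence[Peak],
    window: int = 100_000,
) -> Peak | None:
    """Highest-signal peak whose midpoint is within ``tss ± window``.

    Signal ties are broken by leftmost start; None when no peak qualifies.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = gene.tss
    candidates = [
        p
        for p in peaks
        if p.chrom == gene.chrom and t - window <= p.interval.midpoint <= t + window
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda p: (p.signal, -p.interval.start))


def annotate_peaks(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    promoter_radius: int = 2000,
) -> pd.DataFrame:
    """Per-peak table: id, feature class, nearest gene and signed distance."""
    rows = []
    for peak in peaks:
        cls = classify_peak(peak, annotation, promoter_radius)
        try:
            gene_id, distance = nearest_gene(peak.interval, annotation)
        except ValueError:
            gene_id, distance = None, None
        rows.append(
            {
                "peak": peak.name,
                "chrom": peak.chrom,
                "start": peak.interval.start,
                "end": peak.interval.end,
                "feature_class": cls.value,
                "nearest_gene": gene_id,
                "tss_distance": distance,
            }
        )
    return pd.DataFrame(rows)
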