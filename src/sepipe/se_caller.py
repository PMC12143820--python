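"""ROSE-style super-enhancer calling.

The procedure: (1) drop peaks lying entirely inside a ±2 kb window around any
transcription start site, (2) stitch the surviving peaks when separated by at
most 12.5 kb, (3) rank stitched enhancers by total signal and min-max scale
both rank and signal to [0, 1], (4) find the point where a slope-1 line is
tangent to the scaled curve; enhancers whose signal exceeds the signal at the
tangency point are super-enhancers, the rest are typical enhancers.

For a convex non-decreasing scaled curve the tangency point is the minimizer
of ``scaled_y - scaled_x``: the slope-1 line through it supports the curve
from below, so every other point lies on or above ``y = x + (y* - x*)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import GenomeAnnotation, GenomicInterval, Peak, gap
from .io_formats import SignalTrack, signal_over

__all__ = [
    "SECallParams",
    "StitchedEnhancer",
    "SECallResult",
    "filter_tss_proximal",
    "stitch_peaks",
    "rank_and_scale",
    "tangent_cutoff",
    "call_superenhancers",
]


@dataclass(frozen=True)
class SECallParams:
    """Tunable parameters of the super-enhancer definition.

    ``tss_exclusion_radius``: peaks fully inside TSS ± radius are not
    enhancers.  ``stitch_gap``: maximum gap (inclusive) joining neighbouring
    peaks into one stitched enhancer.  ``min_points_for_cutoff``: minimum
    number of stitched enhancers required to place a tangent cutoff.
    """

    tss_exclusion_radius: int = 2000
    stitch_gap: int = 12500
    min_points_for_cutoff: int = 3

    def __post_init__(self) -> None:
        if self.tss_exclusion_radius <= 0 or self.stitch_gap <= 0:
            raise ValueError("radii and gaps must be positive")
        if self.min_points_for_cutoff <= 0:
            raise ValueError("min_points_for_cutoff must be positive")


@dataclass(frozen=True)
class StitchedEnhancer:
    """A maximal chain of peaks with consecutive gaps <= the stitch gap."""

    id: str
    chrom: str
    span: GenomicInterval
    members: tuple[Peak, ...]
    total_signal: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("stitched enhancer needs >= 1 member peak")

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class SECallResult:
    """Ranked enhancer curve with the slope-1 tangent cutoff applied.

    ``enhancers`` are sorted ascending by total signal (rank 1 = lowest);
    ``scaled_x``/``scaled_y`` are the min-max-normalized rank and signal;
    ``is_super[i]`` iff ``enhancers[i].total_signal > cutoff_signal``.
    ``degenerate`` marks flat or too-small curves on which no cutoff could
    be placed (then nothing is super).
    """

    enhancers: tuple[StitchedEnhancer, ...]
    scaled_x: np.ndarray
    scaled_y: np.ndarray
    cutoff_signal: float
    tangency_rank: int
    is_super: np.ndarray
    degenerate: bool = False

    @property
    def super_enhancers(self) -> tuple[StitchedEnhancer, ...]:
        return tuple(
            e for e, flag in zip(self.enhancers, self.is_super) if flag
        )

    @property
    def typical_enhancers(self) -> tuple[StitchedEnhancer, ...]:
        return tuple(
            e for e, flag in zip(self.enhancers, self.is_super) if not flag
        )

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def to_frame(self) -> pd.DataFrame:
        """Ranked-curve table: one row per enhancer, ascending rank."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.enhancers) + 1),
                "id": [e.id for e in self.enhancers],
                "chrom": [e.chrom for e in self.enhancers],
                "start": [e.span.start for e in self.enhancers],
                "end": [e.span.end for e in self.enhancers],
                "n_members": [e.n_members for e in self.enhancers],
                "scaled_x": self.scaled_x,
                "scaled_y": self.scaled_y,
                "total_signal": [e.total_signal for e in self.enhancers],
                "is_super": self.is_super,
            }
        )


def filter_tss_proximal(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    radius: int = 2000,
) -> list[Peak]:
    """Remove peaks lying entirely within TSS ± radius of any gene.

    The exclusion window is ``[tss - radius, tss + radius + 1)`` (both edge
    bases covered); a peak is removed only when fully contained.  Input order
    is preserved for the survivors.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(annotation) == 0:
        warnings.warn("empty annotation: no TSS filtering applied")
        return list(peaks)
    tss_by_chrom: dict[str, np.ndarray] = {
        chrom: np.array([g.tss for g in annotation.genes_on(chrom)])
        for chrom in annotation.chromosomes
    }
    kept: list[Peak] = []
    for peak in peaks:
        positions = tss_by_chrom.get(peak.chrom)
        if positions is None:
            kept.append(peak)
            continue
        # contained in [tss - r, tss + r + 1)  <=>  exists tss with
        # tss - r <= start  and  end <= tss + r + 1
        contained = np.any(
            (positions - radius <= peak.interval.start)
            & (peak.interval.end <= positions + radius + 1)
        )
        if not contained:
            kept.append(peak)
    return kept


def stitch_peaks(
    peaks: Sequence[Peak], stitch_gap: int = 12500
) -> list[StitchedEnhancer]:
    """Merge peaks separated by at most ``stitch_gap`` bases (inclusive).

    Output equals the connected components of the graph joining peaks whose
    gap is <= the threshold; a single left-to-right sweep per chromosome
    suffices because components of intervals are contiguous in start order.
    Enhancer ids encode the stitched span, so they are stable under input
    permutation.
    """
    if stitch_gap <= 0:
        raise ValueError("stitch_gap must be positive")
    by_chrom: dict[str, list[Peak]] = {}
    for peak in peaks:
        by_chrom.setdefault(peak.chrom, []).append(peak)
    enhancers: list[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(
            by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end, p.name)
        )
        chain: list[Peak] = []
        chain_end = -1
        for peak in chrom_peaks:
            if chain and peak.interval.start - chain_end > stitch_gap:
                enhancers.append(_finish_chain(chrom, chain))
                chain = []
                chain_end = -1
            chain.append(peak)
            chain_end = max(chain_end, peak.interval.end)
        if chain:
            enhancers.append(_finish_chain(chrom, chain))
    return enhancers


def _finish_chain(chrom: str, chain: list[Peak]) -> StitchedEnhancer:
    start = min(p.interval.start for p in chain)
    end = max(p.interval.end for p in chain)
    return StitchedEnhancer(
        id=f"{chrom}:{start}-{end}",
        chrom=chrom,
        span=GenomicInterval(chrom, start, end),
        members=tuple(chain),
        total_signal=float(sum(p.signal for p in chain)),
    )


def rank_and_scale(
    enhancers: Sequence[StitchedEnhancer],
) -> tuple[list[StitchedEnhancer], np.ndarray, np.ndarray, bool]:
    """Sort enhancers ascending by signal and min-max scale rank and signal.

    Returns ``(ordered, scaled_x, scaled_y, degenerate)`` where
    ``scaled_x[i] = i / (n - 1)`` and ``scaled_y`` is the min-max-normalized
    signal.  Ties in signal are broken by (chrom, start) for determinism.
    A flat curve (all signals equal, or n = 1) is flagged degenerate with
    all ``scaled_y = 0``.
    """
    if not enhancers:
        raise ValueError("cannot rank an empty enhancer set")
    ordered = sorted(
        enhancers, key=lambda e: (e.total_signal, e.chrom, e.span.start)
    )
    n = len(ordered)
    signals = np.array([e.total_signal for e in ordered], dtype=float)
    scaled_x = np.arange(n, dtype=float) / (n - 1) if n > 1 else np.zeros(1)
    span = signals[-1] - signals[0]
    if n == 1 or span == 0:
        return ordered, scaled_x, np.zeros(n), True
    scaled_y = (signals - signals[0]) / span
    return ordered, scaled_x, scaled_y, False


def tangent_cutoff(
    scaled_x: np.ndarray,
    scaled_y: np.ndarray,
    signals: np.ndarray,
) -> tuple[float, int]:
    """Slope-1 tangency of the scaled rank/signal curve.

    The tangency point minimizes ``scaled_y - scaled_x``; among exact ties
    the point with the greatest ``scaled_y`` wins (conservative: fewer
    super-enhancers).  Returns ``(cutoff_signal, tangency_rank)`` where the
    cutoff is the un-scaled signal at the tangency point and ranks are
    1-based.
    """
    diffs = scaled_y - scaled_x
    best = diffs.min()
    # ties -> greatest scaled_y; scaled_y is non-decreasing in rank, so the
    # last tied index has the greatest scaled_y
    tied = np.flatnonzero(diffs == best)
    idx = int(tied[np.argmax(scaled_y[tied])])
    return float(signals[idx]), idx + 1


def call_superenhancers(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    params: SECallParams = SECallParams(),
    signal_track: SignalTrack | None = None,
) -> SECallResult:
    """Full super-enhancer call: filter, stitch, rank, tangent cutoff.

    By default a stitched enhancer's signal is the sum of its member peak
    signals; pass ``signal_track`` to score each stitched span by bedGraph
    area instead.  Super status is strict: the tangency enhancer itself is
    typical (only enhancers *above* the point of tangency are super).
    """
    kept = filter_tss_proximal(peaks, annotation, params.tss_exclusion_radius)
    stitched = stitch_peaks(kept, params.stitch_gap)
    if not stitched:
        warnings.warn("no enhancers remain after TSS filtering")
        return SECallResult(
            enhancers=(),
            scaled_x=np.zeros(0),
            scaled_y=np.zeros(0),
            cutoff_signal=float("nan"),
            tangency_rank=0,
            is_super=np.zeros(0, dtype=bool),
            degenerate=True,
        )
    if signal_track is not None:
        stitched = [
            StitchedEnhancer(
                id=e.id,
                chrom=e.chrom,
                span=e.span,
                members=e.members,
                total_signal=signal_over(signal_track, e.span),
            )
            for e in stitched
        ]
    ordered, scaled_x, scaled_y, degenerate = rank_and_scale(stitched)
    signals = np.array([e.total_signal for e in ordered], dtype=float)
    if degenerate or len(ordered) < params.min_points_for_cutoff:
        if not degenerate:
            warnings.warn(
                f"only {len(ordered)} enhancers "
                f"(< {params.min_points_for_cutoff}): no cutoff placed"
            )
        else:
            warnings.warn("flat signal curve: no cutoff placed")
        cutoff = float(signals[-1])  # nothing is strictly above the maximum
        return SECallResult(
            enhancers=tuple(ordered),
            scaled_x=scaled_x,
            scaled_y=scaled_y,
            cutoff_signal=cutoff,
            tangency_rank=len(ordered),
            is_super=np.zeros(len(ordered), dtype=bool),
            degenerate=True,
        )
    cutoff, tangency_rank = tangent_cutoff(scaled_x, scaled_y, signals)
    return SECallResult(
        enhancers=tuple(ordered),
        scaled_x=scaled_x,
        scaled_y=scaled_y,
        cutoff_signal=cutoff,
        tangency_rank=tangency_rank,
        is_super=signals > cutoff,
    )
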