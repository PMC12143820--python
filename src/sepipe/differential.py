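"""Two-condition differential analysis of peak signal and gene expression.

Peak side: consensus regions are scored per condition and tested with an
exact conditional binomial test on pooled (rounded) counts — the classic
dependency-light test for two-library count comparison.  A region is called
up/down when ``|log2FC| > 1`` and ``P < 0.05`` (strict, as printed).

Expression side: FPKM-based fold change with a pseudocount; genes are called
differentially expressed at fold change > 2 and P < 0.05 from a two-sided
Welch t-test on log2(FPKM + 1) across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import GenomicInterval, Peak

__all__ = [
    "ConsensusRegion",
    "DifferentialRegion",
    "ExpressionRecord",
    "build_consensus_regions",
    "signal_in_regions",
    "differential_signal_test",
    "classify_call",
    "classify_regions",
    "differential_regions",
    "fpkm",
    "expression_differential",
    "expression_table",
]

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass(frozen=True)
class ConsensusRegion:
    """A merged region from the union of two peak sets, with contributors."""

    region: GenomicInterval
    peak_names: tuple[str, ...]


@dataclass(frozen=True)
class DifferentialRegion:
    """A consensus region with per-condition counts and its test result."""

    region: GenomicInterval
    count_a: float
    count_b: float
    lib_a: float
    lib_b: float
    log2fc: float
    p_value: float
    call: str


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene expression comparison (condition b vs a)."""

    gene_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    p_value: float
    direction: str


def build_consensus_regions(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> list[ConsensusRegion]:
    """Merge the union of both peak sets where overlapping.

    Adjacent-but-not-overlapping peaks stay separate (half-open semantics).
    Each output region records the names of its contributing peaks.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for peak in list(peaks_a) + list(peaks_b):
        by_chrom.setdefault(peak.chrom, []).append(peak)
    regions: list[ConsensusRegion] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur_start = cur_end = None
        cur_names: list[str] = []
        for peak in chrom_peaks:
            if cur_end is not None and peak.interval.start < cur_end:
                cur_end = max(cur_end, peak.interval.end)
                cur_names.append(peak.name)
            else:
                if cur_end is not None:
                    regions.append(
                        ConsensusRegion(
                            GenomicInterval(chrom, cur_start, cur_end),
                            tuple(dict.fromkeys(cur_names)),
                        )
                    )
                cur_start, cur_end = peak.interval.start, peak.interval.end
                cur_names = [peak.name]
        if cur_end is not None:
            regions.append(
                ConsensusRegion(
                    GenomicInterval(chrom, cur_start, cur_end),
                    tuple(dict.fromkeys(cur_names)),
                )
            )
    return regions


def signal_in_regions(
    regions: Sequence[ConsensusRegion], peaks: Sequence[Peak]
) -> np.ndarray:
    """Summed signal of peaks overlapping each region (one value per region)."""
    by_chrom: dict[str, list[Peak]] = {}
    for peak in peaks:
        by_chrom.setdefault(peak.chrom, []).append(peak)
    for chrom_peaks in by_chrom.values():
        chrom_peaks.sort(key=lambda p: p.interval.start)
    out = np.zeros(len(regions))
    for i, consensus in enumerate(regions):
        region = consensus.region
        total = 0.0
        for peak in by_chrom.get(region.chrom, []):
            if peak.interval.start >= region.end:
                break
            if peak.interval.end > region.start:
                total += peak.signal
        out[i] = total
    return out


def differential_signal_test(
    count_a: float,
    count_b: float,
    lib_a: float,
    lib_b: float,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Library-normalized log2 fold change and exact binomial p-value.

    ``log2fc = log2(((count_b + pc) / lib_b) / ((count_a + pc) / lib_a))``.
    The p-value is the two-sided exact binomial probability of ``count_b``
    successes in ``count_a + count_b`` trials (counts rounded to integers)
    with null success probability ``lib_b / (lib_a + lib_b)`` — the
    conditional test for comparing two count libraries.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    # difference of two symmetric terms: swapping conditions negates the
    # value bit-exactly
    log2fc = float(
        np.log2((count_b + pseudocount) * lib_a)
        - np.log2((count_a + pseudocount) * lib_b)
    )
    ka, kb = int(round(count_a)), int(round(count_b))
    n = ka + kb
    if n == 0:
        return log2fc, 1.0
    p0 = lib_b / (lib_a + lib_b)
    p_value = float(stats.binomtest(kb, n, p0).pvalue)
    return log2fc, p_value


def classify_call(
    log2fc: float,
    p_value: float,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> str:
    """Strict-threshold call: up/down iff |log2fc| > threshold and p < gate."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if p_value < p_threshold:
        if log2fc > fc_threshold:
            return UP
        if log2fc < -fc_threshold:
            return DOWN
    return NS


def classify_regions(
    results: Iterable[tuple[float, float]],
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> tuple[list[str], Mapping[str, int]]:
    """Apply :func:`classify_call` to (log2fc, p) pairs; return calls + counts."""
    calls = [classify_call(fc, p, fc_threshold, p_threshold) for fc, p in results]
    counts = {UP: calls.count(UP), DOWN: calls.count(DOWN), NS: calls.count(NS)}
    return calls, counts


def differential_regions(
    regions: Sequence[ConsensusRegion],
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: float | None = None,
    lib_b: float | None = None,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> list[DifferentialRegion]:
    """Test and classify every consensus region (b vs a).

    Library sizes default to the total counts per condition.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if lib_a is None:
        lib_a = float(counts_a.sum())
    if lib_b is None:
        lib_b = float(counts_b.sum())
    out = []
    for region, ca, cb in zip(regions, counts_a, counts_b):
        log2fc, p = differential_signal_test(ca, cb, lib_a, lib_b, pseudocount)
        out.append(
            DifferentialRegion(
                region=region.region,
                count_a=float(ca),
                count_b=float(cb),
                lib_a=lib_a,
                lib_b=lib_b,
                log2fc=log2fc,
                p_value=p,
                call=classify_call(log2fc, p, fc_threshold, p_threshold),
            )
        )
    return out


def fpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count * 1e9 / (library_size * gene_length_bp)


def expression_differential(
    fpkm_a: Sequence[float],
    fpkm_b: Sequence[float],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[float, float, float, float, str]:
    """Fold change and significance of expression between two groups.

    Returns ``(mean_a, mean_b, fold_change, p_value, direction)`` with
    ``fold_change = (mean_b + pc) / (mean_a + pc)`` and p from a two-sided
    Welch t-test on log2(FPKM + pc) when both groups have >= 2 replicates
    (otherwise p = 1 with a warning).  Direction: up if fold_change >
    fc_threshold, down if < 1/fc_threshold, gated by p < p_threshold.
    """
    a = np.asarray(fpkm_a, dtype=float)
    b = np.asarray(fpkm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs >= 1 replicate")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold_change = (mean_b + pseudocount) / (mean_a + pseudocount)
    if a.size >= 2 and b.size >= 2:
        la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
        if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
            p_value = 1.0  # identical constant groups: no evidence of change
        else:
            p_value = float(stats.ttest_ind(lb, la, equal_var=False).pvalue)
            if np.isnan(p_value):
                p_value = 1.0
    else:
        warnings.warn("fewer than 2 replicates in a group: p-value set to 1")
        p_value = 1.0
    if p_value < p_threshold and fold_change > fc_threshold:
        direction = UP
    elif p_value < p_threshold and fold_change < 1.0 / fc_threshold:
        direction = DOWN
    else:
        direction = NS
    return mean_a, mean_b, fold_change, p_value, direction


def expression_table(
    fpkm_frame: pd.DataFrame,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> list[ExpressionRecord]:
    """Per-gene :class:`ExpressionRecord` list from a replicate FPKM table.

    ``fpkm_frame`` must carry a ``gene_id`` column plus one column per
    replicate named in ``cols_a`` / ``cols_b``.
    """
    records = []
    for _, row in fpkm_frame.iterrows():
        mean_a, mean_b, fc, p, direction = expression_differential(
            [row[c] for c in cols_a],
            [row[c] for c in cols_b],
            fc_threshold,
            p_threshold,
            pseudocount,
        )
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                mean_a=mean_a,
                mean_b=mean_b,
                fold_change=fc,
                p_value=p,
                direction=direction,
            )
        )
    return records
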