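"""Synthetic two-condition enhancer landscapes with ground truth.

The generator emulates the statistical structure the pipeline assumes: a
small genome with non-overlapping genes; background H3K27ac peaks with
log-normal signals, a fraction of them planted inside TSS ± 2 kb windows;
planted "typical" clusters of 2-3 ordinary peaks; planted super-enhancer
clusters of several high-signal peaks whose intra-cluster gaps always
satisfy the 12.5 kb stitching rule; and a second condition in which a chosen
subset of super clusters gains or loses signal by a fixed fold, with the
nearest gene of each such cluster receiving a concordant expression change
in a negative-binomial count table.

Everything is driven by one integer seed; identical configs produce
byte-identical fixture files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import GeneModel, GenomeAnnotation, GenomicInterval, Peak
from .differential import DOWN, UP, fpkm
from .io_formats import write_gtf, write_table
from .peak_annotation import nearest_gene

__all__ = [
    "SimulationConfig",
    "PlantedCluster",
    "GroundTruth",
    "simulate_landscape",
    "simulate_expression",
    "write_fixture",
    "verify_fixture",
]

NONE = "none"

# clearance separating planted clusters from everything else; anything
# farther than the stitch gap cannot merge into a cluster
_CLUSTER_MARGIN = 13_000
# clearance between gene spans and cluster spans so that no TSS ± 2 kb
# window can swallow a planted cluster peak
_GENE_MARGIN = 2_500


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions.

    Signals are log-normal (heavy-tailed ChIP enrichment); expression counts
    are negative-binomial with mean ``expr_mean`` and dispersion
    ``expr_dispersion`` (variance mu + alpha mu^2).  Differential super
    clusters are split evenly up/down and change by ``differential_effect``
    in condition b; their nearest genes change expression concordantly for a
    ``concordant_fraction`` of them.
    """

    seed: int = 42
    n_chrom: int = 4
    chrom_length: int = 25_000_000
    n_genes: int = 3000
    n_background_peaks: int = 2000
    n_typical_enhancers: int = 100
    n_super_clusters: int = 30
    peaks_per_cluster: tuple[int, int] = (3, 8)
    intra_cluster_gap: tuple[int, int] = (500, 11_000)
    background_signal_mu: float = math.log(50.0)
    background_signal_sigma: float = 0.07
    se_signal_multiplier: float = 5.0
    n_differential_ses: int = 8
    differential_effect: float = 4.0
    tss_proximal_fraction: float = 0.15
    expr_mean: float = 200.0
    expr_dispersion: float = 0.05
    n_replicates: int = 3
    concordant_fraction: float = 1.0
    gene_length: tuple[int, int] = (2_000, 20_000)
    peak_width: tuple[int, int] = (500, 2_000)

    def __post_init__(self) -> None:
        counts = (
            self.n_chrom,
            self.n_genes,
            self.n_background_peaks,
            self.n_typical_enhancers,
            self.n_super_clusters,
            self.n_differential_ses,
        )
        if any(c < 0 for c in counts) or self.n_chrom == 0:
            raise ValueError("counts must be non-negative (n_chrom positive)")
        if self.intra_cluster_gap[1] > 12_500:
            raise ValueError("intra-cluster gaps must stay within the stitch gap")
        if self.se_signal_multiplier <= 1 or self.differential_effect <= 1:
            raise ValueError("effect sizes must be > 1")
        if not 0 <= self.tss_proximal_fraction <= 1:
            raise ValueError("tss_proximal_fraction must be in [0, 1]")
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must be in [0, 1]")
        if self.n_differential_ses > self.n_super_clusters:
            raise ValueError("cannot have more differential SEs than clusters")


@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: str
    span: GenomicInterval
    kind: str  # "super" | "typical"
    direction: str  # "up" | "down" | "none"
    nearest_gene: str | None = None


@dataclass
class GroundTruth:
    """Planted structure: cluster spans, differential labels, gene effects."""

    clusters: list[PlantedCluster]
    gene_effects: dict[str, tuple[str, float]]

    @property
    def super_clusters(self) -> list[PlantedCluster]:
        return [c for c in self.clusters if c.kind == "super"]

    @property
    def differential_clusters(self) -> list[PlantedCluster]:
        return [c for c in self.super_clusters if c.direction != NONE]


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _place_blocks(
    rng: np.random.Generator, lengths: Sequence[int], domain: int
) -> list[int]:
    """Non-overlapping uniform placement of blocks inside [0, domain)."""
    total = int(sum(lengths))
    free = domain - total
    if free <= 0:
        raise ValueError(
            f"infeasible placement: {total} bases of blocks on a "
            f"{domain}-base chromosome"
        )
    anchors = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = []
    consumed = 0
    for anchor, length in zip(anchors, lengths):
        starts.append(int(anchor) + consumed)
        consumed += int(length)
    return starts


def _sample_cluster_layout(
    rng: np.random.Generator, config: SimulationConfig, kind: str
) -> tuple[list[int], list[int], list[int]]:
    """Widths, gaps and relative starts of one cluster's peaks."""
    if kind == "super":
        lo, hi = config.peaks_per_cluster
        n_peaks = int(rng.integers(lo, hi + 1))
    else:
        # a typical enhancer is a single short element; only super-enhancers
        # are multi-peak clusters
        n_peaks = 1
    widths = rng.integers(*config.peak_width, size=n_peaks, endpoint=True)
    gaps = rng.integers(*config.intra_cluster_gap, size=n_peaks - 1, endpoint=True)
    rel = [0]
    for width, gap_ in zip(widths[:-1], gaps):
        rel.append(rel[-1] + int(width) + int(gap_))
    return list(map(int, widths)), list(map(int, gaps)), rel


def _overlaps_any(
    start: int, end: int, spans: Sequence[tuple[int, int]]
) -> bool:
    return any(start < e and s < end for s, e in spans)


def simulate_landscape(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, list[Peak], list[Peak], GroundTruth]:
    """Generate (annotation, peaks_a, peaks_b, ground truth).

    Condition b equals condition a except that the chosen differential super
    clusters have their member signals multiplied (up) or divided (down) by
    ``differential_effect``.  Differential clusters are chosen so that their
    nearest genes are pairwise distinct and not shared with any other super
    cluster, making the planted SE-gene map unambiguous.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]

    per_chrom_super = _split_counts(config.n_super_clusters, config.n_chrom)
    per_chrom_typical = _split_counts(config.n_typical_enhancers, config.n_chrom)
    per_chrom_genes = _split_counts(config.n_genes, config.n_chrom)
    n_proximal = round(config.tss_proximal_fraction * config.n_background_peaks)
    per_chrom_bg = _split_counts(config.n_background_peaks - n_proximal, config.n_chrom)
    per_chrom_prox = _split_counts(n_proximal, config.n_chrom)

    genes: list[GeneModel] = []
    peaks_a: list[Peak] = []
    clusters: list[PlantedCluster] = []
    cluster_members: dict[str, list[str]] = {}

    for ci, chrom in enumerate(chrom_names):
        # --- planted clusters (super + typical), placed first with margin ---
        layouts = []
        for k in range(per_chrom_super[ci]):
            layouts.append(("super", f"se_{chrom}_{k}", *_sample_cluster_layout(rng, config, "super")))
        for k in range(per_chrom_typical[ci]):
            layouts.append(("typical", f"te_{chrom}_{k}", *_sample_cluster_layout(rng, config, "typical")))
        block_lengths = [
            rel[-1] + widths[-1] + 2 * _CLUSTER_MARGIN
            for _, _, widths, _, rel in layouts
        ]
        block_starts = _place_blocks(rng, block_lengths, config.chrom_length)
        cluster_spans: list[tuple[int, int]] = []
        for (kind, cid, widths, _, rel), bstart in zip(layouts, block_starts):
            cstart = bstart + _CLUSTER_MARGIN
            members = []
            for j, (width, offset) in enumerate(zip(widths, rel)):
                name = f"{cid}_p{j}"
                interval = GenomicInterval(chrom, cstart + offset, cstart + offset + width)
                signal = float(rng.lognormal(config.background_signal_mu, config.background_signal_sigma))
                if kind == "super":
                    signal *= config.se_signal_multiplier
                peaks_a.append(Peak(interval, name, signal, width // 2))
                members.append(name)
            span = GenomicInterval(chrom, cstart, cstart + rel[-1] + widths[-1])
            clusters.append(PlantedCluster(cid, span, kind, NONE))
            cluster_members[cid] = members
            cluster_spans.append((span.start, span.end))

        # --- genes, kept clear of cluster spans so planted peaks survive
        # the TSS filter ---
        gene_spans: list[tuple[int, int]] = []
        forbidden = [(s - _GENE_MARGIN, e + _GENE_MARGIN) for s, e in cluster_spans]
        for gi in range(per_chrom_genes[ci]):
            for _attempt in range(1000):
                length = int(rng.integers(*config.gene_length, endpoint=True))
                start = int(rng.integers(0, config.chrom_length - length))
                end = start + length
                if _overlaps_any(start, end, forbidden):
                    continue
                if _overlaps_any(start, end, gene_spans):
                    continue
                gene_spans.append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                # 1-4 exons spread over the span
                n_exons = int(rng.integers(1, 5))
                bounds = np.sort(rng.integers(start, end + 1, size=2 * n_exons))
                exons = tuple(
                    GenomicInterval(chrom, int(s), int(e))
                    for s, e in zip(bounds[::2], bounds[1::2])
                    if e > s
                )
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{chrom}_{gi:04d}",
                        chrom=chrom,
                        strand=strand,
                        span=GenomicInterval(chrom, start, end),
                        exons=exons,
                    )
                )
                break
            else:
                raise ValueError(
                    f"infeasible placement: could not fit gene {gi} on {chrom}"
                )

        chrom_genes = [g for g in genes if g.chrom == chrom]

        # --- background peaks away from clusters and from each other ---
        # isolation beyond the stitch range keeps every multi-peak cluster a
        # labelled planted one: unlabelled accidental clusters would make the
        # ground truth ambiguous
        guarded = [
            (s - _CLUSTER_MARGIN, e + _CLUSTER_MARGIN) for s, e in cluster_spans
        ]
        for bi in range(per_chrom_bg[ci]):
            for _attempt in range(1000):
                width = int(rng.integers(*config.peak_width, endpoint=True))
                start = int(rng.integers(0, config.chrom_length - width))
                if _overlaps_any(start, start + width, guarded):
                    continue
                signal = float(
                    rng.lognormal(config.background_signal_mu, config.background_signal_sigma)
                )
                peaks_a.append(
                    Peak(
                        GenomicInterval(chrom, start, start + width),
                        f"bg_{chrom}_{bi:05d}",
                        signal,
                        width // 2,
                    )
                )
                guarded.append(
                    (start - _CLUSTER_MARGIN, start + width + _CLUSTER_MARGIN)
                )
                break
            else:
                raise ValueError(
                    f"infeasible placement: background peak {bi} on {chrom}"
                )

        # --- TSS-proximal background peaks, fully inside TSS ± 2 kb ---
        for pi in range(per_chrom_prox[ci]):
            gene = chrom_genes[int(rng.integers(0, len(chrom_genes)))]
            t = gene.tss
            width = min(int(rng.integers(*config.peak_width, endpoint=True)), 4000)
            lo = max(0, t - 2000)
            hi = min(config.chrom_length, t + 2001)
            start = int(rng.integers(lo, hi - width))
            signal = float(
                rng.lognormal(config.background_signal_mu, config.background_signal_sigma)
            )
            peaks_a.append(
                Peak(
                    GenomicInterval(chrom, start, start + width),
                    f"prox_{chrom}_{pi:05d}",
                    signal,
                    width // 2,
                )
            )

    annotation = GenomeAnnotation(genes)

    # --- choose differential super clusters with unambiguous nearest genes ---
    super_idx = [i for i, c in enumerate(clusters) if c.kind == "super"]
    nearest: dict[int, str] = {}
    for i in super_idx:
        gene_id, _ = nearest_gene(clusters[i].span, annotation)
        nearest[i] = gene_id
    gene_claims: dict[str, int] = {}
    for i in super_idx:
        gene_claims[nearest[i]] = gene_claims.get(nearest[i], 0) + 1
    order = rng.permutation(len(super_idx))
    chosen: list[int] = []
    for j in order:
        i = super_idx[int(j)]
        if gene_claims[nearest[i]] == 1:  # no other super cluster shares it
            chosen.append(i)
        if len(chosen) == config.n_differential_ses:
            break
    if len(chosen) < config.n_differential_ses:
        # relax: allow shared nearest genes but keep them pairwise distinct
        used = {nearest[i] for i in chosen}
        for j in order:
            i = super_idx[int(j)]
            if i not in chosen and nearest[i] not in used:
                chosen.append(i)
                used.add(nearest[i])
            if len(chosen) == config.n_differential_ses:
                break
    if len(chosen) < config.n_differential_ses:
        raise ValueError(
            "infeasible: not enough super clusters with distinct nearest genes"
        )

    directions = {i: (UP if k % 2 == 0 else DOWN) for k, i in enumerate(chosen)}
    for i in chosen:
        c = clusters[i]
        clusters[i] = replace(c, direction=directions[i], nearest_gene=nearest[i])
    for i in super_idx:
        if i not in chosen:
            clusters[i] = replace(clusters[i], nearest_gene=nearest[i])

    # --- condition b: apply the differential effect to member peaks ---
    effect_by_peak: dict[str, float] = {}
    for i in chosen:
        factor = (
            config.differential_effect
            if directions[i] == UP
            else 1.0 / config.differential_effect
        )
        for name in cluster_members[clusters[i].cluster_id]:
            effect_by_peak[name] = factor
    peaks_b = [
        Peak(p.interval, p.name, p.signal * effect_by_peak.get(p.name, 1.0), p.summit_offset)
        for p in peaks_a
    ]

    # --- planted expression effects on concordant nearest genes ---
    n_concordant = round(config.concordant_fraction * len(chosen))
    concordant_idx = [int(chosen[k]) for k in rng.permutation(len(chosen))[:n_concordant]]
    gene_effects = {
        nearest[i]: (directions[i], config.differential_effect)
        for i in concordant_idx
    }

    return annotation, peaks_a, peaks_b, GroundTruth(clusters, gene_effects)


def simulate_expression(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count and FPKM tables for both conditions.

    Returns ``(counts, fpkm_table)``; both have a ``gene_id`` column plus
    replicate columns ``a_1..a_n`` and ``b_1..b_n``.  Genes carrying a
    planted effect have their condition-b mean multiplied (up) or divided
    (down) by the planted fold.  FPKM uses gene span lengths and the
    per-replicate total count as library size.
    """
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = [g.gene_id for g in annotation]
    lengths = np.array([g.span.length for g in annotation], dtype=float)
    base_mean = rng.lognormal(math.log(config.expr_mean), 1.0, size=len(gene_ids))
    mean_a = base_mean.copy()
    mean_b = base_mean.copy()
    for gi, gene_id in enumerate(gene_ids):
        effect = truth.gene_effects.get(gene_id)
        if effect is not None:
            direction, fold = effect
            mean_b[gi] = mean_b[gi] * fold if direction == UP else mean_b[gi] / fold

    def _draw(mu: np.ndarray) -> np.ndarray:
        n = 1.0 / config.expr_dispersion
        p = n / (n + mu)
        return rng.negative_binomial(
            n, p[:, None], size=(len(mu), config.n_replicates)
        )

    counts_a = _draw(mean_a)
    counts_b = _draw(mean_b)
    cols_a = [f"a_{r + 1}" for r in range(config.n_replicates)]
    cols_b = [f"b_{r + 1}" for r in range(config.n_replicates)]
    counts = pd.DataFrame({"gene_id": gene_ids})
    for j, col in enumerate(cols_a):
        counts[col] = counts_a[:, j]
    for j, col in enumerate(cols_b):
        counts[col] = counts_b[:, j]

    fpkm_table = pd.DataFrame({"gene_id": gene_ids})
    for j, col in enumerate(cols_a):
        lib = float(counts_a[:, j].sum())
        fpkm_table[col] = [
            fpkm(c, l, lib) for c, l in zip(counts_a[:, j], lengths)
        ]
    for j, col in enumerate(cols_b):
        lib = float(counts_b[:, j].sum())
        fpkm_table[col] = [
            fpkm(c, l, lib) for c, l in zip(counts_b[:, j], lengths)
        ]
    return counts, fpkm_table


def _write_narrowpeak(peaks: Sequence[Peak], path: Path) -> None:
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end))
    with path.open("w") as handle:
        for p in ordered:
            score = min(1000, int(round(p.signal)))
            summit = p.summit_offset if p.summit_offset is not None else -1
            handle.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.name}\t"
                f"{score}\t.\t{p.signal:.6g}\t-1\t-1\t{summit}\n"
            )


def _write_bedgraph(peaks: Sequence[Peak], path: Path) -> None:
    """Per-base signal density (signal / width, summed where peaks overlap)."""
    events: dict[str, dict[int, float]] = {}
    for p in peaks:
        density = p.signal / p.interval.length
        chrom_events = events.setdefault(p.chrom, {})
        chrom_events[p.interval.start] = chrom_events.get(p.interval.start, 0.0) + density
        chrom_events[p.interval.end] = chrom_events.get(p.interval.end, 0.0) - density
    with path.open("w") as handle:
        for chrom in sorted(events):
            positions = sorted(events[chrom])
            level = 0.0
            for pos, nxt in zip(positions, positions[1:]):
                level += events[chrom][pos]
                if level > 1e-12 and nxt > pos:
                    handle.write(f"{chrom}\t{pos}\t{nxt}\t{level:.8g}\n")
            # level returns to ~0 after the last breakpoint


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def truth_frames(truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground truth as two flat tables (clusters; planted gene effects)."""
    cluster_frame = pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.span.chrom,
                "start": c.span.start,
                "end": c.span.end,
                "kind": c.kind,
                "direction": c.direction,
                "nearest_gene": c.nearest_gene,
            }
            for c in truth.clusters
        ]
    )
    gene_frame = pd.DataFrame(
        [
            {"gene_id": g, "direction": d, "fold": f}
            for g, (d, f) in sorted(truth.gene_effects.items())
        ]
    )
    return cluster_frame, gene_frame


def write_fixture(
    outdir: str | Path,
    config: SimulationConfig,
    overwrite: bool = False,
) -> dict:
    """Simulate and write a complete fixture; returns the manifest.

    Emits genes.gtf, per-condition narrowPeak and bedGraph files, count and
    FPKM tables, ground-truth tables and ``manifest.json`` with sha256
    checksums.  Refuses to clobber an existing manifest unless
    ``overwrite=True``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists (pass overwrite=True to replace)"
        )
    annotation, peaks_a, peaks_b, truth = simulate_landscape(config)
    counts, fpkm_table = simulate_expression(annotation, truth, config)
    cluster_frame, gene_frame = truth_frames(truth)

    write_gtf(annotation, outdir / "genes.gtf")
    _write_narrowpeak(peaks_a, outdir / "peaks_a.narrowPeak")
    _write_narrowpeak(peaks_b, outdir / "peaks_b.narrowPeak")
    _write_bedgraph(peaks_a, outdir / "signal_a.bedgraph")
    _write_bedgraph(peaks_b, outdir / "signal_b.bedgraph")
    write_table(counts, outdir / "counts.tsv")
    write_table(fpkm_table, outdir / "fpkm.tsv")
    write_table(cluster_frame, outdir / "truth_clusters.tsv")
    write_table(gene_frame, outdir / "truth_genes.tsv")

    files = [
        "genes.gtf",
        "peaks_a.narrowPeak",
        "peaks_b.narrowPeak",
        "signal_a.bedgraph",
        "signal_b.bedgraph",
        "counts.tsv",
        "fpkm.tsv",
        "truth_clusters.tsv",
        "truth_genes.tsv",
    ]
    manifest = {
        "seed": config.seed,
        "files": {name: _sha256(outdir / name) for name in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def verify_fixture(outdir: str | Path) -> bool:
    """True iff every file listed in the manifest matches its checksum."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, checksum in manifest["files"].items():
        path = outdir / name
        if not path.exists() or _sha256(path) != checksum:
            return False
    return True
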