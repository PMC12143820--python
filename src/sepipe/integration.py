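"""ChIP/RNA integration: join differential super-enhancers to nearby genes.

Each differential SE is assigned the gene whose TSS is nearest its midpoint
(within a configurable window).  When several SEs map to one gene only the
highest-signal one is kept.  An association survives when the SE's
directional fold change passes ``se_fc_min``, the gene's expression fold
change passes ``rna_fc_min`` in some direction, and (by default) the two
directions agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core_model import GenomeAnnotation, GenomicInterval
from .differential import DOWN, NS, UP, ExpressionRecord
from .peak_annotation import nearest_gene

__all__ = [
    "IntegrationParams",
    "DifferentialSE",
    "SEGeneAssociation",
    "IntegrationResult",
    "integrate",
    "summarize_integration",
    "associations_frame",
]


@dataclass(frozen=True)
class IntegrationParams:
    """Gates of the integration step.

    ``se_fc_min``: minimum directional linear fold change for the SE signal
    (the default 1.0 admits any significantly called SE).  ``rna_fc_min``:
    minimum linear fold change for the gene's expression (1.2 by default;
    a symmetric ``<= 1/rna_fc_min`` rule covers down-regulation).
    ``gene_window``: maximum |TSS - SE midpoint| distance for assignment.
    """

    se_fc_min: float = 1.0
    rna_fc_min: float = 1.2
    gene_window: int = 100_000
    require_concordance: bool = True

    def __post_init__(self) -> None:
        if self.se_fc_min < 1 or self.rna_fc_min < 1:
            raise ValueError("fold-change gates must be >= 1 (linear scale)")
        if self.gene_window <= 0:
            raise ValueError("gene_window must be positive")


@dataclass(frozen=True)
class DifferentialSE:
    """A super-enhancer region with its two-condition differential result."""

    se_id: str
    region: GenomicInterval
    signal: float
    log2fc: float
    p_value: float
    call: str


@dataclass(frozen=True)
class SEGeneAssociation:
    gene_id: str
    se_id: str
    distance: int
    se_log2fc: float
    se_direction: str
    rna_fold_change: float
    rna_direction: str
    concordant: bool


@dataclass
class IntegrationResult:
    associations: list[SEGeneAssociation]
    unmatched_genes: list[str] = field(default_factory=list)
    unassignable_ses: list[str] = field(default_factory=list)


def _rna_direction(fold_change: float, rna_fc_min: float) -> str:
    if fold_change >= rna_fc_min:
        return UP
    if fold_change <= 1.0 / rna_fc_min:
        return DOWN
    return NS


def integrate(
    differential_ses: Sequence[DifferentialSE],
    annotation: GenomeAnnotation,
    de_table: Mapping[str, ExpressionRecord] | Sequence[ExpressionRecord],
    params: IntegrationParams = IntegrationParams(),
) -> IntegrationResult:
    """Join differential SEs to their nearest genes with concordance gating.

    Steps: (1) nearest-gene assignment within ``gene_window``; (2) per gene,
    keep only the highest-signal SE; (3) gate the SE on its directional fold
    change and the gene on its expression fold change; (4) keep concordant
    pairs when ``require_concordance``.  Genes missing from ``de_table`` are
    reported in ``unmatched_genes``; SEs on gene-free chromosomes or beyond
    the window in ``unassignable_ses``.  Output sorted by |SE log2FC|
    descending.
    """
    if not isinstance(de_table, Mapping):
        de_table = {rec.gene_id: rec for rec in de_table}

    # (1) nearest gene per SE
    assigned: list[tuple[DifferentialSE, str, int]] = []
    unassignable: list[str] = []
    for se in differential_ses:
        try:
            gene_id, distance = nearest_gene(se.region, annotation)
        except ValueError:
            unassignable.append(se.se_id)
            continue
        if abs(distance) > params.gene_window:
            unassignable.append(se.se_id)
            continue
        assigned.append((se, gene_id, distance))

    # (2) highest-signal SE per gene (ties: leftmost start)
    best: dict[str, tuple[DifferentialSE, int]] = {}
    for se, gene_id, distance in assigned:
        incumbent = best.get(gene_id)
        if incumbent is None or (se.signal, -se.region.start) > (
            incumbent[0].signal,
            -incumbent[0].region.start,
        ):
            best[gene_id] = (se, distance)

    # (3)+(4) gates
    associations: list[SEGeneAssociation] = []
    unmatched: list[str] = []
    for gene_id, (se, distance) in best.items():
        if se.call == NS:
            continue
        if 2.0 ** abs(se.log2fc) < params.se_fc_min:
            continue
        record = de_table.get(gene_id)
        if record is None:
            unmatched.append(gene_id)
            continue
        rna_dir = _rna_direction(record.fold_change, params.rna_fc_min)
        if rna_dir == NS:
            continue
        concordant = rna_dir == se.call
        if params.require_concordance and not concordant:
            continue
        associations.append(
            SEGeneAssociation(
                gene_id=gene_id,
                se_id=se.se_id,
                distance=distance,
                se_log2fc=se.log2fc,
                se_direction=se.call,
                rna_fold_change=record.fold_change,
                rna_direction=rna_dir,
                concordant=concordant,
            )
        )
    associations.sort(key=lambda a: (-abs(a.se_log2fc), a.gene_id))
    return IntegrationResult(
        associations=associations,
        unmatched_genes=sorted(unmatched),
        unassignable_ses=sorted(unassignable),
    )


def summarize_integration(
    associations: Sequence[SEGeneAssociation],
) -> tuple[int, int, int]:
    """(n_total, n_up, n_down) over concordant associations."""
    concordant = [a for a in associations if a.concordant]
    n_up = sum(1 for a in concordant if a.se_direction == UP)
    n_down = sum(1 for a in concordant if a.se_direction == DOWN)
    return len(concordant), n_up, n_down


def associations_frame(result: IntegrationResult) -> pd.DataFrame:
    """Flat table of associations for TSV output."""
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "se_id": a.se_id,
                "distance": a.distance,
                "se_log2fc": a.se_log2fc,
                "se_direction": a.se_direction,
                "rna_fold_change": a.rna_fold_change,
                "rna_direction": a.rna_direction,
                "concordant": a.concordant,
            }
            for a in result.associations
        ]
    )
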