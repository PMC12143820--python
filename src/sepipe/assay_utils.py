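"""Bench-assay arithmetic: qPCR relative quantification, luciferase
normalization, ChIP-qPCR fold enrichment."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "QpcrSample",
    "ddct_relative_expression",
    "luciferase_normalized_activity",
    "chip_qpcr_fold_enrichment",
]


@dataclass(frozen=True)
class QpcrSample:
    """Paired threshold cycles for a target gene and a reference gene
    (e.g. GAPDH) from one sample."""

    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.target_ct) and math.isfinite(self.reference_ct)):
            raise ValueError("Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def ddct_relative_expression(treated: QpcrSample, control: QpcrSample) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (treated target - treated reference) - (control target - control
    reference); each PCR cycle is a doubling, so expression relative to the
    control sample is 2^-ddCt.
    """
    return 2.0 ** -(treated.delta_ct - control.delta_ct)


def luciferase_normalized_activity(
    firefly: float, renilla: float, firefly_ref: float, renilla_ref: float
) -> float:
    """Firefly/Renilla ratio normalized to an empty-vector reference."""
    if renilla <= 0 or renilla_ref <= 0 or firefly_ref <= 0:
        raise ValueError("reference and Renilla readings must be positive")
    return (firefly / renilla) / (firefly_ref / renilla_ref)


def chip_qpcr_fold_enrichment(ct_specific: float, ct_control_igg: float) -> float:
    """Fold enrichment of a specific antibody over the IgG control:
    2^(Ct_IgG - Ct_specific)."""
    if not (math.isfinite(ct_specific) and math.isfinite(ct_control_igg)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_control_igg - ct_specific)
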