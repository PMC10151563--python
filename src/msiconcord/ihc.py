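"""Immunohistochemistry (IHC) loss rule for the four MMR proteins.

A protein is scored lost when it is expressed in at most 10% of tumor
cells in the presence of an internal positive control (stromal cells or
lymphocytes); without the control the stain is non-evaluable. Loss is
checked for consistency against the family's affected gene through the
heterodimer co-loss map: MLH1 loss destabilizes PMS2 (MutL-alpha) and
MSH2 loss destabilizes MSH6 (MutS-alpha), while MSH6 and PMS2 losses
are typically isolated because their partners find other dimers.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping

from pydantic import BaseModel, Field, field_validator

from .models import GENES, Gene

logger = logging.getLogger(__name__)

ProteinCall = Literal["loss", "retained", "NE"]

#: Proteins expected to be lost when the key gene carries the second hit.
LOSS_PATTERN: dict[Gene, frozenset[str]] = {
    "MLH1": frozenset({"MLH1", "PMS2"}),
    "MSH2": frozenset({"MSH2", "MSH6"}),
    "MSH6": frozenset({"MSH6"}),
    "PMS2": frozenset({"PMS2"}),
}

LOSS_CUTOFF = 0.10


class IhcMeasurement(BaseModel):
    """Tumor-cell positivity fraction per MMR protein for one sample."""

    sample_id: str
    positivity: Mapping[str, float]
    internal_control_present: bool = True

    @field_validator("positivity")
    @classmethod
    def _four_proteins(cls, v: Mapping[str, float]) -> dict[str, float]:
        if set(v) != set(GENES):
            raise ValueError(f"positivity must cover exactly {GENES}")
        for protein, pi in v.items():
            if not 0 <= pi <= 1:
                raise ValueError(f"positivity for {protein} out of [0,1]: {pi}")
        return dict(v)


class IhcResult(BaseModel):
    sample_id: str
    protein_calls: dict[str, ProteinCall]
    sample_status: ProteinCall
    lost_set: frozenset[str] = frozenset()
    pattern_consistent: bool = True


def call_protein(
    pi: float, control_present: bool, cutoff: float = LOSS_CUTOFF
) -> ProteinCall:
    """Score one protein: loss when positivity <= cutoff (boundary inclusive)."""
    if not 0 <= pi <= 1:
        raise ValueError(f"positivity fraction out of [0,1]: {pi}")
    if not control_present:
        return "NE"
    return "loss" if pi <= cutoff else "retained"


def classify_sample_ihc(
    measurement: IhcMeasurement,
    family_gene: Gene,
    cutoff: float = LOSS_CUTOFF,
) -> IhcResult:
    """Combine per-protein calls into a sample-level loss/retained/NE call.

    The sample shows loss when any protein is lost; it is non-evaluable
    only when all four proteins are (i.e. the internal control failed).
    ``pattern_consistent`` is true when the lost proteins are a subset of
    the heterodimer pattern expected for the family's gene and include
    that gene's own protein.
    """
    if family_gene not in LOSS_PATTERN:
        raise ValueError(f"unknown MMR gene: {family_gene}")
    calls = {
        protein: call_protein(
            measurement.positivity[protein], measurement.internal_control_present, cutoff
        )
        for protein in GENES
    }
    lost = frozenset(p for p, c in calls.items() if c == "loss")
    if all(c == "NE" for c in calls.values()):
        status: ProteinCall = "NE"
    elif lost:
        status = "loss"
    else:
        status = "retained"
    expected = LOSS_PATTERN[family_gene]
    consistent = (not lost) or (lost <= expected and family_gene in lost)
    if lost and not consistent:
        logger.warning(
            "sample %s: lost proteins %s inconsistent with %s family pattern %s",
            measurement.sample_id,
            sorted(lost),
            family_gene,
            sorted(expected),
        )
    return IhcResult(
        sample_id=measurement.sample_id,
        protein_calls=calls,
        sample_status=status,
        lost_set=lost,
        pattern_consistent=consistent,
    )
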