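"""Shared domain types.

The package models a three-way comparison of mismatch-repair (MMR)
deficiency tests on urothelial tumors from Lynch-syndrome families:
an amplicon-sequencing microsatellite-instability (MSI) classifier over
mononucleotide-repeat markers, a fragment-length ("Promega-style") rule
classifier, and an immunohistochemistry (IHC) loss rule. Types here are
the vocabulary shared by every stage: markers and panels, cohort sample
records, read-length histograms and the per-marker features derived from
them, and statistics configuration.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

Base = Literal["A", "C", "G", "T"]
PanelName = Literal["promega5", "seq24", "seq54"]
Gene = Literal["MLH1", "MSH2", "MSH6", "PMS2"]
CarrierStatus = Literal["carrier", "FDR"]
VariantClass = Literal["truncating", "missense", "unknown"]
Location = Literal["ureter", "renal_pelvis", "bladder"]
MmrStatus = Literal["deficient", "proficient"]

#: Expected marker count for each of the three default panels.
PANEL_SIZES: dict[str, int] = {"promega5": 5, "seq24": 24, "seq54": 54}

GENES: tuple[Gene, ...] = ("MLH1", "MSH2", "MSH6", "PMS2")


def _longest_run(seq: str, base: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


class MarkerDef(BaseModel):
    """A mononucleotide-repeat locus targeted by an amplicon.

    The repeat is a homopolymer of ``repeat_base`` with reference length
    ``ref_len`` (in bases), anchored by unique flank sequences used to
    locate the repeat inside a read. Repeat lengths everywhere in this
    package are counts of repeat-unit bases, not genomic coordinates.
    """

    marker_id: str = Field(min_length=1)
    repeat_base: Base
    ref_len: int = Field(ge=5)
    left_flank: str = Field(min_length=8)
    right_flank: str = Field(min_length=8)
    panel_tags: tuple[PanelName, ...] = ()

    @field_validator("left_flank", "right_flank")
    @classmethod
    def _acgt_only(cls, v: str) -> str:
        if set(v) - set("ACGT"):
            raise ValueError(f"flank contains non-ACGT characters: {v!r}")
        return v

    @model_validator(mode="after")
    def _flanks_anchor(self) -> "MarkerDef":
        # A long run of the repeat base inside a flank would make the
        # repeat boundary ambiguous during read extraction.
        for name in ("left_flank", "right_flank"):
            if _longest_run(getattr(self, name), self.repeat_base) > 3:
                raise ValueError(
                    f"{name} of {self.marker_id} contains a run of "
                    f"{self.repeat_base} longer than 3"
                )
        return self


class Panel(BaseModel):
    """An ordered collection of marker ids forming one assay panel."""

    name: PanelName
    marker_ids: tuple[str, ...]

    @field_validator("marker_ids")
    @classmethod
    def _unique(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(set(v)) != len(v):
            raise ValueError("duplicate marker ids in panel")
        return v

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.marker_ids)


class SampleRecord(BaseModel):
    """One tumor sample with its clinical covariates.

    ``truth_mmr`` is synthetic ground truth and is absent when reading
    real-data cohort tables.
    """

    sample_id: str = Field(min_length=1)
    carrier_status: CarrierStatus
    gene: Gene
    variant_class: VariantClass
    location: Location
    age_at_diagnosis: float = Field(ge=0)
    block_age: float = Field(ge=0)
    dna_conc: float = Field(ge=0, description="double-stranded DNA, ng/uL")
    truth_mmr: Optional[MmrStatus] = None


class StatsConfig(BaseModel):
    """Settings for concordance statistics."""

    conf_level: float = Field(default=0.95, gt=0, lt=1)
    wilson_continuity: bool = False


class LengthHistogram(BaseModel):
    """Read tallies over observed repeat lengths at one marker."""

    marker_id: str
    counts: Mapping[int, int]

    @field_validator("counts")
    @classmethod
    def _valid_counts(cls, v: Mapping[int, int]) -> dict[int, int]:
        clean = {int(k): int(c) for k, c in v.items()}
        if any(k < 0 for k in clean):
            raise ValueError("repeat lengths must be >= 0")
        if any(c < 0 for c in clean.values()):
            raise ValueError("read counts must be >= 0")
        if not any(c > 0 for c in clean.values()):
            raise ValueError("histogram must contain at least one read")
        return clean

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class MarkerProfile(BaseModel):
    """Per-marker features: deletion frequency ``d`` and allelic bias ``b``.

    ``d`` is the fraction of reads strictly shorter than the reference
    repeat length; ``b`` is the fraction of those deleted reads carried by
    the single modal deleted length (high for a clonal somatic deletion,
    low for diffuse PCR stutter). ``b`` is 0 by convention when ``d`` is 0.
    """

    marker_id: str
    depth: int = Field(ge=0)
    d: float = Field(ge=0, le=1)
    b: float = Field(ge=0, le=1)
    evaluable: bool

    @model_validator(mode="after")
    def _b_zero_without_deletions(self) -> "MarkerProfile":
        if self.d == 0 and self.b != 0:
            raise ValueError("allelic bias must be 0 when deletion frequency is 0")
        return self

    @property
    def n_deleted(self) -> int:
        return int(round(self.d * self.depth))


class ProfilingConfig(BaseModel):
    """Depth thresholds for marker evaluability.

    The assay targets ~2000 reads per amplicon; markers under
    ``min_depth`` (default 10% of target) are flagged non-evaluable.
    """

    min_depth: int = Field(default=200, gt=0)
    target_depth: int = Field(default=2000, gt=0)
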