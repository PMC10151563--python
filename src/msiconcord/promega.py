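"""Fragment-length MSI rules over the five-marker panel, without matched
normal DNA.

Marker calls use an objective modal-shift rule: a secondary allele
carrying at least 20% of reads and deviating from the reference repeat
length by 3+ bp is unstable; 1-2 bp deviations are only 'suggestive'
(unresolvable without germline DNA). Sample classification follows the
no-matched-normal convention: 3+ unstable markers are MSI-H, two are
unresolved MSI-L/MSI-H, one is unresolved MSS/MSI-L, none is MSS, and
any suggestive marker makes the sample non-evaluable. For two-way
comparison with IHC the unresolved classes are pooled: {MSI-H,
MSI-L/MSI-H} -> pooled MSI-H and {MSS, MSS/MSI-L} -> pooled MSS/MSI-L.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping

from pydantic import BaseModel, Field

from .models import LengthHistogram, MarkerDef

MarkerStatus = Literal["stable", "unstable", "suggestive"]
RawClass = Literal["MSS", "MSS/MSI-L", "MSI-L/MSI-H", "MSI-H", "NE"]
PooledClass = Literal["pooled MSI-H", "pooled MSS/MSI-L", "NE"]

PROMEGA5_IDS: tuple[str, ...] = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")

_POOL: dict[str, PooledClass] = {
    "MSI-H": "pooled MSI-H",
    "MSI-L/MSI-H": "pooled MSI-H",
    "MSS/MSI-L": "pooled MSS/MSI-L",
    "MSS": "pooled MSS/MSI-L",
    "NE": "NE",
}


class PromegaMarkerCall(BaseModel):
    marker_id: str
    status: MarkerStatus


class PromegaConfig(BaseModel):
    shift_threshold_bp: int = Field(default=3, ge=1)
    suggestive_min_bp: int = 1
    suggestive_max_bp: int = 2
    allele_fraction_floor: float = Field(default=0.2, ge=0, le=1)


class PromegaResult(BaseModel):
    sample_id: str
    n_unstable: int = Field(ge=0, le=5)
    raw_class: RawClass
    pooled_class: PooledClass


def call_marker_shift(
    hist: LengthHistogram,
    marker: MarkerDef,
    config: PromegaConfig | None = None,
) -> PromegaMarkerCall:
    """Call one marker from its length histogram via the modal-shift rule.

    The candidate allele is the modal non-reference length whose read
    fraction clears ``allele_fraction_floor`` (suppressing stutter);
    ties break toward the shorter length. No such allele means stable.
    """
    config = config or PromegaConfig()
    depth = hist.depth
    candidates = [
        (count, -length, length)
        for length, count in hist.counts.items()
        if length != marker.ref_len and count / depth >= config.allele_fraction_floor
    ]
    if not candidates:
        return PromegaMarkerCall(marker_id=hist.marker_id, status="stable")
    _, _, modal = max(candidates)
    shift = abs(modal - marker.ref_len)
    if shift >= config.shift_threshold_bp:
        status: MarkerStatus = "unstable"
    elif config.suggestive_min_bp <= shift <= config.suggestive_max_bp:
        status = "suggestive"
    else:
        status = "stable"
    return PromegaMarkerCall(marker_id=hist.marker_id, status=status)


def classify_promega(
    calls: Iterable[PromegaMarkerCall] | Mapping[str, MarkerStatus],
    sample_id: str = "",
) -> PromegaResult:
    """Sample-level classification from exactly the five marker calls."""
    if isinstance(calls, Mapping):
        statuses = dict(calls)
    else:
        statuses = {c.marker_id: c.status for c in calls}
    if set(statuses) != set(PROMEGA5_IDS):
        raise ValueError(
            f"expected the five-marker panel {PROMEGA5_IDS}, got {sorted(statuses)}"
        )
    n_unstable = sum(1 for s in statuses.values() if s == "unstable")
    if any(s == "suggestive" for s in statuses.values()):
        raw: RawClass = "NE"
    elif n_unstable >= 3:
        raw = "MSI-H"
    elif n_unstable == 2:
        raw = "MSI-L/MSI-H"
    elif n_unstable == 1:
        raw = "MSS/MSI-L"
    else:
        raw = "MSS"
    return PromegaResult(
        sample_id=sample_id,
        n_unstable=n_unstable,
        raw_class=raw,
        pooled_class=pool_class(raw),
    )


def pool_class(raw_class: str) -> PooledClass:
    """Dichotomize the five-level classification for 2x2 comparison."""
    try:
        return _POOL[raw_class]
    except KeyError:
        raise ValueError(f"unknown raw class: {raw_class!r}") from None
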