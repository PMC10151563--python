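"""Diagnostic-concordance statistics for paired IHC-vs-MSI calls.

With IHC as the reference method, each sample falls into a 2x2 table:

    a = IHC loss     & pooled MSI-H      (both call deficiency)
    b = IHC loss     & pooled MSS/MSI-L  (MSI misses)
    c = IHC retained & pooled MSI-H      (MSI calls, IHC does not)
    d = IHC retained & pooled MSS/MSI-L  (both call proficiency)

Concordance is (a+d)/n with a Wilson score interval; sensitivity
a/(a+b) and specificity d/(c+d) carry exact Clopper-Pearson intervals;
marginal homogeneity is tested with the exact (binomial) McNemar test
on the discordant pair (b, c). Samples non-evaluable on either side are
excluded listwise per assay, so each assay keeps its own denominator.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, Field
from scipy.stats import binom, fisher_exact
from statsmodels.stats.proportion import proportion_confint

from .models import StatsConfig


class ConfusionTable(BaseModel):
    a: int = Field(ge=0)
    b: int = Field(ge=0)
    c: int = Field(ge=0)
    d: int = Field(ge=0)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class Interval(BaseModel):
    lower: float
    upper: float


class ConcordanceReport(BaseModel):
    assay: str
    table: ConfusionTable
    n: int
    n_dropped: int = 0
    concordance: float
    concordance_ci: Interval
    sensitivity: float
    sensitivity_ci: Interval
    specificity: float
    specificity_ci: Interval
    mcnemar_b: int
    mcnemar_c: int
    mcnemar_p: float


def build_confusion(
    ihc_status: Mapping[str, str],
    msi_pooled: Mapping[str, str],
) -> tuple[ConfusionTable, int]:
    """Tally the paired 2x2 table, dropping pairs with an NE on either side.

    Returns the table and the number of dropped pairs. Sample ids must
    match one-to-one between the two mappings.
    """
    if set(ihc_status) != set(msi_pooled):
        raise ValueError("IHC and MSI results must cover the same sample ids")
    if len(ihc_status) != len(set(ihc_status)):  # pragma: no cover - dict keys unique
        raise ValueError("duplicate sample ids")
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    dropped = 0
    for sid, ihc in ihc_status.items():
        msi = msi_pooled[sid]
        if ihc == "NE" or msi == "NE":
            dropped += 1
            continue
        if ihc not in ("loss", "retained"):
            raise ValueError(f"unknown IHC status {ihc!r} for {sid}")
        if msi not in ("pooled MSI-H", "pooled MSS/MSI-L"):
            raise ValueError(f"unknown pooled MSI class {msi!r} for {sid}")
        key = {
            ("loss", "pooled MSI-H"): "a",
            ("loss", "pooled MSS/MSI-L"): "b",
            ("retained", "pooled MSI-H"): "c",
            ("retained", "pooled MSS/MSI-L"): "d",
        }[(ihc, msi)]
        cells[key] += 1
    table = ConfusionTable(**cells)
    if table.n == 0:
        raise ValueError("empty table: every pair was non-evaluable")
    return table, dropped


def concordance_wilson(
    ct: ConfusionTable, config: StatsConfig | None = None
) -> tuple[float, Interval]:
    """Matched fraction (a+d)/n with a Wilson score interval."""
    config = config or StatsConfig()
    if ct.n == 0:
        raise ValueError("empty confusion table")
    matched = ct.a + ct.d
    lo, hi = proportion_confint(
        matched, ct.n, alpha=1 - config.conf_level, method="wilson"
    )
    return matched / ct.n, Interval(lower=float(lo), upper=float(hi))


def sens_spec_cp(
    ct: ConfusionTable, config: StatsConfig | None = None
) -> tuple[float, Interval, float, Interval]:
    """Sensitivity and specificity with exact (Clopper-Pearson) intervals."""
    config = config or StatsConfig()
    alpha = 1 - config.conf_level
    if ct.a + ct.b == 0:
        raise ValueError("empty reference-positive margin (a+b=0)")
    if ct.c + ct.d == 0:
        raise ValueError("empty reference-negative margin (c+d=0)")
    sens = ct.a / (ct.a + ct.b)
    spec = ct.d / (ct.c + ct.d)
    s_lo, s_hi = proportion_confint(ct.a, ct.a + ct.b, alpha=alpha, method="beta")
    p_lo, p_hi = proportion_confint(ct.d, ct.c + ct.d, alpha=alpha, method="beta")
    return (
        sens,
        Interval(lower=float(s_lo), upper=float(s_hi)),
        spec,
        Interval(lower=float(p_lo), upper=float(p_hi)),
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact McNemar p: doubled binomial tail over the discordant pairs.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    p = 1 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n_d = b + c
    if n_d == 0:
        return 1.0
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), n_d, 0.5)))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by the probability-mass rule."""
    (r0a, r0b), (r1a, r1b) = table
    if min(r0a, r0b, r1a, r1b) < 0:
        raise ValueError("cell counts must be non-negative")
    if r0a + r0b == 0 or r1a + r1b == 0 or r0a + r1a == 0 or r0b + r1b == 0:
        raise ValueError("zero margin in 2x2 table")
    return float(fisher_exact([[r0a, r0b], [r1a, r1b]], alternative="two-sided")[1])


def compare_panels_mcnemar(
    calls_a: Mapping[str, str], calls_b: Mapping[str, str]
) -> tuple[int, int, float]:
    """Exact McNemar comparison of two dichotomous call sets on one cohort.

    Returns (b', c', p) where b' counts samples MSS under A but MSI-H
    under B, and c' the reverse.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("panel comparisons require identical sample sets")
    b = sum(1 for s in calls_a if calls_a[s] == "MSS" and calls_b[s] == "MSI-H")
    c = sum(1 for s in calls_a if calls_a[s] == "MSI-H" and calls_b[s] == "MSS")
    return b, c, mcnemar_exact(b, c)


def make_concordance_report(
    ct: ConfusionTable,
    assay: str,
    config: StatsConfig | None = None,
    n_dropped: int = 0,
) -> ConcordanceReport:
    """Assemble every agreement statistic for one assay's 2x2 table."""
    conc, conc_ci = concordance_wilson(ct, config)
    sens, sens_ci, spec, spec_ci = sens_spec_cp(ct, config)
    return ConcordanceReport(
        assay=assay,
        table=ct,
        n=ct.n,
        n_dropped=n_dropped,
        concordance=conc,
        concordance_ci=conc_ci,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        mcnemar_b=ct.b,
        mcnemar_c=ct.c,
        mcnemar_p=mcnemar_exact(ct.b, ct.c),
    )
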