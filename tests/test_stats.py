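"""Agreement statistics: confusion building, intervals, exact tests.

Exact McNemar and Fisher values are cross-checked against brute-force
enumeration oracles implemented here from first principles.
"""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from msiconcord import (
    ConfusionTable,
    StatsConfig,
    build_confusion,
    compare_panels_mcnemar,
    concordance_wilson,
    fisher_exact_2x2,
    make_concordance_report,
    mcnemar_exact,
    sens_spec_cp,
)


def _mcnemar_oracle(b, c):
    """Enumerate all 2^(b+c) discordant-pair outcomes under H0."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


def _fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(a_):
        return (
            math.comb(r1, a_) * math.comb(r2, c1 - a_) / math.comb(n, c1)
        )

    p_obs = p_of(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = p_of(a_)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestBuildConfusion:
    def test_cells_tallied_by_matching_rule(self):
        ihc = {}
        msi = {}
        i = 0
        for (ihc_s, msi_s), count in {
            ("loss", "pooled MSI-H"): 45,
            ("loss", "pooled MSS/MSI-L"): 17,
            ("retained", "pooled MSI-H"): 3,
            ("retained", "pooled MSS/MSI-L"): 3,
        }.items():
            for _ in range(count):
                ihc[f"S{i}"] = ihc_s
                msi[f"S{i}"] = msi_s
                i += 1
        table, dropped = build_confusion(ihc, msi)
        assert (table.a, table.b, table.c, table.d) == (45, 17, 3, 3)
        assert table.n == 68 and dropped == 0

    def test_ne_pairs_dropped_listwise(self):
        ihc = {f"S{i}": "loss" for i in range(10)}
        msi = {f"S{i}": "pooled MSI-H" for i in range(10)}
        ihc["S3"] = "NE"
        table, dropped = build_confusion(ihc, msi)
        assert table.n == 9 and dropped == 1

    def test_all_ne_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_confusion({"S1": "NE"}, {"S1": "pooled MSI-H"})

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="same sample ids"):
            build_confusion({"S1": "loss"}, {"S2": "pooled MSI-H"})


class TestConcordance:
    def test_published_promega_point(self):
        p, ci = concordance_wilson(ConfusionTable(a=45, b=17, c=3, d=3))
        assert p == pytest.approx(0.7059, abs=5e-5)
        assert (ci.lower, ci.upper) == (
            pytest.approx(0.5889, abs=5e-5),
            pytest.approx(0.8008, abs=5e-5),
        )

    def test_perfect_agreement(self):
        p, ci = concordance_wilson(ConfusionTable(a=10, b=0, c=0, d=10))
        assert p == 1.0 and ci.upper == pytest.approx(1.0)

    def test_interval_contains_point(self):
        for cells in [(45, 17, 3, 3), (54, 8, 1, 9), (58, 4, 3, 7), (1, 1, 1, 1)]:
            p, ci = concordance_wilson(ConfusionTable(a=cells[0], b=cells[1], c=cells[2], d=cells[3]))
            assert ci.lower <= p <= ci.upper


class TestSensSpec:
    @pytest.mark.parametrize(
        "cells,sens,spec",
        [
            ((45, 17, 3, 3), 0.7258, 0.5000),
            ((54, 8, 1, 9), 0.8710, 0.9000),
            ((58, 4, 3, 7), 0.9355, 0.7000),
            ((7, 0, 0, 7), 1.0, 1.0),
        ],
    )
    def test_point_estimates(self, cells, sens, spec):
        a, b, c, d = cells
        s, _, sp, _ = sens_spec_cp(ConfusionTable(a=a, b=b, c=c, d=d))
        assert s == pytest.approx(sens, abs=5e-5)
        assert sp == pytest.approx(spec, abs=5e-5)

    def test_clopper_pearson_equals_beta_quantiles(self):
        # CP bounds for 45/62 from the defining Beta quantiles
        from scipy.stats import beta as beta_dist

        s, ci, _, _ = sens_spec_cp(ConfusionTable(a=45, b=17, c=1, d=1))
        assert ci.lower == pytest.approx(beta_dist.ppf(0.025, 45, 18), abs=1e-12)
        assert ci.upper == pytest.approx(beta_dist.ppf(0.975, 46, 17), abs=1e-12)
        assert ci.lower == pytest.approx(0.598, abs=5e-4)
        assert ci.upper == pytest.approx(0.831, abs=5e-4)

    def test_empty_margin_named(self):
        with pytest.raises(ValueError, match="a\\+b"):
            sens_spec_cp(ConfusionTable(a=0, b=0, c=1, d=1))
        with pytest.raises(ValueError, match="c\\+d"):
            sens_spec_cp(ConfusionTable(a=1, b=1, c=0, d=0))

    def test_cp_never_narrower_than_wilson(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(3, 6), (45, 62), (9, 10), (1, 50), (49, 50)]:
            w_lo, w_hi = proportion_confint(x, n, 0.05, method="wilson")
            c_lo, c_hi = proportion_confint(x, n, 0.05, method="beta")
            assert (c_hi - c_lo) >= (w_hi - w_lo) - 1e-12


class TestMcnemar:
    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (17, 3, 0.00258),
            (8, 1, 0.03906),
            (4, 3, 1.0),
            (0, 0, 1.0),
            (6, 0, 0.03125),
        ],
    )
    def test_frozen_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=5e-6)

    @given(st.integers(min_value=0, max_value=6), st.integers(min_value=0, max_value=6))
    def test_matches_enumeration_oracle(self, b, c):
        assert mcnemar_exact(b, c) == pytest.approx(_mcnemar_oracle(b, c), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_exact(-1, 2)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[69, 5], [17, 6]], 0.020),
            ([[2, 59], [9, 27]], 0.002),
            ([[1, 14], [5, 3]], 0.009),
            ([[1, 45], [4, 24]], 0.065),
            ([[5, 5], [5, 5]], 1.0),
        ],
    )
    def test_published_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=5e-4)

    @given(
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=1, max_value=12),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
            _fisher_oracle([[a, b], [c, d]]), rel=1e-7
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestComparePanels:
    def test_six_vs_zero(self):
        calls_a = {f"S{i}": "MSS" for i in range(6)} | {f"T{i}": "MSI-H" for i in range(10)}
        calls_b = {f"S{i}": "MSI-H" for i in range(6)} | {f"T{i}": "MSI-H" for i in range(10)}
        b, c, p = compare_panels_mcnemar(calls_a, calls_b)
        assert (b, c) == (6, 0)
        assert p == pytest.approx(0.03125)

    def test_identical_calls(self):
        calls = {f"S{i}": "MSI-H" for i in range(8)}
        assert compare_panels_mcnemar(calls, dict(calls))[2] == 1.0

    def test_one_each_way_capped(self):
        calls_a = {"S1": "MSS", "S2": "MSI-H", "S3": "MSS"}
        calls_b = {"S1": "MSI-H", "S2": "MSS", "S3": "MSS"}
        assert compare_panels_mcnemar(calls_a, calls_b)[2] == 1.0

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_panels_mcnemar({"S1": "MSS"}, {"S2": "MSS"})


class TestSymmetry:
    @pytest.mark.parametrize("cells", [(45, 17, 3, 3), (54, 8, 1, 9), (12, 2, 5, 30)])
    def test_label_swap_exchanges_sens_and_spec(self, cells):
        a, b, c, d = cells
        ct = ConfusionTable(a=a, b=b, c=c, d=d)
        swapped = ConfusionTable(a=d, b=c, c=b, d=a)
        sens, _, spec, _ = sens_spec_cp(ct)
        sens_sw, _, spec_sw, _ = sens_spec_cp(swapped)
        assert sens == pytest.approx(spec_sw) and spec == pytest.approx(sens_sw)
        assert concordance_wilson(ct)[0] == pytest.approx(concordance_wilson(swapped)[0])
        assert mcnemar_exact(ct.b, ct.c) == pytest.approx(mcnemar_exact(swapped.b, swapped.c))


def test_report_assembles_all_statistics():
    rep = make_concordance_report(ConfusionTable(a=45, b=17, c=3, d=3), "promega")
    assert rep.n == 68
    assert rep.concordance == pytest.approx(48 / 68)
    assert rep.mcnemar_p == pytest.approx(0.00258, abs=5e-6)
    assert rep.sensitivity_ci.lower <= rep.sensitivity <= rep.sensitivity_ci.upper
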