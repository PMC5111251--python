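"""Impact cumulation and Fisher exact test checks.

The Fisher oracle here enumerates all 2x2 tables with the observed margins
using exact integer binomial coefficients (math.comb), so its p-values are
correct to one floating-point rounding of an exact rational.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from dysbiota.annotate import (
    DISCARDED,
    HARMFUL,
    HARMLESS,
    DifferentialGenus,
    GenusAnnotation,
)
from dysbiota.impact import (
    ImpactContingency,
    cartesian_plane_data,
    cumulate_impact,
    fisher_exact,
    pairwise_condition_tests,
    round_half_up,
)
from dysbiota.impact import test_vs_control as fisher_vs_control

# ----------------------------------------------------------------- oracle

_RELTOL_NUM = 10**7 + 1
_RELTOL_DEN = 10**7


def oracle_fisher(a, b, c, d, alternative):
    """Exact-integer hypergeometric enumeration over the margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if lo == hi:
        return 1.0
    nums = [math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    denom = math.comb(n, c1)
    i = a - lo
    if alternative == "greater":
        return sum(nums[i:]) / denom
    if alternative == "less":
        return sum(nums[: i + 1]) / denom
    obs = nums[i]
    total = sum(x for x in nums if x * _RELTOL_DEN <= obs * _RELTOL_NUM)
    return total / denom


# ----------------------------------------------------------------- helpers

def _ann(pair, genus, label):
    evidence = (f"{genus} somespecies",) if label == HARMFUL else ()
    return GenusAnnotation(pair, genus, label, evidence)


def _case(pair, rows):
    """rows: list of (genus, label, delta)."""
    diffs = [DifferentialGenus(pair, g, d) for g, _, d in rows]
    anns = [_ann(pair, g, lab) for g, lab, _ in rows]
    return diffs, anns


# ----------------------------------------------------------------- tests

class TestCumulateImpact:
    def test_single_harmless_increase(self):
        diffs, anns = _case("a-b", [("X", HARMLESS, 5.0)])
        contingency, contributions = cumulate_impact(diffs, anns)
        assert contingency.row("a-b") == (5, 0)
        assert contributions[0].quadrant == 1

    def test_four_quadrants(self):
        rows = [
            ("W", HARMLESS, 3.0),   # Q1 eubiotic
            ("X", HARMFUL, 2.0),    # Q2 dysbiotic
            ("Y", HARMFUL, -4.0),   # Q3 eubiotic
            ("Z", HARMLESS, -1.0),  # Q4 dysbiotic
        ]
        diffs, anns = _case("a-b", rows)
        contingency, contributions = cumulate_impact(diffs, anns)
        assert contingency.row("a-b") == (7, 3)
        quadrants = {c.genus: c.quadrant for c in contributions}
        assert quadrants == {"W": 1, "X": 2, "Y": 3, "Z": 4}

    def test_discarded_genera_excluded(self):
        diffs, anns = _case(
            "a-b", [("X", HARMLESS, 5.0), ("Y", DISCARDED, 100.0)]
        )
        contingency, contributions = cumulate_impact(diffs, anns)
        assert contingency.row("a-b") == (5, 0)
        assert len(contributions) == 1

    def test_missing_annotation_is_error(self):
        diffs, _ = _case("a-b", [("X", HARMLESS, 5.0)])
        with pytest.raises(ValueError, match="no annotation"):
            cumulate_impact(diffs, [])

    def test_all_discarded_pair_warns_with_zero_row(self):
        diffs, anns = _case("a-b", [("X", DISCARDED, 5.0)])
        with pytest.warns(UserWarning, match="no usable genera"):
            contingency, _ = cumulate_impact(diffs, anns)
        assert contingency.row("a-b") == (0, 0)

    def test_conservation_with_fractional_deltas(self, rng):
        # rounded entries must sum to the rounded total, whatever the split
        for trial in range(200):
            n = int(rng.integers(1, 12))
            rows = [
                (
                    f"G{i}",
                    HARMLESS if rng.random() < 0.5 else HARMFUL,
                    float(rng.normal(0, 20)) or 1.0,
                )
                for i in range(n)
            ]
            diffs, anns = _case("a-b", rows)
            contingency, _ = cumulate_impact(diffs, anns)
            eub, dys = contingency.row("a-b")
            total = sum(abs(d.delta) for d in diffs)
            assert eub + dys == round_half_up(total)
            assert eub >= 0 and dys >= 0

    def test_table_shape_matches_study_format(self):
        # rows like "NORA-HLT | 3147 | 977": pair label + two integer columns
        diffs, anns = _case("NORA-HLT", [("X", HARMLESS, 3147.0),
                                         ("Y", HARMFUL, 977.0)])
        contingency, _ = cumulate_impact(diffs, anns)
        assert list(contingency.table.columns) == ["eubiotic", "dysbiotic"]
        assert contingency.row("NORA-HLT") == (3147, 977)


class TestCartesianPlane:
    def test_quadrant_sums(self):
        rows = [
            ("W", HARMLESS, 3.0),
            ("X", HARMFUL, 2.0),
            ("Y", HARMFUL, -4.0),
            ("Z", HARMLESS, -1.0),
        ]
        diffs, anns = _case("a-b", rows)
        _, contributions = cumulate_impact(diffs, anns)
        cart = cartesian_plane_data(contributions)
        by_q = cart.set_index("quadrant")["sum_abs_delta"]
        assert by_q[1] == 3 and by_q[2] == 2 and by_q[3] == 4 and by_q[4] == 1

    def test_all_harmless_increases_fill_only_q1(self):
        diffs, anns = _case("a-b", [("X", HARMLESS, 2.0), ("Y", HARMLESS, 3.0)])
        _, contributions = cumulate_impact(diffs, anns)
        cart = cartesian_plane_data(contributions)
        nonzero = cart[cart["sum_abs_delta"] > 0]["quadrant"].tolist()
        assert nonzero == [1]

    def test_conservation_vs_contingency(self, rng):
        for trial in range(50):
            rows = [
                (
                    f"G{i}",
                    HARMLESS if rng.random() < 0.5 else HARMFUL,
                    float(rng.normal(0, 10)) or 1.0,
                )
                for i in range(int(rng.integers(1, 10)))
            ]
            diffs, anns = _case("a-b", rows)
            contingency, contributions = cumulate_impact(diffs, anns)
            cart = cartesian_plane_data(contributions)
            eub = cart[cart["quadrant"].isin([1, 3])]["sum_abs_delta"].sum()
            dys = cart[cart["quadrant"].isin([2, 4])]["sum_abs_delta"].sum()
            eub_r, dys_r = contingency.row("a-b")
            assert eub_r + dys_r == round_half_up(eub + dys)
            assert eub_r == round_half_up(eub)


class TestFisherExact:
    def test_symmetric_table_two_sided_is_one(self):
        assert fisher_exact([[2, 2], [2, 2]], "two_sided") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_study_contingency_pvalues(self):
        # one-sided tests on the printed treated-vs-untreated rows
        p_mtx = fisher_exact([[1965, 0], [0, 16]], "greater")
        assert p_mtx == pytest.approx(3.95e-40, rel=0.02)
        p_pred = fisher_exact([[266, 102], [0, 16]], "greater")
        assert p_pred == pytest.approx(2.99e-09, rel=0.02)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_agrees_with_scipy(self, rng, alternative):
        scipy_alt = {"two_sided": "two-sided"}.get(alternative, alternative)
        for _ in range(100):
            table = rng.integers(0, 40, size=(2, 2))
            if table.sum() == 0:
                continue
            mine = fisher_exact(table, alternative)
            ref = scipy_fisher(table, alternative=scipy_alt).pvalue
            assert mine == pytest.approx(float(ref), rel=1e-9, abs=1e-300)

    def test_extreme_table_stays_in_log_range(self):
        # far beyond double underflow of any naive factorial product
        p = fisher_exact([[20000, 0], [0, 2000]], "greater")
        assert 0.0 <= p < 1e-300 or p == 0.0

    def test_degenerate_margin_is_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact([[0, 0], [0, 16]], "two_sided") == 1.0

    @pytest.mark.parametrize(
        "bad", [[[1, -1], [2, 3]], [[0.5, 1], [2, 3]], [[1, 2, 3], [4, 5, 6]]]
    )
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_exact(bad, "greater")

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=200)
    def test_sidedness_identities(self, cells):
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        table = [[a, b], [c, d]]
        p_g = fisher_exact(table, "greater")
        p_l = fisher_exact(table, "less")
        p_obs = oracle_fisher(a, b, c, d, "greater") + oracle_fisher(
            a, b, c, d, "less"
        ) - 1.0  # P(observed), from the oracle
        assert 0.0 <= p_g <= 1.0 and 0.0 <= p_l <= 1.0
        # greater- and less-sided overlap exactly in the observed table
        assert p_g + p_l - p_obs == pytest.approx(1.0, abs=1e-9)
        # swapping rows swaps the sidedness
        assert fisher_exact([[c, d], [a, b]], "greater") == pytest.approx(
            p_l, rel=1e-12
        )

    def test_identical_rows_match_enumeration(self):
        for row in [(5, 3), (10, 0), (7, 7)]:
            table = [list(row), list(row)]
            for alt in ("greater", "less", "two_sided"):
                assert fisher_exact(table, alt) == pytest.approx(
                    oracle_fisher(*row, *row, alt), rel=1e-12
                )

    def test_balanced_diagonal_matches_enumeration(self):
        assert fisher_exact([[10, 0], [0, 10]], "two_sided") == pytest.approx(
            oracle_fisher(10, 0, 0, 10, "two_sided"), rel=1e-12
        )


class TestConditionTests:
    @pytest.fixture
    def study_contingency(self):
        table = pd.DataFrame(
            {
                "eubiotic": [3147, 0, 1965, 266],
                "dysbiotic": [977, 16, 0, 102],
            },
            index=["NORA-HLT", "UCRA-HLT", "MTX-HLT", "Prednisone-HLT"],
        )
        return ImpactContingency(table=table)

    def test_pairwise_matrix(self, study_contingency):
        pvals = pairwise_condition_tests(study_contingency)
        assert pvals.loc["MTX-HLT", "UCRA-HLT"] == pytest.approx(
            3.95e-40, rel=0.02
        )
        assert pvals.loc["Prednisone-HLT", "UCRA-HLT"] == pytest.approx(
            2.99e-09, rel=0.02
        )
        assert (np.diag(pvals.to_numpy()) == 1.0).all()
        assert ((pvals.to_numpy() >= 0) & (pvals.to_numpy() <= 1)).all()

    def test_single_row_is_error(self):
        contingency = ImpactContingency(
            table=pd.DataFrame(
                {"eubiotic": [5], "dysbiotic": [3]}, index=["a-b"]
            )
        )
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_condition_tests(contingency)

    def test_vs_control_identical_rows(self):
        assert fisher_vs_control((10, 5), (10, 5)) == pytest.approx(1.0, abs=1e-9)

    def test_vs_control_matches_enumeration(self):
        assert fisher_vs_control((10, 0), (0, 10)) == pytest.approx(
            oracle_fisher(10, 0, 0, 10, "two_sided"), rel=1e-12
        )

    def test_vs_control_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_vs_control((0, 0), (0, 16)) == 1.0


def test_contingency_csv_round_trip(tmp_path):
    table = pd.DataFrame(
        {"eubiotic": [12, 0], "dysbiotic": [3, 7]}, index=["a-b", "c-b"]
    )
    contingency = ImpactContingency(table=table)
    dest = tmp_path / "contingency.csv"
    contingency.to_csv(dest)
    reloaded = ImpactContingency.from_csv(dest)
    pd.testing.assert_frame_equal(
        reloaded.table, contingency.table, check_names=False
    )
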