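"""Exact-test statistics, normalisation rules and ranking."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from smrnade import datasets
from smrnade.de_stats import (
    DeCallParams,
    ac_pmf,
    ac_pvalue,
    apply_zero_and_low_rules,
    bonferroni,
    de_table,
    log2_fold_change,
    top_n,
    tpm,
)


def pmf_oracle(y: int, x: int, ratio: Fraction) -> float:
    """Direct factorial evaluation of the count pmf (exact rationals)."""
    value = (
        Fraction(ratio) ** y
        * Fraction(math.factorial(x + y), math.factorial(x) * math.factorial(y))
        / (1 + Fraction(ratio)) ** (x + y + 1)
    )
    return float(value)


class TestAcPmf:
    def test_hand_computed_values(self):
        assert ac_pmf(0, 0, 1.0) == pytest.approx(0.5)
        assert ac_pmf(1, 0, 1.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("ratio", [Fraction(1, 2), Fraction(1), Fraction(2)])
    def test_matches_factorial_oracle(self, ratio):
        for x in range(0, 31, 3):
            for y in range(0, 31, 3):
                expected = pmf_oracle(y, x, ratio)
                assert ac_pmf(y, x, float(ratio)) == pytest.approx(
                    expected, rel=1e-10
                )

    @pytest.mark.parametrize("x", [0, 1, 5, 20])
    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_sums_to_one(self, x, ratio):
        ys = np.arange(0, 3000)
        total = ac_pmf(ys, x, ratio).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ac_pmf(-1, 0, 1.0)


class TestAcPvalue:
    def test_pmf_symmetric_when_totals_equal(self):
        # at N1 = N2 the conditional pmf is symmetric: p(y|x) = p(x|y);
        # the discrete tail sums (hence p-values) are only asymptotically so
        for x, y in [(3, 7), (0, 12), (40, 11)]:
            assert ac_pmf(y, x, 1.0) == pytest.approx(ac_pmf(x, y, 1.0))
        for x, y in [(220, 260), (500, 430)]:
            assert ac_pvalue(x, y, 1e6, 1e6) == pytest.approx(
                ac_pvalue(y, x, 1e6, 1e6), rel=0.2
            )

    def test_equal_counts_give_large_p(self):
        for x in [0, 5, 50]:
            assert ac_pvalue(x, x, 1e6, 1e6) >= 0.5

    def test_extreme_count_gives_tiny_p(self):
        assert ac_pvalue(100, 0, 1e6, 1e6) < 1e-20

    def test_matches_brute_force_tails(self):
        x, n1, n2 = 8, 1e6, 2e6
        ratio = Fraction(2)
        for y in [0, 2, 8, 30, 60]:
            lower = sum(pmf_oracle(k, x, ratio) for k in range(y + 1))
            upper = 1.0 - sum(pmf_oracle(k, x, ratio) for k in range(y))
            expected = min(1.0, 2 * min(lower, upper))
            assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_extremity(self):
        ps = [ac_pvalue(10, y, 1e6, 1e6) for y in range(10, 60, 5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestNormalisation:
    def test_tpm_examples(self):
        assert tpm(100, 1_000_000) == pytest.approx(100.0)
        assert tpm(0, 123) == 0.0
        assert tpm(194, 11_023_426) == pytest.approx(17.60, abs=5e-3)

    def test_tpm_rejects_bad_total(self):
        with pytest.raises(ValueError):
            tpm(1, 0)

    def test_zero_rule_floors_at_001(self):
        mat = pd.DataFrame([[0.0, 5.0]], index=["m1"], columns=["a", "b"])
        out = apply_zero_and_low_rules(mat)
        assert out.loc["m1"].tolist() == [0.01, 5.0]

    def test_low_expression_row_dropped(self):
        mat = pd.DataFrame(
            [[0.5, 0.9, 0.2, 0.7, 0.3], [0.5, 1.2, 0.2, 0.2, 0.2]],
            index=["low", "kept"],
        )
        out = apply_zero_and_low_rules(mat)
        assert list(out.index) == ["kept"]
        assert out.loc["kept"].tolist() == [0.5, 1.2, 0.2, 0.2, 0.2]


class TestFoldChange:
    def test_published_tpm_pairs_reproduce_fold_changes(self):
        """Each printed (control, treatment, log2fc) triple is reproduced."""
        de = datasets.de_published()
        for _, row in de.iterrows():
            for suffix in ("12h", "18h"):
                got = log2_fold_change(row[f"tpm_{suffix}"], row["tw_tpm"])
                assert got == pytest.approx(row[f"log2fc_{suffix}"], abs=1e-3)

    def test_identity_is_zero(self):
        assert log2_fold_change(3.3, 3.3) == 0.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 1.0)


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01]).tolist() == [0.01]
        assert bonferroni([0.01, 0.02]).tolist() == pytest.approx([0.02, 0.04])
        assert bonferroni([0.9, 0.9]).tolist() == [1.0, 1.0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestDeTable:
    def _counts(self):
        return pd.DataFrame(
            {"TW": [100, 40, 0, 1], "T": [100, 40, 35, 1]},
            index=["m1", "m2", "m3", "m4"],
        )

    def test_identical_libraries_no_calls(self):
        counts = pd.DataFrame({"TW": [50, 500], "T": [50, 500]}, index=["a", "b"])
        tab = de_table(counts, {"TW": 1e5, "T": 1e5}, "TW", "T")
        assert not tab["significant"].any()

    def test_zero_count_retained_with_floor(self):
        tab = de_table(self._counts(), {"TW": 1e5, "T": 1e5}, "TW", "T")
        assert tab.loc["m3", "control_tpm"] == pytest.approx(0.01)
        assert tab.loc["m3", "significant"]

    def test_all_low_row_dropped(self):
        # m4: 1 count in 1e7 reads -> 0.1 TPM everywhere -> ignored
        tab = de_table(self._counts(), {"TW": 1e7, "T": 1e7}, "TW", "T")
        assert "m4" not in tab.index

    def test_adjusted_p_at_least_p(self):
        tab = de_table(self._counts(), {"TW": 1e5, "T": 1e5}, "TW", "T")
        assert (tab["fdr"] >= tab["pvalue"] - 1e-15).all()

    def test_rejects_bad_totals(self):
        with pytest.raises(ValueError):
            de_table(self._counts(), {"TW": 0, "T": 1e5}, "TW", "T")


class TestTopN:
    def test_published_counts_rank_mir1_first(self):
        counts = datasets.top_abundant_published().drop(columns="mature_sequence")
        assert top_n(counts, 1).index.tolist() == ["pxy-mir-1-3p"]
        assert top_n(counts, 99).shape[0] == 10

    def test_requires_expression_in_all_libraries(self):
        counts = pd.DataFrame({"TW": [10, 9], "T": [0, 9]}, index=["a", "b"])
        assert top_n(counts, 5).index.tolist() == ["b"]

    def test_ties_break_lexicographically(self):
        counts = pd.DataFrame({"TW": [7, 7, 7]}, index=["c", "a", "b"])
        assert top_n(counts, 3).index.tolist() == ["a", "b", "c"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n(pd.DataFrame({"TW": [1]}), 0)


def test_call_params_validate_alpha():
    with pytest.raises(ValueError):
        DeCallParams(alpha=1.5)
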