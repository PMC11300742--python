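import numpy as np
import pandas as pd
import pytest

from segqa.cohort_stats import (
    CrossTab,
    DegenerateTableError,
    ScoreTable,
    chi_square_test,
    cross_tabulate,
    icc_consistency,
    mann_whitney_test,
    score_summary,
    subgroup_compare,
)


def icc3_ss_oracle(r):
    """ICC(3,1) straight from the two-way ANOVA sums of squares."""
    r = np.asarray(r, float)
    n, k = r.shape
    gm = r.mean()
    ss_rows = k * ((r.mean(axis=1) - gm) ** 2).sum()
    ss_cols = n * ((r.mean(axis=0) - gm) ** 2).sum()
    ss_err = ((r - gm) ** 2).sum() - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestScoreSummary:
    def test_degenerate_distribution(self):
        s = score_summary(ScoreTable({5: 10}))
        assert s["mean"] == 5.0
        assert s["sd"] == 0.0
        assert s["fraction_ge3"] == 1.0

    def test_sd_needs_two_observations(self):
        with pytest.raises(ValueError):
            score_summary(ScoreTable({4: 1}))

    def test_sd_matches_direct_formula(self):
        counts = {2: 6, 3: 42, 4: 37, 5: 12}
        x = np.repeat(list(counts), list(counts.values())).astype(float)
        expected_sd = np.sqrt(((x - x.mean()) ** 2).sum() / (len(x) - 1))
        assert score_summary(ScoreTable(counts))["sd"] == pytest.approx(expected_sd)

    def test_rejects_out_of_scale_levels(self):
        with pytest.raises(ValueError):
            ScoreTable({0: 3})


class TestCrossTab:
    def test_diagonal_on_identical_scores(self):
        scores = [3, 3, 4, 5, 2, 4, 4, 3, 5, 2]
        ct = cross_tabulate(scores, scores)
        assert np.all(ct.cells[~np.eye(len(ct.rows), dtype=bool)] == 0)
        assert ct.n == 10

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            cross_tabulate([1, 2], [1])
        with pytest.raises(ValueError):
            cross_tabulate([], [])

    def test_marginals_sum_to_total(self):
        ct = CrossTab(rows=(2, 3), cols=(2, 3), cells=np.array([[1, 2], [3, 4]]))
        assert ct.row_totals.sum() == ct.col_totals.sum() == ct.n == 10


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chi_square_test(np.array([[10, 10], [10, 10]]))
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_separation_hand_computed(self):
        # expected cells all 10; chi2 = 4 * (20-10)^2/10 = 40
        res = chi_square_test(np.array([[20, 0], [0, 20]]))
        assert res["statistic"] == pytest.approx(40.0)
        assert res["df"] == 1

    def test_zero_rows_dropped_then_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(np.array([[5, 5], [0, 0]]))

    def test_permutation_invariance(self, rng):
        t = rng.integers(0, 20, size=(4, 3))
        t[0, 0] += 1  # ensure non-degenerate
        base = chi_square_test(t)["statistic"]
        perm = t[rng.permutation(4)][:, rng.permutation(3)]
        assert chi_square_test(perm)["statistic"] == pytest.approx(base)

    def test_proportional_rows_give_zero(self):
        res = chi_square_test(np.array([[2, 4, 6], [4, 8, 12]]))
        assert res["statistic"] == pytest.approx(0.0)


class TestMannWhitney:
    def test_full_tie_u_is_half_product(self):
        res = mann_whitney_test([1, 1], [1, 1])
        assert res["U"] == pytest.approx(2 * 2 / 2)

    def test_separated_groups_exact_enumeration(self):
        # all 20 rank assignments enumerable; one-sided p = 1/20
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res["U"] in (0.0, 9.0)
        assert res["method"] == "exact"
        assert res["p_two_sided"] == pytest.approx(2 / 20)

    def test_method_selection(self):
        a = np.arange(25, dtype=float)
        b = np.arange(25, dtype=float) + 0.5
        assert mann_whitney_test(a, b)["method"] == "asymptotic"  # 625 > 400
        assert mann_whitney_test(a[:10], b[:10])["method"] == "exact"
        assert mann_whitney_test([1, 1, 2], [2, 3, 4])["method"] == "asymptotic"  # tie

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestICC:
    def test_identical_raters(self):
        r = np.column_stack([[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]])
        assert icc_consistency(r) == pytest.approx(1.0)

    def test_shift_invariance(self):
        r1 = np.array([1, 3, 2, 5, 4, 2, 3], float)
        shifted = np.column_stack([r1, r1 + 1])
        assert icc_consistency(shifted) == pytest.approx(1.0)

    def test_joint_affine_rescaling_invariance(self, rng):
        r = rng.integers(1, 6, size=(12, 2)).astype(float)
        base = icc_consistency(r)
        assert icc_consistency(2.5 * r + 3) == pytest.approx(base)

    @pytest.mark.parametrize("seed", [9, 21, 33])
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.integers(1, 6, size=(30, 2)).astype(float)
        assert icc_consistency(r) == pytest.approx(icc3_ss_oracle(r), abs=1e-10)

    def test_zero_between_case_variance_errors(self):
        r = np.column_stack([[3, 3, 3, 3], [2, 2, 2, 2]])
        with pytest.raises(ValueError, match="between-case variance"):
            icc_consistency(r)

    def test_needs_three_cases(self):
        with pytest.raises(ValueError):
            icc_consistency(np.array([[1, 2], [3, 4]], float))


class TestSubgroupCompare:
    @staticmethod
    def _cohort(rng):
        n = 40
        return pd.DataFrame(
            {
                "status": ["newly_diagnosed"] * 10 + ["recurrent"] * 30,
                "focality": ["unifocal"] * 30 + ["multifocal"] * 10,
                "wt_dice": rng.uniform(0.4, 0.9, size=n),
                "score": rng.integers(2, 6, size=n),
            }
        )

    def test_planted_dsc_effect_detected(self, rng):
        df = self._cohort(rng)
        df.loc[df.status == "newly_diagnosed", "wt_dice"] = rng.normal(0.85, 0.02, 10)
        df.loc[df.status == "recurrent", "wt_dice"] = rng.normal(0.60, 0.05, 30)
        res = subgroup_compare(df, "status", "dsc")
        assert res["levels"]["newly_diagnosed"]["median"] > res["levels"]["recurrent"]["median"]
        assert res["p_two_sided"] < 0.05

    def test_identical_score_distributions_p_one(self):
        df = pd.DataFrame(
            {
                "status": ["newly_diagnosed"] * 20 + ["recurrent"] * 20,
                "focality": ["unifocal"] * 40,
                "wt_dice": 0.7,
                "score": [3, 4] * 10 + [3, 4] * 10,
            }
        )
        res = subgroup_compare(df, "status", "semiquant")
        assert res["p"] == pytest.approx(1.0)

    def test_absent_level_errors(self, rng):
        df = self._cohort(rng)
        df["status"] = "recurrent"
        with pytest.raises(ValueError, match="absent"):
            subgroup_compare(df, "status", "dsc")
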