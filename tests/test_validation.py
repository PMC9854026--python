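"""Calibration table, Hosmer-Lemeshow, ROC/AUC and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vbacval import (
    Cohort,
    auc_with_ci,
    calibration_table,
    decile_bin,
    decile_bins,
    hosmer_lemeshow,
    predicted_summary,
    prevalence,
    roc_curve,
)
from vbacval.cohort import DomainError

from .conftest import make_antenatal


def concordance_auc(scores, labels):
    """Brute-force all-pairs concordance oracle (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


class TestPrevalence:
    @pytest.mark.parametrize(
        "n_vbac, n_total, expected",
        [(599, 714, 83.89), (578, 697, 82.92)],
    )
    def test_registry_fractions(self, n_vbac, n_total, expected):
        records = [make_antenatal(outcome="VBAC")] * n_vbac + [
            make_antenatal(outcome="ERCS")
        ] * (n_total - n_vbac)
        result = prevalence(Cohort(records, "antenatal"))
        # 578/697 = 82.927%, printed as 82.92 (truncated): compare to 1 ulp
        # of the printed 2-dp precision rather than by re-rounding
        assert result.percent == pytest.approx(expected, abs=0.01)
        assert (result.numerator, result.denominator) == (n_vbac, n_total)

    def test_all_vbac_is_100(self):
        cohort = Cohort([make_antenatal(outcome="VBAC")] * 5, "antenatal")
        assert prevalence(cohort).percent == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(DomainError):
            prevalence(Cohort([], "antenatal"))


class TestDecileBin:
    @pytest.mark.parametrize(
        "pct, expected",
        [(0.0, 1), (10.0, 1), (10.0001, 2), (20.0, 2), (90.54, 10), (100.0, 10)],
    )
    def test_boundary_convention(self, pct, expected):
        assert decile_bin(pct) == expected

    def test_exhaustive_grid_partitions(self):
        grid = np.round(np.arange(0, 100.01, 0.01), 2)
        bins = decile_bins(grid)
        assert set(bins) == set(range(1, 11))
        # brute-force partition check against the scalar definition
        brute = np.array([1 if p <= 10 else int(np.ceil(p / 10 - 1e-12)) for p in grid])
        np.testing.assert_array_equal(bins, brute)

    @pytest.mark.parametrize("bad", [-0.1, 100.1, np.nan])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DomainError):
            decile_bin(bad)


class TestCalibrationTable:
    @pytest.mark.parametrize("n, k, expected", [(222, 201, 90.5), (200, 179, 89.5)])
    def test_top_decile_observed_proportions(self, n, k, expected):
        scores = np.full(n, 0.95)
        outcomes = np.array([1] * k + [0] * (n - k))
        table = calibration_table(scores, outcomes)
        row = table.rows[table.rows["label"] == "91-100"].iloc[0]
        assert (row["n"], row["attended_vb"]) == (n, k)
        assert round(row["observed_probability"], 1) == expected

    def test_single_populated_bin(self):
        table = calibration_table(np.full(7, 0.95), np.ones(7))
        populated = table.rows[table.rows["n"] > 0]
        assert list(populated["bin"]) == [10]
        assert populated.iloc[0]["observed_probability"] == 100.0
        empty = table.rows[table.rows["n"] == 0]
        assert empty["observed_probability"].isna().all()

    def test_conservation_invariant(self, synthetic_antenatal_cohort):
        from vbacval import score_cohort

        scores = score_cohort(synthetic_antenatal_cohort, "antenatal")
        outcomes = synthetic_antenatal_cohort.outcomes()
        table = calibration_table(scores, outcomes)
        assert table.rows["n"].sum() == len(synthetic_antenatal_cohort)
        assert table.rows["attended_vb"].sum() == sum(o == "VBAC" for o in outcomes)

    def test_wilson_within_bounds_wald_may_exceed(self):
        scores = np.full(20, 0.95)
        outcomes = np.array([1] * 19 + [0])
        wilson = calibration_table(scores, outcomes, ci_method="wilson").rows.iloc[9]
        wald = calibration_table(scores, outcomes, ci_method="wald").rows.iloc[9]
        assert 0.0 <= wilson["ci_low"] <= wilson["ci_high"] <= 100.0
        assert wald["ci_high"] > 100.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            calibration_table(np.full(3, 0.5), np.ones(4))


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # two groups whose observed counts equal the summed predictions
        scores = np.array([0.25] * 4 + [0.75] * 4)
        outcomes = np.array([1, 0, 0, 0, 1, 1, 1, 0])
        res = hosmer_lemeshow(scores, outcomes)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_constructed_two_group_statistic(self):
        # group 1: n=10, p=0.45 each -> E=4.5, O=7: (2.5)^2/(4.5*0.55)
        # group 2: n=10, p=0.55 each -> E=5.5, O=3: (2.5)^2/(5.5*0.45)
        # total = 12.5/2.475 = 5.050505...
        scores = np.array([0.45] * 10 + [0.55] * 10)
        outcomes = np.array([1] * 7 + [0] * 3 + [1] * 3 + [0] * 7)
        res = hosmer_lemeshow(scores, outcomes)
        assert res.statistic == pytest.approx(12.5 / 2.475)
        assert res.df == len(res.table) - 2

    def test_statistic_zero_iff_observed_matches_expected(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.05, 0.95, 300)
        outcomes = rng.random(300) < scores
        res = hosmer_lemeshow(scores, outcomes)
        mismatch = np.any(res.table["observed"] != res.table["expected"])
        assert (res.statistic > 0) == bool(mismatch)

    def test_df_policies(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.05, 0.95, 500)
        outcomes = rng.random(500) < scores
        dev = hosmer_lemeshow(scores, outcomes, df_policy="development")
        val = hosmer_lemeshow(scores, outcomes, df_policy="validation")
        assert val.df == dev.df + 2
        assert val.statistic == pytest.approx(dev.statistic)

    def test_equal_size_binning_balances_groups(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0.7, 0.99, 1000)  # crowded top deciles
        outcomes = rng.random(1000) < scores
        res = hosmer_lemeshow(scores, outcomes, binning="equal_size")
        sizes = res.table["n"].to_numpy()
        assert sizes.min() >= 50 and len(sizes) >= 8

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            hosmer_lemeshow(np.full(10, 0.95), np.ones(10))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert any(np.allclose(pt, [0.0, 1.0]) for pt in res.points)

    def test_all_ties_give_chance_diagonal(self):
        res = roc_curve(np.full(10, 0.7), [1, 0] * 5)
        assert res.auc == pytest.approx(0.5)
        np.testing.assert_allclose(res.points, [[0, 0], [1, 1]])

    def test_interleaved_example(self):
        res = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError, match="ERCS"):
            roc_curve([0.2, 0.9], ["VBAC", "VBAC"])
        with pytest.raises(DomainError, match="VBAC"):
            roc_curve([0.2, 0.9], ["ERCS", "ERCS"])

    def test_points_monotone_nondecreasing(self, synthetic_antenatal_cohort):
        from vbacval import score_cohort

        scores = score_cohort(synthetic_antenatal_cohort, "antenatal")
        res = roc_curve(scores, synthetic_antenatal_cohort.outcomes())
        assert np.all(np.diff(res.points[:, 0]) >= 0)
        assert np.all(np.diff(res.points[:, 1]) >= 0)

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_auc_equals_concordance_oracle(self, data):
        n = data.draw(st.integers(6, 50))
        scores = data.draw(
            st.lists(st.floats(0.01, 0.99).map(lambda v: round(v, 2)),
                     min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        res = roc_curve(np.array(scores), np.array(labels))
        assert res.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(0.01, 0.99, 80)
        labels = rng.random(80) < 0.7
        a = roc_curve(scores, labels)
        b = roc_curve(np.exp(3 * scores), labels)
        np.testing.assert_allclose(a.points, b.points)
        assert a.auc == pytest.approx(b.auc)

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        scores = np.round(rng.uniform(0.01, 0.99, 200), 2)
        labels = rng.random(200) < 0.6
        ours = roc_curve(scores, labels).auc
        theirs = sklearn_metrics.roc_auc_score(labels, scores)
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestAucCi:
    def test_perfect_separation_clips_to_one(self):
        roc = roc_curve([0.9, 0.8, 0.7, 0.2, 0.1, 0.05], [1, 1, 1, 0, 0, 0])
        res = auc_with_ci(roc)
        assert res.ci_high == 1.0

    @pytest.mark.parametrize("method", ["delong", "hanley_mcneil"])
    def test_interval_brackets_auc(self, method, synthetic_antenatal_cohort):
        from vbacval import score_cohort

        scores = score_cohort(synthetic_antenatal_cohort, "antenatal")
        roc = roc_curve(scores, synthetic_antenatal_cohort.outcomes())
        res = auc_with_ci(roc, method=method)
        assert res.ci_low < res.auc < res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0

    def test_tiny_class_flags_undefined_ci(self):
        roc = roc_curve([0.9, 0.3, 0.5], [1, 0, 1])
        with pytest.warns(UserWarning):
            res = auc_with_ci(roc)
        assert res.ci_low is None and res.ci_high is None

    def test_delong_narrows_with_sample_size(self):
        rng = np.random.default_rng(6)

        def width(n):
            scores = rng.uniform(0, 1, n)
            labels = rng.random(n) < scores
            res = auc_with_ci(roc_curve(scores, labels))
            return res.ci_high - res.ci_low

        assert width(2000) < width(100)


class TestPredictedSummary:
    def test_two_scores_hand_arithmetic(self):
        mean, sd = predicted_summary(np.array([0.7, 0.9]))
        assert mean == pytest.approx(80.0)
        assert sd == pytest.approx(14.142135, abs=1e-4)

    def test_single_score_flags_undefined_sd(self):
        with pytest.warns(UserWarning):
            mean, sd = predicted_summary(np.array([0.8]))
        assert mean == pytest.approx(80.0) and np.isnan(sd)

    def test_mean_invariant_under_permutation(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.99, 50)
        m1, s1 = predicted_summary(p)
        m2, s2 = predicted_summary(p[::-1].copy())
        assert m1 == pytest.approx(m2) and s1 == pytest.approx(s2)
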