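"""Statistical engine: oracles, error control and clinical rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glymph_alps import (
    SubgroupRules,
    assign_subgroups,
    bh_adjust,
    compare_groups,
    generate_cohort,
    icc_average,
    ks_normality,
    logistic_discrimination,
    longitudinal_regression,
    propensity_match,
    rate_of_change,
    spearman_fdr,
)


def bh_oracle(pvals):
    """Brute-force step-up: adj_i = min over j with p_(j) >= p_(i) of p_(j)*m/j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        tail = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(tail))
    return adj


class TestKSNormality:
    def test_gaussian_sample_flagged_normal(self):
        rng = np.random.default_rng(42)
        r = ks_normality(rng.normal(10, 2, 500))
        assert r.extra["normal"]

    def test_uniform_sample_flagged_non_normal(self):
        rng = np.random.default_rng(42)
        r = ks_normality(rng.uniform(0, 1, 500))
        assert not r.extra["normal"]

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ks_normality([1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            ks_normality([1.0, 1.0, 1.0, 1.0])


class TestCompareGroups:
    def test_null_rejection_rate_nominal(self):
        # identical distributions: the omnibus test should reject at
        # about the nominal 5% whatever branch the gate picks
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "group": np.repeat(["a", "b", "c"], 25),
                    "y": rng.normal(0, 1, 75),
                }
            )
            omnibus = compare_groups(df, "y")[0]
            rejections += omnibus.p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_separated_groups_detected_with_posthoc(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": np.repeat(["HC", "PD", "piRBD"], [129, 168, 119]),
                "y": np.concatenate(
                    [
                        rng.normal(1.31, 0.17, 129),
                        rng.normal(1.20, 0.17, 168),
                        rng.normal(1.25, 0.17, 119),
                    ]
                ),
            }
        )
        res = compare_groups(df, "y")
        assert res[0].p < 0.001
        by_name = {r.name: r for r in res}
        assert by_name["y:HC_vs_PD"].p_adjusted < 0.01
        # Bonferroni: adjusted p is raw * number of pairs, capped
        for r in res[1:]:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))

    def test_power_at_reported_group_parameters(self):
        # groups at the reported ALPS means/SDs and sizes: the omnibus
        # contrast is overwhelmingly significant, as in the source table
        rng = np.random.default_rng(20)
        hits = 0
        n_rep = 500
        labels = np.repeat(["HC", "piRBD", "PD"], [129, 119, 168])
        for _ in range(n_rep):
            y = np.concatenate(
                [
                    rng.normal(1.31, 0.17, 129),
                    rng.normal(1.25, 0.17, 119),
                    rng.normal(1.20, 0.17, 168),
                ]
            )
            df = pd.DataFrame({"group": labels, "y": y})
            hits += compare_groups(df, "y")[0].p < 0.001
        assert hits / n_rep >= 0.95

    def test_two_group_branches(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"group": np.repeat(["a", "b"], 60), "y": rng.normal(0, 1, 120)}
        )
        res = compare_groups(df, "y")
        assert res[0].method in ("t-test", "mann-whitney")
        skew = pd.DataFrame(
            {"group": np.repeat(["a", "b"], 200), "y": rng.exponential(1, 400) ** 3}
        )
        assert compare_groups(skew, "y")[0].method == "mann-whitney"

    def test_categorical_chi_square(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b", "c"], 100),
                "flag": rng.integers(0, 2, 300),
            }
        )
        res = compare_groups(df, "flag", categorical=True)
        assert res[0].method == "chi-square"
        assert len(res) == 4  # omnibus + 3 pairs

    def test_degenerate_variance_errors(self):
        df = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5, "y": [1.0] * 10})
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups(df, "y")


class TestICC:
    def test_identical_raters_give_unity(self, rng):
        x = rng.normal(1.25, 0.17, 40)
        r = icc_average(np.column_stack([x, x]))
        assert r.estimate == pytest.approx(1.0, abs=1e-12)

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(4)
        ratings = rng.normal(0, 1, (1000, 2))
        r = icc_average(ratings)
        assert abs(r.estimate) < 0.1

    def test_worked_table_matches_anova_oracle(self):
        # independent mean-squares decomposition on a fixed 6x2 table
        x = np.array(
            [[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]]
        )
        n, k = x.shape
        grand = x.mean()
        msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (np.sum((x - grand) ** 2) - msr * (n - 1) - msc * (k - 1)) / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (msc - mse) / n)
        r = icc_average(x)
        assert r.estimate == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        subj = rng.normal(1.25, 0.17, 60)
        ratings = np.column_stack(
            [subj + rng.normal(0, 0.05, 60), subj + rng.normal(0.02, 0.05, 60)]
        )
        long = pd.DataFrame(
            {
                "s": np.repeat(np.arange(60), 2),
                "r": np.tile(["a", "b"], 60),
                "y": ratings.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="y")
        for model, label in (("icc2k", "ICC(A,k)"), ("icc3k", "ICC(C,k)")):
            mine = icc_average(ratings, model=model)
            row = ref[ref.Type == label].iloc[0]
            assert mine.estimate == pytest.approx(row.ICC, abs=1e-10)
            lo, hi = row.CI95
            assert mine.ci_low == pytest.approx(lo, abs=0.005)
            assert mine.ci_high == pytest.approx(hi, abs=0.005)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="at least 5"):
            icc_average(np.ones((3, 2)))
        with pytest.raises(ValueError, match="missing"):
            icc_average(np.array([[1.0, np.nan]] * 6))


class TestPropensityMatch:
    @staticmethod
    def _shifted_arms(n=200, shift=5.0, seed=6):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "treated": np.repeat([1, 0], n),
                "age": np.concatenate(
                    [rng.normal(60 + shift, 8, n), rng.normal(60, 8, n)]
                ),
                "sex": rng.choice(["F", "M"], 2 * n),
            }
        )

    def test_balance_improves_on_shifted_arms(self):
        df = self._shifted_arms()
        matched, balance = propensity_match(df, "treated")
        age = balance.set_index("covariate").loc["age"]
        assert abs(age.smd_after) < abs(age.smd_before)

    def test_no_control_reused(self):
        df = self._shifted_arms()
        matched, _ = propensity_match(df, "treated")
        controls = matched[matched.treated == 0]
        assert controls.index.is_unique
        assert len(matched) <= 2 * min((df.treated == 1).sum(), (df.treated == 0).sum())

    def test_identical_arms_all_matched(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "treated": np.repeat([1, 0], 300),
                "age": rng.normal(60, 8, 600),
                "sex": rng.choice(["F", "M"], 600),
            }
        )
        # greedy matching without replacement exhausts nearby controls
        # late in the queue; identical arms still pair nearly everyone
        matched, _ = propensity_match(df, "treated")
        assert (matched.treated == 1).sum() >= 0.9 * 300

    def test_small_arm_rejected(self):
        df = self._shifted_arms(n=9)
        with pytest.raises(ValueError, match="at least 10"):
            propensity_match(df, "treated")


class TestBHAdjust:
    def test_published_longitudinal_family(self):
        # five raw p-values of a reported longitudinal regression family
        raw = [0.0005, 0.040, 0.045, 0.332, 0.442]
        adj = bh_adjust(raw)
        np.testing.assert_allclose(adj[1:], [0.075, 0.075, 0.415, 0.442], atol=1e-12)
        assert adj[0] < 0.01

    def test_nine_member_family_flattens_to_0045(self):
        # four correlated tests inside a nine-test family all adjust to
        # the same 0.045 by the step-up minimum
        raw = [0.007, 0.010, 0.019, 0.020, 0.10, 0.25, 0.41, 0.60, 0.85]
        adj = bh_adjust(raw)
        np.testing.assert_allclose(adj[:4], [0.045, 0.045, 0.045, 0.045], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12)
    )
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_oracle(pvals), atol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSpearmanFDR:
    def test_monotone_pair(self):
        df = pd.DataFrame({"x": np.arange(50.0), "y": np.arange(50.0) ** 2})
        r = spearman_fdr(df, [("x", "y")])[0]
        assert r.estimate == pytest.approx(1.0)
        assert r.p < 1e-10

    def test_generator_round_trip(self):
        rhos = [
            spearman_fdr(
                generate_cohort(seed=s).query("group == 'piRBD'"),
                [("alps_index", "rbdq_hk_ii")],
            )[0].estimate
            for s in range(8)
        ]
        assert np.mean(rhos) == pytest.approx(-0.236, abs=0.1)

    def test_family_adjustment_applied(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(0, 1, (100, 4)), columns=list("abcd"))
        res = spearman_fdr(df, [("a", "b"), ("a", "c"), ("a", "d")], family="f")
        raws = [r.p for r in res]
        np.testing.assert_allclose([r.p_adjusted for r in res], bh_oracle(raws), atol=1e-12)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": np.ones(20), "y": np.arange(20.0)})
        with pytest.raises(ValueError, match="constant"):
            spearman_fdr(df, [("x", "y")])


class TestSubgroups:
    @staticmethod
    def _pd_row(**kw):
        base = dict(
            group="PD", hy_stage=2.0, updrs_iii=20.0, mmse=28, moca=25,
            rbdq_hk_total=10.0, rbdq_hk_ii=3.0, ess=5.0,
        )
        base.update(kw)
        return base

    def test_threshold_rules(self):
        rows = [
            self._pd_row(rbdq_hk_total=18, rbdq_hk_ii=5),  # total > 17 -> sRBD
            self._pd_row(rbdq_hk_total=10, rbdq_hk_ii=8),  # factor II > 7 -> sRBD
            self._pd_row(rbdq_hk_total=17, rbdq_hk_ii=7),  # neither -> nRBD
            self._pd_row(ess=10),  # ESS >= 10 inclusive -> EDS
            self._pd_row(mmse=27, moca=24),  # both at cut -> normal cognition
            self._pd_row(mmse=26, moca=24),  # MMSE below -> CI
            self._pd_row(hy_stage=2.5),  # H-Y <= 2.5 -> early
            self._pd_row(hy_stage=3.0),
        ]
        # pad so the motor tercile SD is defined
        df = pd.DataFrame(rows + [self._pd_row(updrs_iii=u) for u in (5, 15, 40)])
        out = assign_subgroups(df)
        assert out.loc[0, "rbd_group"] == "PD-sRBD"
        assert out.loc[1, "rbd_group"] == "PD-sRBD"
        assert out.loc[2, "rbd_group"] == "PD-nRBD"
        assert out.loc[3, "eds_group"] == "PD-EDS"
        assert out.loc[4, "cognitive_group"] == "PDN"
        assert out.loc[5, "cognitive_group"] == "PD-CI"
        assert out.loc[6, "stage_group"] == "Early-PD"
        assert out.loc[7, "stage_group"] == "Late-PD"

    def test_motor_terciles_from_table_statistics(self, cohort_df):
        out = assign_subgroups(cohort_df)
        pd_rows = out[out.group == "PD"]
        mu, sd = pd_rows.updrs_iii.mean(), pd_rows.updrs_iii.std(ddof=1)
        assert (pd_rows.loc[pd_rows.motor_group == "mild", "updrs_iii"] < mu - sd).all()
        assert (pd_rows.loc[pd_rows.motor_group == "severe", "updrs_iii"] > mu + sd).all()
        assert pd_rows.motor_group.notna().all()

    def test_pirbd_cognitive_labels(self, cohort_df):
        out = assign_subgroups(cohort_df)
        labels = set(out.loc[out.group == "piRBD", "cognitive_group"].dropna())
        assert labels <= {"piRBD-CI", "piRBDN"}
        assert out.loc[out.group == "HC", "rbd_group"].isna().all()


class TestLogisticDiscrimination:
    def test_uninformative_predictor_auc_half(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"group": rng.choice(["PD", "HC"], 2000), "x": rng.normal(0, 1, 2000)}
        )
        _, roc = logistic_discrimination(df, predictors=("x",))
        assert roc["auc"] == pytest.approx(0.5, abs=0.05)

    def test_separation_guard(self):
        df = pd.DataFrame(
            {"group": ["PD"] * 50 + ["HC"] * 50, "x": [1.0] * 50 + [-1.0] * 50}
        )
        with pytest.raises(ValueError, match="separation"):
            logistic_discrimination(df, predictors=("x",))

    def test_synthetic_cohort_discrimination(self, cohort_df):
        res, roc = logistic_discrimination(cohort_df)
        assert roc["auc"] > 0.55
        by_name = {r.name: r for r in res}
        # lower ALPS index in PD: odds ratio below 1
        assert by_name["or:alps_index"].estimate < 1.0
        assert by_name["or:alps_index"].ci_low < by_name["or:alps_index"].estimate


class TestRateOfChange:
    def test_worked_example(self):
        assert rate_of_change(1.30, 1.20, 20.0) == pytest.approx(-0.5)

    def test_zero_change(self):
        assert rate_of_change(5.0, 5.0, 12.0) == 0.0

    def test_exact_antisymmetry(self, rng):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        t = rng.uniform(12, 40, 100)
        np.testing.assert_array_equal(rate_of_change(a, b, t), -rate_of_change(b, a, t))

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rate_of_change(1.0, 2.0, 0.0)


class TestLongitudinalRegression:
    @staticmethod
    def _table(n=200, seed=11):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        return pd.DataFrame(
            {
                "x": x,
                "y": x.copy(),
                "age": rng.normal(60, 8, n),
                "sex": rng.choice(["F", "M"], n),
            }
        )

    def test_identity_outcome_gives_unit_standardised_slope(self):
        df = self._table()
        r = longitudinal_regression(df, "y", "x")
        assert r.estimate == pytest.approx(1.0, abs=1e-10)
        assert r.p < 1e-20

    def test_collinear_covariates_rejected(self):
        df = self._table()
        df["age2"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            longitudinal_regression(df, "y", "x", covariates=("age", "age2"))

    def test_raw_coefficient_reported(self):
        df = self._table()
        df["y"] = 3.0 * df["x"] + 1.0
        r = longitudinal_regression(df, "y", "x")
        assert r.extra["coef_raw"] == pytest.approx(3.0, abs=1e-10)
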