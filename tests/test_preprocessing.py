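"""Scale scoring, reliability, residualization and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcots.preprocessing import (
    SCALES,
    Residualizer,
    cronbach_alpha,
    phenotypic_correlation,
    residualize,
    score_scale,
)


class TestScoreScale:
    def test_scale_definitions_match_instruments(self):
        assert (SCALES["asrs"].n_items, SCALES["asrs"].likert_levels) == (6, 5)
        assert (SCALES["cprs_r"].n_items, SCALES["cprs_r"].likert_levels) == (12, 4)
        assert (SCALES["rsdbd_adhd"].n_items, SCALES["rsdbd_odd"].n_items,
                SCALES["rsdbd_cd"].n_items) == (18, 8, 8)
        assert (SCALES["scared"].n_items, SCALES["scared"].likert_levels) == (5, 3)
        assert (SCALES["smfq"].n_items, SCALES["smfq"].likert_levels) == (13, 3)

    @pytest.mark.parametrize(
        "responses,scale,expected",
        [
            (np.zeros((1, 6)), "asrs", 0.0),
            (np.full((1, 6), 4.0), "asrs", 24.0),  # 6 items x top code 4
            (np.full((1, 13), 2.0), "smfq", 26.0),
        ],
    )
    def test_sum_scores(self, responses, scale, expected):
        assert score_scale(responses, scale)[0] == expected

    def test_prorating_one_missing_item(self):
        # 12-item scale, one missing: answered sum scaled by 12/11, half-even
        resp = np.full((1, 12), 2.0)
        resp[0, 0] = np.nan
        expected = np.round(22 * 12 / 11)  # 24.0
        assert score_scale(resp, "cprs_r")[0] == expected

    def test_prorating_toy_three_items(self):
        # hand computation on a 3-item toy: (1+2) * 3/2 = 4.5 -> 4 (half-even)
        from mcots.preprocessing import ScaleDefinition

        toy = ScaleDefinition("toy", 3, 4)
        resp = np.array([[1.0, 2.0, np.nan]])
        assert score_scale(resp, toy, prorate_threshold=0.6)[0] == 4.0

    def test_below_threshold_scores_missing(self):
        resp = np.full((1, 6), 1.0)
        resp[0, :2] = np.nan  # 4/6 answered < 80%
        assert np.isnan(score_scale(resp, "asrs")[0])

    def test_out_of_range_names_item(self):
        resp = np.zeros((1, 6))
        resp[0, 3] = 9.0
        with pytest.raises(ValueError, match="item 3"):
            score_scale(resp, "asrs")

    @given(st.integers(0, 5), st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_any_item(self, item, data):
        base = np.array(
            [data.draw(st.integers(0, 4)) for _ in range(6)], dtype=float
        )[None, :]
        if base[0, item] == 4:
            base[0, item] = 3
        raised = base.copy()
        raised[0, item] += 1
        assert score_scale(raised, "asrs")[0] >= score_scale(base, "asrs")[0]


class TestCronbachAlpha:
    def test_two_items_correlation_half(self):
        # Spearman-Brown: alpha = 2r/(1+r) = 2/3 at r = 0.5
        rng = np.random.default_rng(0)
        z = rng.standard_normal((200_00, 3))
        x = z[:, 0]
        y = 0.5 * z[:, 0] + np.sqrt(1 - 0.25) * z[:, 1]
        assert cronbach_alpha(np.column_stack([x, y])) == pytest.approx(
            2 * 0.5 / 1.5, abs=0.02
        )

    def test_identical_items_give_one(self):
        x = np.arange(10.0)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10_000, 5))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        z = rng.standard_normal((500, 1))
        X = 0.6 * z + 0.8 * rng.standard_normal((500, 4))
        ours = cronbach_alpha(X)
        theirs = pingouin.cronbach_alpha(pd.DataFrame(X))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    @given(st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        assert cronbach_alpha(X + shift) == pytest.approx(cronbach_alpha(X))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(np.ones((10, 3)))


class TestResidualize:
    @staticmethod
    def toy_frame():
        return pd.DataFrame(
            {"score": [1.0, 3.0, 2.0, 5.0, 4.0], "age": [20.0, 25, 30, 35, 40]}
        )

    def test_matches_normal_equations(self):
        df = self.toy_frame()
        out = residualize(df, ["score"], ["age"])
        D = np.column_stack([np.ones(5), df["age"]])
        beta = np.linalg.solve(D.T @ D, D.T @ df["score"])
        expected = df["score"] - D @ beta
        assert np.allclose(out["score_resid"], expected, atol=1e-10)

    def test_residuals_orthogonal_and_centered(self, demo_cohort):
        from mcots.preprocessing import residualize_cohort

        out = residualize_cohort(demo_cohort)
        kids = out[out["role"] == "child"]
        r = kids["adhd_age8_resid"]
        ok = r.notna()
        assert abs(r[ok].mean()) < 1e-10
        for cov in ("maternal_age", "parity", "birth_year", "sex"):
            assert abs(np.corrcoef(r[ok], kids.loc[ok, cov])[0, 1]) < 1e-10

    def test_idempotent(self):
        df = self.toy_frame()
        once = residualize(df, ["score"], ["age"])
        again = residualize(
            once.rename(columns={"score_resid": "r1"}), ["r1"], ["age"]
        )
        assert np.allclose(again["r1_resid"], once["score_resid"], atol=1e-10)

    def test_collinear_covariates_error(self):
        df = self.toy_frame()
        df["age2"] = 2.0 * df["age"]
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            residualize(df, ["score"], ["age", "age2"])

    def test_missing_sex_column_errors(self):
        df = self.toy_frame()
        with pytest.raises(ValueError, match="sex"):
            Residualizer(covariates=["age", "sex"], targets=["score"]).fit(df)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"score": rng.standard_normal(100), "a": rng.standard_normal(100),
             "b": rng.standard_normal(100)}
        )
        ours = residualize(df, ["score"], ["a", "b"])["score_resid"]
        theirs = sm.OLS(df["score"], sm.add_constant(df[["a", "b"]])).fit().resid
        assert np.allclose(ours, theirs, atol=1e-8)


class TestPhenotypicCorrelation:
    def test_self_correlation_is_one(self):
        x = np.arange(20.0)
        r, _ = phenotypic_correlation(x, x + 0.0)
        assert r == pytest.approx(1.0)

    def test_independent_pairs_ci_covers_zero(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 10_000))
        r, (lo, hi) = phenotypic_correlation(x, y)
        assert abs(r) < 0.05 and lo < 0.0 < hi

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            phenotypic_correlation(np.ones(20), np.arange(20.0))

    def test_cluster_option_widens_interval(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 400))
        clusters = np.repeat(np.arange(100), 4)
        _, (lo1, hi1) = phenotypic_correlation(x, y)
        _, (lo2, hi2) = phenotypic_correlation(x, y, clusters=clusters)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_mother_child_correlation_matches_analytic(self, test_params):
        """With rA=0 but m>0, the mother-child correlation equals
        m * sd(adult) / sd(child) from the closed-form covariance."""
        from tests.conftest import generative_from
        from mcots.simulate import recovery_config, simulate_cohort

        import dataclasses

        p = dataclasses.replace(test_params, rA=0.0, m=0.3)
        gp = generative_from(p, rA=0.0, m=0.3)
        df = simulate_cohort(recovery_config(40_000, seed=9), gp,
                             outcomes=["adhd_age8"])
        mothers = df[df["role"] == "mother"][["person_id", "adhd_adult"]]
        kids = df[df["role"] == "child"][["mother_id", "adhd_age8"]]
        mc = kids.merge(mothers, left_on="mother_id", right_on="person_id")
        r, _ = phenotypic_correlation(mc["adhd_adult"], mc["adhd_age8"])
        expected = 0.3 * np.sqrt(p.adult_variance) / np.sqrt(p.child_variance)
        assert r == pytest.approx(expected, abs=0.02)
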