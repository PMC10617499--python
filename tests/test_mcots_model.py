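"""MCoTS structural model: covariance algebra, fitting, reductions."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcots import likelihood as lk
from mcots.mcots_model import (
    PARAM_NAMES,
    MCoTSModel,
    MCoTSParams,
    _cov_builder_factory,
    expected_covariance,
    family_vectors,
    fit_mcots,
)
from mcots.simulate import CohortConfig, simulate_cohort
from tests.conftest import generative_from


def member_labels(n1, n2):
    return (["m1", "m2"] + [f"c1_{i}" for i in range(n1)]
            + [f"c2_{i}" for i in range(n2)])


class TestExpectedCovariance:
    def test_no_transmission_channels_zero_cross_generation(self, test_params):
        p = dataclasses.replace(test_params, rA=0.0, m=0.0)
        S = expected_covariance(p, ("DZ", 1, 1))
        assert S[0, 2] == S[0, 3] == S[1, 2] == S[1, 3] == 0.0

    def test_mz_mother_child_equals_aunt_child(self, test_params):
        """Children of identical twins share as many genes with their aunt
        as with their mother, so with no phenotypic transmission the two
        covariances coincide."""
        p = dataclasses.replace(test_params, m=0.0)
        S = expected_covariance(p, ("MZ", 1, 1))
        assert S[0, 2] == pytest.approx(S[1, 2], abs=1e-12)
        assert S[0, 3] == pytest.approx(S[0, 2], abs=1e-12)

    def test_entry_formulas_dz(self, test_params):
        p = test_params
        S = expected_covariance(p, ("DZ", 1, 1))
        v1 = p.adult_variance
        s = 0.5 * p.a1**2 + p.c1**2
        assert S[0, 1] == pytest.approx(s)
        assert S[0, 2] == pytest.approx(0.5 * p.rA * p.a1 * p.a2 + p.m * v1)
        assert S[1, 2] == pytest.approx(
            0.5 * 0.5 * p.rA * p.a1 * p.a2 + p.m * s
        )
        assert S[2, 3] == pytest.approx(
            0.25 * 0.5 * p.a2**2
            + 2 * p.m * (0.5 * 0.5 * p.rA * p.a1 * p.a2)
            + p.m**2 * s
        )
        assert S[2, 2] == pytest.approx(p.child_variance)

    def test_within_unit_siblings_share_environment(self, test_params):
        S = expected_covariance(test_params, ("COUSIN", 2, 0))
        p = test_params
        assert S[2, 3] == pytest.approx(
            0.5 * p.a2**2 + p.c2**2
            + 2 * p.m * (0.5 * p.rA * p.a1 * p.a2) + p.m**2 * p.adult_variance
        )

    def test_singleton_two_units_rejected(self, test_params):
        with pytest.raises(ValueError, match="SINGLETON"):
            expected_covariance(test_params, ("SINGLETON", 1, 1))

    @given(
        a1=st.floats(0.1, 0.9), c1=st.floats(0.0, 0.5),
        a2=st.floats(0.1, 0.9), c2=st.floats(0.0, 0.5),
        rA=st.floats(-1.0, 1.0), m=st.floats(-0.3, 0.3),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric_psd_for_admissible_params(self, a1, c1, a2, c2, rA, m):
        p = MCoTSParams(a1=a1, c1=c1, e1=0.5, a2=a2, c2=c2, e2=0.5, rA=rA, m=m)
        for config in [("MZ", 2, 1), ("COUSIN", 1, 2), ("PAT_HALF_SIB", 2, 2)]:
            S = expected_covariance(p, config)
            assert np.allclose(S, S.T)
            assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_monotone_in_rA(self, test_params):
        """Mother-child covariance strictly increases with rA when both
        genetic paths are positive."""
        vals = []
        for ra in (0.0, 0.3, 0.6, 0.9):
            p = dataclasses.replace(test_params, rA=ra)
            vals.append(expected_covariance(p, ("DZ", 1, 1))[0, 2])
        assert np.all(np.diff(vals) > 0)


class TestOracleEquivalence:
    def test_analytic_matches_simulation_moments(self, test_params):
        """Closed-form family covariance equals empirical moments of the
        mechanistic generator (one mixed configuration at moderate n; the
        full configuration sweep runs in the acceptance suite)."""
        gp = generative_from(test_params)
        cfg = CohortConfig(n_families=120_000, rel_mix={"MAT_HALF_SIB": 1.0},
                           children_per_mother={1: 1.0}, seed=31)
        df = simulate_cohort(cfg, gp, outcomes=["adhd_age8"])
        Y = np.array([y for _, y in family_vectors(df, "adhd_adult", "adhd_age8")])
        emp = np.cov(Y.T)
        ana = expected_covariance(test_params, ("MAT_HALF_SIB", 1, 1))
        assert np.abs(emp - ana).max() < 0.015


class TestFitting:
    def test_recovers_generating_parameters(self, small_cohort, test_params):
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=2).fit(small_cohort)
        # single replicate at n=1500: loose sanity bands (3+ MC s.e.)
        assert model.params_.rA == pytest.approx(test_params.rA, abs=0.45)
        assert model.params_.a1 == pytest.approx(test_params.a1, abs=0.15)
        assert model.result_.converged

    def test_truth_deviance_not_below_optimum(self, small_cohort, test_params):
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=2).fit(small_cohort)
        builder = _cov_builder_factory()
        theta_true = test_params.to_theta()
        d_true = lk.fiml_neg2ll(theta_true, model._groups, builder)
        assert d_true >= model.neg2ll_ - 1e-6

    def test_family_order_invariance(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=9)
        a = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1).fit(small_cohort)
        b = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1).fit(shuffled)
        assert a.neg2ll_ == pytest.approx(b.neg2ll_, abs=1e-6)
        assert a.params_.rA == pytest.approx(b.params_.rA, abs=1e-6)

    def test_unit_relabelling_invariance(self, small_cohort, test_params):
        """Swapping the two nuclear units leaves the likelihood unchanged."""
        swapped = small_cohort.copy()
        swapped["nuclear_id"] = 3 - swapped["nuclear_id"].astype(int)
        builder = _cov_builder_factory()
        theta = test_params.to_theta()
        g1, _, _ = lk.group_observations(
            family_vectors(small_cohort, "adhd_adult", "adhd_age8"))
        g2, _, _ = lk.group_observations(
            family_vectors(swapped, "adhd_adult", "adhd_age8"))
        assert lk.fiml_neg2ll(theta, g1, builder) == pytest.approx(
            lk.fiml_neg2ll(theta, g2, builder), abs=1e-8)

    def test_single_group_identification_error(self, test_params):
        gp = generative_from(test_params)
        cfg = CohortConfig(n_families=200, rel_mix={"MZ": 1.0},
                           children_per_mother={1: 1.0}, seed=2)
        df = simulate_cohort(cfg, gp, outcomes=["adhd_age8"])
        with pytest.raises(ValueError, match="identification"):
            MCoTSModel("adhd_adult", "adhd_age8").fit(df)

    def test_wrapper_returns_fit_result(self, small_cohort):
        res = fit_mcots(small_cohort, "adhd_adult", "adhd_age8", n_starts=1)
        assert set(PARAM_NAMES) == set(res.estimates)
        assert np.isfinite(res.neg2ll)

    def test_genetic_share_of_covariance(self, small_cohort):
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1).fit(small_cohort)
        share = model.genetic_share_of_covariance()
        assert 0.0 < share <= 1.5

    def test_sklearn_protocol(self, small_cohort):
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1)
        assert model.get_params()["child_col"] == "adhd_age8"
        clone = model.set_params(random_state=3)
        assert clone.random_state == 3
        model.fit(small_cohort)
        assert np.isfinite(model.score(small_cohort))


class TestReductions:
    def test_reduction_degrees_of_freedom(self, small_cohort):
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1).fit(small_cohort)
        comps = {c.label: c for c in model.reductions()}
        assert comps["drop rA"].delta_df == 1
        assert comps["drop m"].delta_df == 1
        assert comps["drop rA and m"].delta_df == 2
        assert comps["drop adult C"].delta_df == 1
        for c in comps.values():
            assert c.delta_neg2ll >= 0.0
            assert 0.0 <= c.p_value <= 1.0
        assert comps["drop adult C"].boundary is True

    def test_null_data_full_and_reduced_agree(self, test_params):
        """With rA = m = 0 in truth, the doubly reduced model loses almost
        nothing (chi-square(2) noise)."""
        gp = generative_from(test_params, rA=0.0, m=0.0)
        cfg = CohortConfig(
            n_families=3000,
            rel_mix={"MZ": 0.34, "DZ": 0.33, "COUSIN": 0.33},
            children_per_mother={1: 1.0}, seed=77,
        )
        df = simulate_cohort(cfg, gp, outcomes=["adhd_age8"])
        model = MCoTSModel("adhd_adult", "adhd_age8", n_starts=1).fit(df)
        comp = {c.label: c for c in model.reductions()}["drop rA and m"]
        assert comp.delta_neg2ll < 13.8  # chi2(2).ppf(0.999)
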