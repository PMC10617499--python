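"""Extended bivariate twin model: Cholesky algebra, fitting, derived rG."""

import numpy as np
import pytest

from mcots.simulate import BivariateACEParams, simulate_pairs
from mcots.twin_model import (
    CholeskyBivariateParams,
    ExtendedBivariateTwinModel,
    derived_genetic_correlation,
    expected_pair_covariance,
    extract_child_pairs,
    fit_extended_bivariate,
)


def chol(**kw):
    base = dict(a11=0.7, a21=0.3, a22=0.4, c11=0.3, c21=0.1, c22=0.2,
                e11=0.5, e21=0.1, e22=0.5)
    base.update(kw)
    return CholeskyBivariateParams(**base)


class TestDerivedGeneticCorrelation:
    def test_hand_checked_value(self):
        # 0.7*0.3 / (0.7 * 0.5) = 0.6
        assert derived_genetic_correlation(chol()) == pytest.approx(0.6)

    def test_zero_cross_path_gives_zero(self):
        assert derived_genetic_correlation(chol(a21=0.0)) == 0.0

    def test_pure_shared_path_gives_one(self):
        assert derived_genetic_correlation(chol(a22=0.0)) == pytest.approx(1.0)

    def test_zero_genetic_variance_errors(self):
        with pytest.raises(ValueError, match="zero genetic variance"):
            derived_genetic_correlation(chol(a11=0.0))
        with pytest.raises(ValueError, match="zero genetic variance"):
            derived_genetic_correlation(chol(a21=0.0, a22=0.0))


class TestExpectedPairCovariance:
    def test_cousins_share_no_environment(self):
        p = chol()
        S = expected_pair_covariance(p, "COUSIN")
        C = p.component("C")
        A = p.component("A")
        assert np.allclose(S[:2, 2:], 0.125 * A)  # C contributes exactly 0
        S_full = expected_pair_covariance(p, "FULL_SIB")
        assert np.allclose(S_full[:2, 2:], 0.5 * A + C)

    def test_independent_traits_zero_cross_entries(self):
        p = chol(a21=0.0, c21=0.0, e21=0.0)
        S = expected_pair_covariance(p, "FULL_SIB")
        assert S[0, 3] == S[1, 2] == 0.0  # cross-trait cross-person

    def test_explicit_gamma_configuration(self):
        p = chol()
        S = expected_pair_covariance(p, (0.25, 0.0))  # children of MZ mothers
        assert np.allclose(S[:2, 2:], 0.25 * p.component("A"))

    def test_unknown_code_errors(self):
        with pytest.raises(ValueError):
            expected_pair_covariance(chol(), "STEP_SIB")

    def test_matches_simulation_moments(self):
        pars = BivariateACEParams(rG=0.84)
        p = pars.to_cholesky()
        for rel in ("MAT_HALF_SIB", "COUSIN"):
            pairs = simulate_pairs(120_000, pars, rel_mix={rel: 1.0}, seed=4)
            Y = pairs[["trait1_a", "trait2_a", "trait1_b", "trait2_b"]].to_numpy()
            assert np.abs(np.cov(Y.T) - expected_pair_covariance(p, rel)).max() < 0.015


class TestFitting:
    def test_standardized_shares_sum_to_one(self):
        pairs = simulate_pairs(4000, BivariateACEParams(rG=0.7), seed=8)
        model = ExtendedBivariateTwinModel(n_starts=1).fit(pairs)
        shares = model.params_.standardized_shares()
        assert shares["A1_share"] + shares["C1_share"] + shares["E1_share"] == (
            pytest.approx(1.0, abs=1e-8))
        assert shares["A2_share"] + shares["C2_share"] + shares["E2_share"] == (
            pytest.approx(1.0, abs=1e-8))

    def test_trait_order_invariance_of_rG(self):
        pairs = simulate_pairs(4000, BivariateACEParams(rG=0.7), seed=9)
        swapped = pairs.rename(columns={
            "trait1_a": "trait2_a", "trait2_a": "trait1_a",
            "trait1_b": "trait2_b", "trait2_b": "trait1_b"})
        a = ExtendedBivariateTwinModel(n_starts=1).fit(pairs)
        b = ExtendedBivariateTwinModel(n_starts=1).fit(swapped)
        assert a.rG_ == pytest.approx(b.rG_, abs=5e-3)

    def test_pure_environment_flags_unidentified_rG(self):
        pars = BivariateACEParams(va1=0.0, vc1=0.0, ve1=1.0,
                                  va2=0.0, vc2=0.0, ve2=1.0, rG=0.0)
        pairs = simulate_pairs(3000, pars, seed=10)
        model = ExtendedBivariateTwinModel(n_starts=1).fit(pairs)
        assert model.rG_identified_ is False

    def test_single_group_identification_error(self):
        pairs = simulate_pairs(500, rel_mix={"FULL_SIB": 1.0}, seed=1)
        with pytest.raises(ValueError, match="identification"):
            ExtendedBivariateTwinModel().fit(pairs)

    def test_classical_bivariate_limit(self):
        """On sibling-vs-cousin data the cross-trait cross-person moments
        identify the same rG as Falconer-style moment contrasts."""
        pars = BivariateACEParams(rG=0.6)
        pairs = simulate_pairs(150_000, pars, seed=12)
        model = ExtendedBivariateTwinModel(n_starts=1).fit(pairs)
        # Falconer-style moments on trait 1: regress the observed pair
        # correlation per group on (gamma_A, gamma_C) to solve for (va, vc)
        rows = []
        for rel, grp in pairs.groupby("pair_rel"):
            r = np.corrcoef(grp["trait1_a"], grp["trait1_b"])[0, 1]
            rows.append((grp["gamma_a"].iloc[0], grp["gamma_c"].iloc[0], r))
        G = np.array([[ga, gc] for ga, gc, _ in rows])
        r_obs = np.array([r for *_, r in rows])
        va_moment, vc_moment = np.linalg.lstsq(G, r_obs, rcond=None)[0]
        assert model.params_.a11**2 == pytest.approx(va_moment, abs=0.05)
        assert model.params_.c11**2 == pytest.approx(vc_moment, abs=0.05)
        assert model.rG_ == pytest.approx(0.6, abs=0.05)

    def test_wrapper_with_ci(self):
        pairs = simulate_pairs(2500, BivariateACEParams(rG=0.84), seed=13)
        res = fit_extended_bivariate(pairs, ci=True, n_starts=1)
        lo, hi, level = res.cis["rG"]
        assert level == 0.95
        assert lo <= res.estimates["rG"] <= hi


class TestExtractChildPairs:
    @staticmethod
    def family_table():
        import pandas as pd

        return pd.DataFrame({
            "family_id": ["f1"] * 5,
            "nuclear_id": [1, 2, 1, 1, 2],
            "role": ["mother", "mother", "child", "child", "child"],
            "adult_rel": ["MZ"] * 5,
            "adhd_age5": [np.nan, np.nan, 1.0, 2.0, 3.0],
            "adhd_age8": [np.nan, np.nan, 4.0, 5.0, 6.0],
        })

    def test_enumerates_within_and_cross_unit_dyads(self):
        pairs = extract_child_pairs(self.family_table())
        assert len(pairs) == 3  # 1 within-unit + 2 cross-unit
        within = pairs[pairs.pair_rel == "FULL_SIB"]
        assert len(within) == 1 and within.iloc[0]["gamma_c"] == 1.0
        cross = pairs[pairs.pair_rel == "CROSS_MZ"]
        assert len(cross) == 2
        assert (cross["gamma_a"] == 0.25).all() and (cross["gamma_c"] == 0.0).all()

    def test_one_dyad_mode_keeps_single_pair_per_family(self):
        pairs = extract_child_pairs(self.family_table(), mode="one", seed=0)
        assert len(pairs) == 1

    def test_invalid_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            extract_child_pairs(self.family_table(), mode="some")
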