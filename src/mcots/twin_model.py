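"""Extended bivariate twin ACE model for pairs of related children.

Two traits per child (early ADHD at age 5 and one outcome at age 8) are
decomposed into additive-genetic (A), shared-environment (C) and non-shared
(E) components with a lower-triangular (Cholesky) path structure per
component.  The classical bivariate twin model is extended to sibling
(gamma_A = 0.5), half-sibling (0.25) and cousin (0.125) pairs, and the
shared-environment correlation is constrained to zero for cousins and
paternal half-siblings, who do not share a household.

The quantity of interest is the genetic correlation between the two traits,

    rG = a11*a21 / sqrt(a11^2 * (a21^2 + a22^2)),

derived from the A-component Cholesky paths.  Internally the model is
parameterised directly in ``(a11, sa2, rG)`` with ``a21 = rG*sa2`` and
``a22 = sqrt(1-rG^2)*sa2`` — an equivalent rotation that makes ``rG`` a
bounded free parameter, so profile intervals can terminate exactly at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import likelihood as lk
from .pedigree import ChildPairRelationship, child_pair_gammas

__all__ = [
    "CholeskyBivariateParams",
    "derived_genetic_correlation",
    "expected_pair_covariance",
    "pair_vectors",
    "extract_child_pairs",
    "ExtendedBivariateTwinModel",
    "fit_extended_bivariate",
]

PARAM_NAMES = ("a11", "sa2", "rG", "c11", "c21", "c22",
               "e11", "e21", "e22", "mu1", "mu2")

DEFAULT_BOUNDS = {
    "a11": (0.0, 2.0),
    "sa2": (0.0, 2.0),
    "rG": (-1.0, 1.0),
    "c11": (0.0, 2.0),
    "c21": (-2.0, 2.0),
    "c22": (0.0, 2.0),
    "e11": (1e-3, 2.0),
    "e21": (-2.0, 2.0),
    "e22": (1e-3, 2.0),
    "mu1": (-10.0, 10.0),
    "mu2": (-10.0, 10.0),
}

DEFAULT_START = {
    "a11": 0.7, "sa2": 0.7, "rG": 0.4,
    "c11": 0.3, "c21": 0.1, "c22": 0.3,
    "e11": 0.5, "e21": 0.1, "e22": 0.5,
    "mu1": 0.0, "mu2": 0.0,
}


@dataclass
class CholeskyBivariateParams:
    """Lower-triangular A/C/E paths of the bivariate model."""

    a11: float
    a21: float
    a22: float
    c11: float
    c21: float
    c22: float
    e11: float
    e21: float
    e22: float

    def component(self, which: str) -> np.ndarray:
        """2x2 covariance contributed by one component (A, C or E)."""
        x11, x21, x22 = {
            "A": (self.a11, self.a21, self.a22),
            "C": (self.c11, self.c21, self.c22),
            "E": (self.e11, self.e21, self.e22),
        }[which]
        L = np.array([[x11, 0.0], [x21, x22]])
        return L @ L.T

    def trait_variances(self) -> np.ndarray:
        return np.diag(self.component("A") + self.component("C") + self.component("E"))

    def standardized_shares(self) -> dict[str, float]:
        v = self.trait_variances()
        out = {}
        for which in "ACE":
            K = self.component(which)
            out[f"{which}1_share"] = K[0, 0] / v[0]
            out[f"{which}2_share"] = K[1, 1] / v[1]
        return out


def derived_genetic_correlation(params: CholeskyBivariateParams) -> float:
    """Genetic correlation implied by the A-component Cholesky paths."""
    va2 = params.a21**2 + params.a22**2
    if params.a11 == 0.0 or va2 == 0.0:
        raise ValueError(
            "genetic correlation undefined: zero genetic variance in a trait"
        )
    return params.a11 * params.a21 / (abs(params.a11) * math.sqrt(va2))


def _params_from_theta(theta: np.ndarray) -> CholeskyBivariateParams:
    a11, sa2, rG = theta[0], theta[1], theta[2]
    return CholeskyBivariateParams(
        a11=a11,
        a21=rG * sa2,
        a22=math.sqrt(max(0.0, 1.0 - rG**2)) * sa2,
        c11=theta[3], c21=theta[4], c22=theta[5],
        e11=theta[6], e21=theta[7], e22=theta[8],
    )


# configuration key: (gamma_A, gamma_C) of the pair
PairConfig = tuple[float, float]


def expected_pair_covariance(
    params: CholeskyBivariateParams,
    pair_rel: ChildPairRelationship | str | PairConfig,
) -> np.ndarray:
    """4x4 expected covariance of (trait1, trait2) x (child a, child b).

    Cross-person blocks scale the A block by the pair's genetic relatedness
    and the C block by its household indicator; E is never shared.
    ``pair_rel`` may be a relationship code or an explicit
    ``(gamma_A, gamma_C)`` pair (used for cross-unit dyads whose relatedness
    derives from the mothers' relationship).
    """
    if isinstance(pair_rel, tuple):
        gamma_a, gamma_c = pair_rel
    else:
        gamma_a, gamma_c = child_pair_gammas(ChildPairRelationship(pair_rel))
    A = params.component("A")
    C = params.component("C")
    E = params.component("E")
    within = A + C + E
    cross = gamma_a * A + gamma_c * C
    return np.block([[within, cross], [cross, within]])


def _cov_builder(theta: np.ndarray, config: PairConfig):
    params = _params_from_theta(theta)
    mu = np.array([theta[9], theta[10], theta[9], theta[10]])
    return mu, expected_pair_covariance(params, config)


PAIR_COLUMNS = ["pair_rel", "gamma_a", "gamma_c",
                "trait1_a", "trait2_a", "trait1_b", "trait2_b"]


def pair_vectors(df: pd.DataFrame) -> list[tuple[PairConfig, np.ndarray]]:
    """Extract (config, y) units from a wide pair table.

    The table needs ``gamma_a``/``gamma_c`` columns (or a ``pair_rel`` code
    column from which they are filled) and the four phenotype columns
    ``trait1_a, trait2_a, trait1_b, trait2_b``.
    """
    df = df.copy()
    if "gamma_a" not in df.columns or df["gamma_a"].isna().any():
        gam = df["pair_rel"].map(
            lambda r: child_pair_gammas(ChildPairRelationship(r))
        )
        df["gamma_a"] = [g[0] for g in gam]
        df["gamma_c"] = [g[1] for g in gam]
    ys = df[["trait1_a", "trait2_a", "trait1_b", "trait2_b"]].to_numpy(float)
    return [
        ((float(ga), float(gc)), y)
        for ga, gc, y in zip(df["gamma_a"], df["gamma_c"], ys)
    ]


def extract_child_pairs(
    df: pd.DataFrame,
    trait1: str = "adhd_age5",
    trait2: str = "adhd_age8",
    *,
    mode: str = "all",
    seed: int = 0,
) -> pd.DataFrame:
    """Enumerate child dyads from a long-format family table.

    Within-unit dyads are full siblings; cross-unit dyads get
    ``gamma_A = 0.25 * gamma_A(adult pair)`` and no shared household.
    ``mode='all'`` keeps every dyad (default, whole-sibship information);
    ``mode='one'`` keeps one random dyad per family to avoid unit reuse.
    """
    if mode not in ("all", "one"):
        raise ValueError(f"mode must be 'all' or 'one', got {mode!r}")
    rng = np.random.default_rng(seed)
    rows = []
    kids = df[df["role"] == "child"]
    for fid, grp in kids.groupby("family_id", sort=True):
        fam_rows = []
        recs = grp[["nuclear_id", trait1, trait2]].to_numpy(object)
        rel = str(grp["adult_rel"].iloc[0])
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                same_unit = recs[i][0] == recs[j][0]
                if same_unit:
                    ga, gc = child_pair_gammas(ChildPairRelationship.FULL_SIB)
                    code = "FULL_SIB"
                else:
                    ga, gc = child_pair_gammas(rel, cross_unit=True)
                    code = f"CROSS_{rel}"
                fam_rows.append(
                    {
                        "family_id": fid,
                        "pair_rel": code,
                        "gamma_a": ga,
                        "gamma_c": gc,
                        "trait1_a": recs[i][1],
                        "trait2_a": recs[i][2],
                        "trait1_b": recs[j][1],
                        "trait2_b": recs[j][2],
                    }
                )
        if fam_rows:
            if mode == "one":
                fam_rows = [fam_rows[rng.integers(len(fam_rows))]]
            rows.extend(fam_rows)
    return pd.DataFrame(rows)


class ExtendedBivariateTwinModel(BaseEstimator):
    """FIML estimator of the extended bivariate twin model on pair tables.

    Fit-only scikit-learn-style estimator; fitted attributes are
    ``params_`` (Cholesky paths), ``rG_`` (derived genetic correlation) and
    ``result_``.  Identification requires at least two relationship groups
    with different genetic relatedness (e.g. full siblings and cousins).
    """

    def __init__(
        self,
        *,
        n_starts: int = 5,
        random_state: int = 0,
        fixed: dict[str, float] | None = None,
    ) -> None:
        self.n_starts = n_starts
        self.random_state = random_state
        self.fixed = fixed

    def _prepare(self, X: pd.DataFrame):
        units = pair_vectors(X)
        gammas = {cfg[0] for cfg, _ in units}
        if len(gammas) < 2:
            raise ValueError(
                "extended twin identification requires >=2 relationship groups "
                f"with different genetic relatedness; found gamma_A = {sorted(gammas)}"
            )
        return lk.group_observations(units)

    def fit(self, X: pd.DataFrame, y=None) -> "ExtendedBivariateTwinModel":
        groups, n_units, n_obs = self._prepare(X)
        bounds = [DEFAULT_BOUNDS[p] for p in PARAM_NAMES]
        start = [DEFAULT_START[p] for p in PARAM_NAMES]
        res = lk.fit_fiml(
            groups,
            _cov_builder,
            PARAM_NAMES,
            start,
            bounds,
            fixed=self.fixed,
            n_starts=self.n_starts,
            seed=self.random_state,
            model_name="ExtendedBivariateTwin",
            n_units=n_units,
            n_obs=n_obs,
        )
        self.result_ = res
        self.params_ = _params_from_theta(
            np.array([res.estimates[p] for p in PARAM_NAMES])
        )
        self.rG_ = float(res.estimates["rG"])
        self.rG_identified_ = (
            res.estimates["a11"] > 1e-3 and res.estimates["sa2"] > 1e-3
        )
        self.neg2ll_ = res.neg2ll
        self.n_pairs_ = n_units
        self._groups = groups
        self._bounds = bounds
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        groups, n_units, _ = self._prepare(X)
        theta = np.array([self.result_.estimates[p] for p in PARAM_NAMES])
        return -0.5 * lk.fiml_neg2ll(theta, groups, _cov_builder) / n_units

    def profile_ci(self, param: str = "rG", level: float = 0.95) -> tuple[float, float]:
        return lk.profile_ci(
            self._groups, _cov_builder, PARAM_NAMES, self._bounds,
            self.result_, param, level,
        )

    def reductions(self) -> list[lk.ModelComparison]:
        """LRTs dropping the cross-trait genetic correlation and the C paths."""
        full = self.result_
        out = []
        for label, fx in [
            ("drop rG", {"rG": 0.0}),
            ("drop C", {"c11": 0.0, "c21": 0.0, "c22": 0.0}),
        ]:
            start = [full.estimates[p] for p in PARAM_NAMES]
            red = lk.fit_fiml(
                self._groups, _cov_builder, PARAM_NAMES, start, self._bounds,
                fixed={**(self.fixed or {}), **fx},
                n_starts=1, seed=self.random_state,
                model_name=f"{full.model} [{label}]",
                n_units=full.n_units, n_obs=full.n_obs,
            )
            out.append(lk.lrt(full, red, label=label))
        return out


def fit_extended_bivariate(
    pairs: pd.DataFrame, *, ci: bool = False, **kwargs
) -> lk.FitResult:
    """Fit the extended bivariate twin model to a pair table."""
    model = ExtendedBivariateTwinModel(**kwargs).fit(pairs)
    if ci:
        model.profile_ci("rG")
    return model.result_
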