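"""Multiple-Children-of-Twins-and-Siblings (MCoTS) structural model.

The model relates one adult trait measured in a pair of related mothers to
one child trait measured in their children.  Its power comes from the
contrast between mother-child and aunt-child (avuncular) correlations:
children of identical twins share as many genes with their aunt as with
their own mother but share a rearing household only with the mother, so an
excess of the mother-child over the avuncular correlation indicates direct
phenotypic transmission rather than shared genes.

Parameters
----------
The adult trait follows an ACE decomposition with paths ``a1, c1, e1``; the
child trait has paths ``a2, c2, e2``.  ``rA`` is the correlation between
the additive-genetic influences on the adult trait and those on the child
trait (the intergenerational genetic correlation reported as r_G), and
``m`` is the direct phenotypic-transmission path from the mother's observed
phenotype to each of her children's phenotypes.

Expected covariance
-------------------
With ``v1 = a1^2 + c1^2 + e1^2`` (adult phenotypic variance), adult-pair
genetic correlation ``gamma`` and household indicator ``kappa``:

* adult-adult:            ``gamma*a1^2 + kappa*c1^2``
* mother-own child:       ``0.5*rA*a1*a2 + m*v1``
* aunt-child:             ``0.5*gamma*rA*a1*a2 + m*(gamma*a1^2 + kappa*c1^2)``
* child-child, same unit: ``0.5*a2^2 + c2^2 + 2*m*(0.5*rA*a1*a2) + m^2*v1``
* child-child, cross unit:``0.25*gamma*a2^2 + 2*m*(0.5*gamma*rA*a1*a2)
  + m^2*(gamma*a1^2 + kappa*c1^2)`` (no shared household across units)
* child variance:         ``a2^2 + c2^2 + e2^2 + 2*m*(0.5*rA*a1*a2) + m^2*v1``

These closed forms are locked against the simulation oracle in the test
suite for every supported family configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import likelihood as lk
from .pedigree import (
    ADULT_GAMMA_A,
    ADULT_GAMMA_C,
    AdultPairRelationship,
    KinshipSpec,
)

__all__ = [
    "MCoTSParams",
    "expected_covariance",
    "family_vectors",
    "MCoTSModel",
    "fit_mcots",
    "mcots_model_reductions",
]

PARAM_NAMES = ("a1", "c1", "e1", "a2", "c2", "e2", "rA", "m", "mu_m", "mu_c")

DEFAULT_BOUNDS = {
    "a1": (0.0, 2.0),
    "c1": (0.0, 2.0),
    "e1": (1e-3, 2.0),
    "a2": (0.0, 2.0),
    "c2": (0.0, 2.0),
    "e2": (1e-3, 2.0),
    "rA": (-1.0, 1.0),
    "m": (-1.0, 1.0),
    "mu_m": (-10.0, 10.0),
    "mu_c": (-10.0, 10.0),
}

DEFAULT_START = {
    "a1": 0.55,
    "c1": 0.25,
    "e1": 0.75,
    "a2": 0.7,
    "c2": 0.3,
    "e2": 0.55,
    "rA": 0.3,
    "m": 0.05,
    "mu_m": 0.0,
    "mu_c": 0.0,
}


@dataclass
class MCoTSParams:
    """Path coefficients of the MCoTS model (see module docstring)."""

    a1: float
    c1: float
    e1: float
    a2: float
    c2: float
    e2: float
    rA: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rA <= 1.0:
            raise ValueError(f"rA={self.rA} outside [-1, 1]")

    @property
    def adult_variance(self) -> float:
        return self.a1**2 + self.c1**2 + self.e1**2

    @property
    def child_variance(self) -> float:
        """Child phenotypic variance including the transmission channel."""
        return (
            self.a2**2
            + self.c2**2
            + self.e2**2
            + 2.0 * self.m * (0.5 * self.rA * self.a1 * self.a2)
            + self.m**2 * self.adult_variance
        )

    def standardized(self) -> dict[str, float]:
        """Standardised variance shares and paths for both traits."""
        v1, v2 = self.adult_variance, self.child_variance
        return {
            "A1_share": self.a1**2 / v1,
            "C1_share": self.c1**2 / v1,
            "E1_share": self.e1**2 / v1,
            "A2_share": self.a2**2 / v2,
            "C2_share": self.c2**2 / v2,
            "E2_share": self.e2**2 / v2,
            "rA": self.rA,
            "m_std": float(self.m * np.sqrt(v1 / v2)),
        }

    def to_theta(self, mu_m: float = 0.0, mu_c: float = 0.0) -> np.ndarray:
        return np.array(
            [self.a1, self.c1, self.e1, self.a2, self.c2, self.e2, self.rA,
             self.m, mu_m, mu_c]
        )

    @classmethod
    def from_estimates(cls, est: dict[str, float]) -> "MCoTSParams":
        return cls(**{k: est[k] for k in
                      ("a1", "c1", "e1", "a2", "c2", "e2", "rA", "m")})


# configuration key: (adult_rel value, children in unit 1, children in unit 2)
FamilyConfig = tuple[str, int, int]


@lru_cache(maxsize=256)
def _structures(config: FamilyConfig, c2_cross_share: float = 0.0):
    """Pre-compute theta-independent structure matrices for one configuration."""
    rel, n1, n2 = config
    rel = AdultPairRelationship(rel)
    gamma = ADULT_GAMMA_A[rel]
    kappa = ADULT_GAMMA_C[rel]
    n_m = 1 if rel is AdultPairRelationship.SINGLETON else 2
    n_c = n1 + n2
    unit_of_child = np.array([0] * n1 + [1] * n2)

    B = np.zeros((n_c, n_m))  # own-mother selector
    for i, u in enumerate(unit_of_child):
        B[i, min(u, n_m - 1)] = 1.0
    Aunt = np.zeros((n_c, n_m))
    if n_m == 2:
        for i, u in enumerate(unit_of_child):
            Aunt[i, 1 - u] = 1.0

    same_unit = (unit_of_child[:, None] == unit_of_child[None, :]).astype(float)
    off = same_unit - np.eye(n_c)
    cross = 1.0 - same_unit
    R_A_cc = np.eye(n_c) + 0.5 * off + 0.25 * gamma * cross
    R_C_cc = np.eye(n_c) + off + c2_cross_share * cross
    return gamma, kappa, n_m, n_c, B, Aunt, R_A_cc, cross


def expected_covariance(
    params: MCoTSParams,
    config: FamilyConfig | tuple[AdultPairRelationship, int, int],
    spec: KinshipSpec | None = None,
) -> np.ndarray:
    """Expected phenotypic covariance for one family configuration.

    Member order is mothers first, then children grouped by mother,
    matching :class:`~mcots.pedigree.ExtendedFamily`.
    """
    rel, n1, n2 = config
    rel = AdultPairRelationship(rel)
    if rel is AdultPairRelationship.SINGLETON and n2:
        raise ValueError("SINGLETON families have one nuclear unit")
    c2x = spec.c2_cross_share if spec is not None else 0.0
    gamma, kappa, n_m, n_c, B, Aunt, R_A_cc, cross = _structures(
        (rel.value, n1, n2), c2x
    )
    a1, c1, e1 = params.a1, params.c1, params.e1
    a2, c2, e2 = params.a2, params.c2, params.e2
    rA, m = params.rA, params.m

    v1 = a1**2 + c1**2 + e1**2
    s = gamma * a1**2 + kappa * c1**2
    sigma_mm = np.full((n_m, n_m), s)
    np.fill_diagonal(sigma_mm, v1)

    if n_c == 0:
        return sigma_mm

    # Cov(latent child part, adult phenotypes): child x mother
    G_cm = 0.5 * rA * a1 * a2 * (B + gamma * Aunt)
    sigma_cm = G_cm + m * (B @ sigma_mm)

    R_C_cc = np.eye(n_c) + (1.0 - cross - np.eye(n_c)) + c2x * cross
    sigma_L_cc = a2**2 * R_A_cc + c2**2 * R_C_cc + e2**2 * np.eye(n_c)
    X = m * (G_cm @ B.T)
    sigma_cc = sigma_L_cc + X + X.T + m**2 * (B @ sigma_mm @ B.T)

    n = n_m + n_c
    out = np.empty((n, n))
    out[:n_m, :n_m] = sigma_mm
    out[n_m:, :n_m] = sigma_cm
    out[:n_m, n_m:] = sigma_cm.T
    out[n_m:, n_m:] = sigma_cc
    return out


def _mean_vector(theta: np.ndarray, config: FamilyConfig) -> np.ndarray:
    rel, n1, n2 = config
    n_m = 1 if rel == "SINGLETON" else 2
    return np.concatenate(
        [np.full(n_m, theta[8]), np.full(n1 + n2, theta[9])]
    )


def _cov_builder_factory(c2_cross_share: float = 0.0):
    """Fast assembly of (mean, covariance) from a raw parameter vector."""

    def builder(theta: np.ndarray, config: FamilyConfig):
        gamma, kappa, n_m, n_c, B, Aunt, R_A_cc, cross = _structures(
            config, c2_cross_share
        )
        a1, c1, e1, a2, c2, e2, rA, m, mu_m, mu_c = theta
        v1 = a1 * a1 + c1 * c1 + e1 * e1
        s = gamma * a1 * a1 + kappa * c1 * c1
        sigma_mm = np.full((n_m, n_m), s)
        np.fill_diagonal(sigma_mm, v1)
        mu = np.empty(n_m + n_c)
        mu[:n_m] = mu_m
        mu[n_m:] = mu_c
        if n_c == 0:
            return mu, sigma_mm
        G_cm = (0.5 * rA * a1 * a2) * (B + gamma * Aunt)
        sigma_cm = G_cm + m * (B @ sigma_mm)
        eye_c = np.eye(n_c)
        R_C_cc = 1.0 - cross + c2_cross_share * cross
        sigma_L_cc = a2 * a2 * R_A_cc + c2 * c2 * R_C_cc + e2 * e2 * eye_c
        X = m * (G_cm @ B.T)
        sigma_cc = sigma_L_cc + X + X.T + (m * m) * (B @ sigma_mm @ B.T)
        n = n_m + n_c
        out = np.empty((n, n))
        out[:n_m, :n_m] = sigma_mm
        out[n_m:, :n_m] = sigma_cm
        out[:n_m, n_m:] = sigma_cm.T
        out[n_m:, n_m:] = sigma_cc
        return mu, out

    return builder


def family_vectors(
    df: pd.DataFrame,
    maternal_col: str,
    child_col: str,
    max_children_per_mother: int = 4,
    *,
    canonical_child_order: bool = True,
) -> list[tuple[FamilyConfig, np.ndarray]]:
    """Extract (configuration, phenotype vector) per family from a long table.

    The vector is ordered mothers (unit 1, unit 2) then children grouped by
    unit; unobserved phenotypes become NaN.  Mothers with more than the cap
    of children keep the first ``max_children_per_mother`` rows in table
    order (the generator never exceeds the cap).

    With ``canonical_child_order`` (default), children within a unit are
    sorted by value, missing last.  Children of one mother are exchangeable
    under the model — the expected covariance is symmetric in their
    coordinates — so the likelihood is unchanged while becoming exactly
    invariant to the input row order.  Disable this when comparing raw
    slot-wise sample moments (sorted coordinates are order statistics).
    """
    need = {"family_id", "nuclear_id", "role", "adult_rel", maternal_col, child_col}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    cols = df[["family_id", "nuclear_id", "role", "adult_rel",
               maternal_col, child_col]].copy()
    cols["nuclear_id"] = cols["nuclear_id"].astype(int)

    mothers = cols[cols["role"] == "mother"]
    mom_wide = mothers.pivot_table(
        index="family_id", columns="nuclear_id", values=maternal_col,
        aggfunc="first", dropna=False,
    ).reindex(columns=[1, 2])
    rel_by_fam = cols.groupby("family_id", sort=True)["adult_rel"].first()

    kids = cols[cols["role"] != "mother"].copy()
    kids["slot"] = kids.groupby(["family_id", "nuclear_id"]).cumcount()
    kids = kids[kids["slot"] < max_children_per_mother]
    if len(kids):
        kid_wide = kids.pivot_table(
            index="family_id", columns=["nuclear_id", "slot"],
            values=child_col, aggfunc="first", dropna=False,
        )
        counts = (
            kids.groupby(["family_id", "nuclear_id"]).size().unstack(fill_value=0)
        ).reindex(columns=[1, 2], fill_value=0)
    else:
        kid_wide = pd.DataFrame(index=mom_wide.index)
        counts = pd.DataFrame(0, index=mom_wide.index, columns=[1, 2])

    fam_index = rel_by_fam.index
    mom_wide = mom_wide.reindex(fam_index)
    counts = counts.reindex(fam_index, fill_value=0)
    kid_wide = kid_wide.reindex(fam_index)

    rels = rel_by_fam.to_numpy(object)
    n1 = counts[1].to_numpy(int)
    n2 = counts[2].to_numpy(int)
    out: list[tuple[FamilyConfig, np.ndarray]] = []
    for rel, k1, k2 in sorted(set(zip(rels, n1, n2))):
        sel = (rels == rel) & (n1 == k1) & (n2 == k2)
        n_m = 1 if rel == "SINGLETON" else 2
        parts = [mom_wide.loc[sel].to_numpy(float)[:, :n_m]]
        for unit, k in ((1, k1), (2, k2)):
            for s in range(k):
                col = (unit, s)
                if col in kid_wide.columns:
                    parts.append(kid_wide.loc[sel, [col]].to_numpy(float))
                else:  # pragma: no cover
                    parts.append(np.full((sel.sum(), 1), np.nan))
        Y = np.hstack(parts)
        if canonical_child_order:
            if k1 > 1:
                Y[:, n_m:n_m + k1] = np.sort(Y[:, n_m:n_m + k1], axis=1)
            if k2 > 1:
                Y[:, n_m + k1:] = np.sort(Y[:, n_m + k1:], axis=1)
        config: FamilyConfig = (str(rel), int(k1), int(k2))
        out.extend((config, y) for y in Y)
    return out


class MCoTSModel(BaseEstimator):
    """FIML estimator of the MCoTS model on a long-format family table.

    Follows the scikit-learn estimator protocol (``get_params`` /
    ``set_params``; fitted attributes carry a trailing underscore) but, like
    a covariance estimator, is fit-only: ``fit(X)`` estimates the path
    coefficients from the family blocks in ``X`` and ``score(X)`` returns
    the mean log-likelihood per family.

    Parameters
    ----------
    maternal_col, child_col : str
        Phenotype columns of the adult and child trait.
    n_starts : int
        Jittered optimizer starts (the first start is deterministic).
    random_state : int
        Seed for the start jitter.
    c2_cross_share : float
        Fraction of the child shared environment correlated across nuclear
        units (sensitivity option; 0 = cousins share no household).
    fixed : dict or None
        Parameters pinned during fitting, e.g. ``{"m": 0.0}``.
    """

    def __init__(
        self,
        maternal_col: str = "adhd_adult",
        child_col: str = "adhd_age8",
        *,
        n_starts: int = 5,
        random_state: int = 0,
        max_children_per_mother: int = 4,
        c2_cross_share: float = 0.0,
        fixed: dict[str, float] | None = None,
    ) -> None:
        self.maternal_col = maternal_col
        self.child_col = child_col
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_children_per_mother = max_children_per_mother
        self.c2_cross_share = c2_cross_share
        self.fixed = fixed

    # -- internals ---------------------------------------------------------
    def _prepare(self, X: pd.DataFrame):
        units = family_vectors(
            X, self.maternal_col, self.child_col, self.max_children_per_mother
        )
        rels = {cfg[0] for cfg, _ in units if cfg[0] != "SINGLETON"}
        if len(rels) < 2:
            raise ValueError(
                "MCoTS identification requires at least two adult relationship "
                f"groups with different relatedness; found {sorted(rels)}"
            )
        groups, n_units, n_obs = lk.group_observations(units)
        return groups, n_units, n_obs

    def _bounds_start(self):
        bounds = [DEFAULT_BOUNDS[p] for p in PARAM_NAMES]
        start = [DEFAULT_START[p] for p in PARAM_NAMES]
        return bounds, start

    # -- sklearn-style API -------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "MCoTSModel":
        groups, n_units, n_obs = self._prepare(X)
        builder = _cov_builder_factory(self.c2_cross_share)
        bounds, start = self._bounds_start()
        res = lk.fit_fiml(
            groups,
            builder,
            PARAM_NAMES,
            start,
            bounds,
            fixed=self.fixed,
            n_starts=self.n_starts,
            seed=self.random_state,
            model_name=f"MCoTS({self.maternal_col}~{self.child_col})",
            n_units=n_units,
            n_obs=n_obs,
        )
        self.result_ = res
        self.params_ = MCoTSParams.from_estimates(res.estimates)
        self.neg2ll_ = res.neg2ll
        self.n_families_ = n_units
        self._groups = groups
        self._builder = builder
        self._bounds = bounds
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per family under the fitted parameters."""
        groups, n_units, _ = self._prepare(X)
        theta = np.array([self.result_.estimates[p] for p in PARAM_NAMES])
        return -0.5 * lk.fiml_neg2ll(theta, groups, self._builder) / n_units

    def profile_ci(self, param: str = "rA", level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood CI for one parameter (stored on ``result_``)."""
        return lk.profile_ci(
            self._groups, self._builder, PARAM_NAMES, self._bounds,
            self.result_, param, level,
        )

    def reductions(self) -> list[lk.ModelComparison]:
        """Likelihood-ratio tests of the standard nested reductions.

        Drops, in turn: the intergenerational genetic correlation ``rA``;
        the phenotypic-transmission path ``m``; both; and the adult shared
        environment ``c1``.
        """
        full = self.result_
        out = []
        for label, fx in [
            ("drop rA", {"rA": 0.0}),
            ("drop m", {"m": 0.0}),
            ("drop rA and m", {"rA": 0.0, "m": 0.0}),
            ("drop adult C", {"c1": 0.0}),
        ]:
            bounds, _ = self._bounds_start()
            start = [full.estimates[p] for p in PARAM_NAMES]
            red = lk.fit_fiml(
                self._groups,
                self._builder,
                PARAM_NAMES,
                start,
                bounds,
                fixed={**(self.fixed or {}), **fx},
                n_starts=1,
                seed=self.random_state,
                model_name=f"{full.model} [{label}]",
                n_units=full.n_units,
                n_obs=full.n_obs,
            )
            out.append(lk.lrt(full, red, label=label))
        return out

    def genetic_share_of_covariance(self) -> float:
        """Share of the mother-child phenotypic covariance carried by genes."""
        p = self.params_
        total = 0.5 * p.rA * p.a1 * p.a2 + p.m * p.adult_variance
        if abs(total) < 1e-12:
            raise ValueError("mother-child covariance is zero")
        return (0.5 * p.rA * p.a1 * p.a2) / total


def fit_mcots(
    df: pd.DataFrame,
    maternal_col: str = "adhd_adult",
    child_col: str = "adhd_age8",
    *,
    ci: bool = False,
    **kwargs,
) -> lk.FitResult:
    """Fit the MCoTS model to a family table; thin wrapper over the estimator."""
    model = MCoTSModel(maternal_col, child_col, **kwargs).fit(df)
    if ci:
        model.profile_ci("rA")
    return model.result_


def mcots_model_reductions(
    df: pd.DataFrame,
    maternal_col: str = "adhd_adult",
    child_col: str = "adhd_age8",
    **kwargs,
) -> list[lk.ModelComparison]:
    return MCoTSModel(maternal_col, child_col, **kwargs).fit(df).reductions()
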