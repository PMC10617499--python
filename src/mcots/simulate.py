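"""Synthetic extended-family cohort generator.

Generates long-format family phenotype tables under exactly the generative
assumptions the MCoTS and extended twin models make, so parameter recovery
can be tested without access to the registry cohort the design targets.

The cohort emulated by :func:`emulate_study_defaults` mirrors a national
birth-registry linkage: ~25,470 mothers in twin/sibling/half-sibling/cousin
pairs, ~1.2 children per mother (51% male), maternal age at birth drawn
from a truncated normal (mean 29.97 y, s.d. 4.21, bounds 17-45).

Genetic transmission is simulated mechanistically, not by sampling from the
models' implied covariance: each mother carries standard-normal genetic
scores for the adult trait and (via a correlation ``rA``) for each child
trait; each child receives half of its mother's score, half of an
independent founder father's score, and a Mendelian segregation deviate of
variance one half.  Shared environments are drawn per household.  This
independent route is what makes the closed-form expected covariances
testable against simulation moments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .pedigree import (
    ADULT_GAMMA_A,
    ADULT_GAMMA_C,
    SCHEMA_COLUMNS,
    AdultPairRelationship,
    ChildPairRelationship,
    child_pair_gammas,
)
from .preprocessing import SCALES, ScaleDefinition

__all__ = [
    "CohortConfig",
    "OutcomeParams",
    "GenerativeParams",
    "BivariateACEParams",
    "simulate_cohort",
    "simulate_pairs",
    "simulate_item_responses",
    "emulate_study_defaults",
    "recovery_config",
    "save_config",
    "load_config",
]

CHILD_MEASURES = [
    "adhd_age5",
    "adhd_age8",
    "odd_age8",
    "conduct_age8",
    "anxiety_age8",
    "depression_age8",
]

#: point estimates of the adult-child genetic correlation per outcome,
#: used as generating defaults
DEFAULT_RA = {
    "adhd_age5": 0.55,  # synthetic: no printed adult<->age-5 estimate
    "adhd_age8": 0.55,
    "odd_age8": 0.80,
    "conduct_age8": 0.44,
    "anxiety_age8": 0.72,
    "depression_age8": 1.0,
}

#: child-child genetic correlations (age-5 ADHD vs each age-8 outcome)
DEFAULT_RG = {
    "adhd_age8": 0.84,
    "odd_age8": 0.70,
    "depression_age8": 0.64,
    "conduct_age8": 0.43,
    "anxiety_age8": 0.41,
}


def _check_probs(probs: dict, what: str) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError(f"{what}: probabilities must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-8:
        raise ValueError(f"{what}: probabilities sum to {vals.sum()}, not 1")


@dataclass
class CohortConfig:
    """Shape of the simulated cohort (sizes, demographics, missingness)."""

    n_families: int = 1000
    rel_mix: dict[str, float] = field(
        default_factory=lambda: {
            "MZ": 0.03, "DZ": 0.04, "FULL_SIB": 0.55,
            "MAT_HALF_SIB": 0.07, "PAT_HALF_SIB": 0.04, "COUSIN": 0.27,
        }
    )
    children_per_mother: dict[int, float] = field(
        default_factory=lambda: {0: 0.10, 1: 0.62, 2: 0.24, 3: 0.04}
    )
    maternal_age: tuple[float, float, float, float] = (29.97, 4.21, 17.0, 45.0)
    parity_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.45, 1: 0.35, 2: 0.15, 3: 0.05}
    )
    birth_year_range: tuple[int, int] = (1999, 2008)
    child_sex_male_prob: float = 0.51
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        _check_probs(self.rel_mix, "rel_mix")
        _check_probs(self.children_per_mother, "children_per_mother")
        _check_probs(self.parity_probs, "parity_probs")
        mean, sd, lo, hi = self.maternal_age
        if not lo < hi:
            raise ValueError("maternal_age bounds must be ordered")
        if not 0.0 <= self.child_sex_male_prob <= 1.0:
            raise ValueError("child_sex_male_prob outside [0, 1]")
        if max(self.children_per_mother) > 4:
            raise ValueError("children_per_mother supports at most 4 per mother")
        for k, v in self.missingness.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missingness[{k!r}] outside [0, 1]")


@dataclass
class OutcomeParams:
    """Child-trait ACE paths plus its two links to the maternal trait."""

    a2: float
    c2: float
    e2: float
    rA: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rA <= 1.0:
            raise ValueError(f"rA={self.rA} outside [-1, 1]")


@dataclass
class GenerativeParams:
    """True parameter values the cohort is generated under."""

    a1: float = np.sqrt(0.35)
    c1: float = np.sqrt(0.05)
    e1: float = np.sqrt(0.60)
    outcomes: dict[str, OutcomeParams] = field(
        default_factory=lambda: {
            name: OutcomeParams(
                a2=np.sqrt(0.6), c2=np.sqrt(0.1), e2=np.sqrt(0.3),
                rA=DEFAULT_RA[name], m=0.1,
            )
            for name in CHILD_MEASURES
        }
    )
    beta_age: float = 0.05
    beta_parity: float = 0.05
    beta_birth_year: float = 0.02
    beta_sex: float = 0.10

    def __post_init__(self) -> None:
        tot = self.a1**2 + self.c1**2 + self.e1**2
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(
                f"adult paths must be standardised (a1^2+c1^2+e1^2 = {tot:.4f})"
            )


def emulate_study_defaults() -> tuple[CohortConfig, GenerativeParams]:
    """Configuration emulating the analytic sample's shape.

    12,735 mother pairs give 25,470 mothers (the analytic sample has
    25,469) with ~1.2 children each; 20% per-measure missingness stands in
    for cohort attrition.  Group sizes per relatedness stratum are
    synthetic defaults: full-sibling mothers dominate, twins are rare.
    """
    cfg = CohortConfig(
        n_families=12_735,
        missingness={m: 0.2 for m in CHILD_MEASURES + ["adhd_adult"]},
    )
    return cfg, GenerativeParams()


def recovery_config(
    n_families: int = 5000, seed: int = 0, missingness: float = 0.0
) -> CohortConfig:
    """Cohort shape used by the parameter-recovery studies.

    A relationship mixture rich in informative contrasts (twins through
    cousins) with 1-2 children per mother and, by default, complete data.
    """
    return CohortConfig(
        n_families=n_families,
        rel_mix={
            "MZ": 0.2, "DZ": 0.2, "FULL_SIB": 0.2,
            "MAT_HALF_SIB": 0.1, "PAT_HALF_SIB": 0.1, "COUSIN": 0.2,
        },
        children_per_mother={1: 0.5, 2: 0.5},
        missingness=(
            {m: missingness for m in CHILD_MEASURES + ["adhd_adult"]}
            if missingness else {}
        ),
        seed=seed,
    )


def _draw_counts(rng, probs: dict[int, float], n: int) -> np.ndarray:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys])
    return np.asarray(keys)[rng.choice(len(keys), size=n, p=p)]


def simulate_cohort(
    config: CohortConfig,
    params: GenerativeParams | None = None,
    *,
    outcomes: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a long-format family table (pedigree schema).

    Fixed ``config.seed`` makes the output bit-reproducible: families are
    assigned to configurations first, then each (relationship x child
    count) batch is generated in sorted order from a single generator
    stream, so stream order is part of the contract.
    """
    params = params or GenerativeParams()
    outcomes = list(outcomes or params.outcomes)
    for name in outcomes:
        if name not in params.outcomes:
            raise ValueError(f"no generative parameters for outcome {name!r}")
    rng = np.random.default_rng(config.seed)

    rel_keys = sorted(config.rel_mix)
    rel_p = np.array([config.rel_mix[k] for k in rel_keys])
    rel_draw = rng.choice(len(rel_keys), size=config.n_families, p=rel_p)
    fam_rel = np.array([rel_keys[i] for i in rel_draw])
    n1 = _draw_counts(rng, config.children_per_mother, config.n_families)
    n2 = np.where(
        fam_rel == "SINGLETON",
        0,
        _draw_counts(rng, config.children_per_mother, config.n_families),
    )

    mean, sd, lo, hi = config.maternal_age
    a_, b_ = (lo - mean) / sd, (hi - mean) / sd
    y0, y1 = config.birth_year_range
    parity_mean = sum(k * v for k, v in config.parity_probs.items())
    parity_var = sum(
        (k - parity_mean) ** 2 * v for k, v in config.parity_probs.items()
    )
    by_mean, by_sd = (y0 + y1) / 2.0, max((y1 - y0) / np.sqrt(12.0), 1e-9)
    p_male = config.child_sex_male_prob

    frames: list[pd.DataFrame] = []
    fam_ids = np.arange(config.n_families)
    configs = sorted(set(zip(fam_rel, n1, n2)))
    for rel, k1, k2 in configs:
        sel = (fam_rel == rel) & (n1 == k1) & (n2 == k2)
        nb = int(sel.sum())
        if nb == 0:
            continue
        frames.append(
            _simulate_batch(
                rng, fam_ids[sel], str(rel), int(k1), int(k2), nb,
                config, params, outcomes,
                (mean, sd, a_, b_), (parity_mean, parity_var), (by_mean, by_sd),
                p_male,
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(
        ["family_id", "nuclear_id", "role", "person_id"],
        ascending=[True, True, False, True],
        ignore_index=True,
        kind="stable",
    )

    # missing at random, independent of every phenotype value by construction
    for col, p_miss in config.missingness.items():
        if col not in df.columns or p_miss <= 0:
            continue
        present = df[col].notna().to_numpy()
        drop = rng.random(len(df)) < p_miss
        df.loc[present & drop, col] = np.nan
    return df[SCHEMA_COLUMNS]


def _simulate_batch(
    rng, fam_ids, rel, k1, k2, nb, config, params, outcomes,
    age_pars, parity_pars, by_pars, p_male,
):
    gamma = ADULT_GAMMA_A[AdultPairRelationship(rel)]
    kappa = ADULT_GAMMA_C[AdultPairRelationship(rel)]
    n_m = 1 if rel == "SINGLETON" else 2
    a1, c1, e1 = params.a1, params.c1, params.e1
    comp = np.sqrt(max(0.0, 1.0 - gamma**2))

    # maternal genetic score for the adult trait
    g1 = np.empty((nb, n_m))
    g1[:, 0] = rng.standard_normal(nb)
    if n_m == 2:
        g1[:, 1] = gamma * g1[:, 0] + comp * rng.standard_normal(nb)
    # adult shared and unique environment
    cc = np.empty((nb, n_m))
    cc[:, 0] = rng.standard_normal(nb)
    if n_m == 2:
        cc[:, 1] = cc[:, 0] if kappa == 1.0 else rng.standard_normal(nb)
    ee = rng.standard_normal((nb, n_m))
    y_m = a1 * g1 + c1 * cc + e1 * ee

    # demographics
    mean, sd, a_, b_ = age_pars
    parity_mean, parity_var = parity_pars
    by_mean, by_sd = by_pars
    ages = truncnorm.rvs(a_, b_, loc=mean, scale=sd, size=(nb, n_m), random_state=rng)
    parity = _draw_counts(rng, config.parity_probs, nb * n_m).reshape(nb, n_m)
    y0, y1 = config.birth_year_range
    m_by = rng.integers(y0, y1 + 1, size=(nb, n_m))

    z_age = (ages - mean) / sd
    z_par = (parity - parity_mean) / np.sqrt(max(parity_var, 1e-9))
    z_by = (m_by - by_mean) / by_sd
    y_m_obs = (
        y_m
        + params.beta_age * z_age
        + params.beta_parity * z_par
        + params.beta_birth_year * z_by
    )

    counts = [k1, k2][:n_m]
    n_c = sum(counts)
    unit_of_child = np.concatenate(
        [np.full(k, u) for u, k in enumerate(counts)]
    ).astype(int) if n_c else np.empty(0, dtype=int)

    kid_vals: dict[str, np.ndarray] = {}
    if n_c:
        sexes = (rng.random((nb, n_c)) < p_male).astype(int)
        c_by = rng.integers(y0, y1 + 1, size=(nb, n_c))
        z_sex = (sexes - p_male) / np.sqrt(p_male * (1 - p_male))
        z_cby = (c_by - by_mean) / by_sd
        for name in outcomes:
            op = params.outcomes[name]
            rA, m_t = op.rA, op.m
            comp_ra = np.sqrt(max(0.0, 1.0 - rA**2))
            # maternal genetic score for the child trait: rA-correlated with g1
            w = np.empty((nb, n_m))
            w[:, 0] = rng.standard_normal(nb)
            if n_m == 2:
                w[:, 1] = gamma * w[:, 0] + comp * rng.standard_normal(nb)
            g2_m = rA * g1 + comp_ra * w
            # one independent founder father per nuclear unit
            g2_f = rng.standard_normal((nb, n_m))
            c2_unit = rng.standard_normal((nb, n_m))
            seg = rng.standard_normal((nb, n_c)) * np.sqrt(0.5)
            e2 = rng.standard_normal((nb, n_c))
            u = unit_of_child
            a2_child = 0.5 * g2_m[:, u] + 0.5 * g2_f[:, u] + seg
            y_c = (
                op.a2 * a2_child
                + op.c2 * c2_unit[:, u]
                + op.e2 * e2
                + m_t * y_m[:, u]
            )
            kid_vals[name] = (
                y_c
                + params.beta_age * z_age[:, u]
                + params.beta_parity * z_par[:, u]
                + params.beta_birth_year * z_cby
                + params.beta_sex * z_sex
            )

    fid = np.char.add("F", np.char.zfill(fam_ids.astype("U"), 6))

    # mothers block: nb * n_m rows (family-major order)
    fid_m = np.repeat(fid, n_m)
    unit_m = np.tile(np.arange(1, n_m + 1), nb)
    mother_block = pd.DataFrame({
        "family_id": fid_m,
        "nuclear_id": unit_m,
        "role": "mother",
        "person_id": np.char.add(np.char.add(fid_m, "M"), unit_m.astype("U")),
        "mother_id": "",
        "adult_rel": rel,
        "sex": 0,
        "birth_year": m_by.ravel(),
        "maternal_age": ages.ravel(),
        "parity": parity.ravel(),
        "adhd_adult": y_m_obs.ravel(),
    })
    blocks = [mother_block]

    if n_c:
        fid_c = np.repeat(fid, n_c)
        u_c = np.tile(unit_of_child, nb)
        slot = np.tile(np.arange(1, n_c + 1), nb)
        child_block = pd.DataFrame({
            "family_id": fid_c,
            "nuclear_id": u_c + 1,
            "role": "child",
            "person_id": np.char.add(np.char.add(fid_c, "C"), slot.astype("U")),
            "mother_id": np.char.add(
                np.char.add(fid_c, "M"), (u_c + 1).astype("U")
            ),
            "adult_rel": rel,
            "sex": sexes.ravel(),
            "birth_year": c_by.ravel(),
            "maternal_age": ages[:, unit_of_child].ravel(),
            "parity": parity[:, unit_of_child].ravel(),
            **{name: kid_vals[name].ravel() for name in outcomes},
        })
        blocks.append(child_block)
    out = pd.concat(blocks, ignore_index=True)
    for c in SCHEMA_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    return out


# ---------------------------------------------------------------------------
# bivariate child-pair generator (extended twin model oracle and test bed)
# ---------------------------------------------------------------------------


@dataclass
class BivariateACEParams:
    """Standardised variance shares and cross-trait component correlations."""

    va1: float = 0.7
    vc1: float = 0.1
    ve1: float = 0.2
    va2: float = 0.7
    vc2: float = 0.1
    ve2: float = 0.2
    rG: float = 0.84
    rC: float = 0.3
    rE: float = 0.3

    def __post_init__(self) -> None:
        for v, r in ((self.rG, "rG"), (self.rC, "rC"), (self.rE, "rE")):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{r}={v} outside [-1, 1]")
        for tot, t in ((self.va1 + self.vc1 + self.ve1, 1),
                       (self.va2 + self.vc2 + self.ve2, 2)):
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"trait {t} variance shares sum to {tot:.4f}")

    def component_cov(self, which: str) -> np.ndarray:
        v1, v2, r = {
            "A": (self.va1, self.va2, self.rG),
            "C": (self.vc1, self.vc2, self.rC),
            "E": (self.ve1, self.ve2, self.rE),
        }[which]
        off = r * np.sqrt(v1 * v2)
        return np.array([[v1, off], [off, v2]])

    def to_cholesky(self):
        from .twin_model import CholeskyBivariateParams

        return CholeskyBivariateParams(
            a11=np.sqrt(self.va1),
            a21=self.rG * np.sqrt(self.va2),
            a22=np.sqrt(self.va2 * (1 - self.rG**2)),
            c11=np.sqrt(self.vc1),
            c21=self.rC * np.sqrt(self.vc2),
            c22=np.sqrt(self.vc2 * (1 - self.rC**2)),
            e11=np.sqrt(self.ve1),
            e21=self.rE * np.sqrt(self.ve2),
            e22=np.sqrt(self.ve2 * (1 - self.rE**2)),
        )


DEFAULT_PAIR_MIX = {
    "FULL_SIB": 0.40, "MAT_HALF_SIB": 0.15, "PAT_HALF_SIB": 0.15, "COUSIN": 0.30,
}


def simulate_pairs(
    n_pairs: int,
    params: BivariateACEParams | None = None,
    rel_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate child pairs for the extended bivariate twin model.

    Each component (A, C, E) is drawn per pair member with the second
    member's component constructed as ``gamma*first + sqrt(1-gamma^2)*new``,
    so relative-pair correlations arise mechanistically rather than from
    the model's implied 4x4 covariance.
    """
    params = params or BivariateACEParams()
    rel_mix = rel_mix or DEFAULT_PAIR_MIX
    _check_probs(rel_mix, "rel_mix")
    rng = np.random.default_rng(seed)
    keys = sorted(rel_mix)
    rel = np.array(keys)[
        rng.choice(len(keys), size=n_pairs, p=[rel_mix[k] for k in keys])
    ]
    gammas = {k: child_pair_gammas(ChildPairRelationship(k)) for k in keys}
    ga = np.array([gammas[r][0] for r in rel])
    gc = np.array([gammas[r][1] for r in rel])

    def draw(Kroot: np.ndarray, gamma: np.ndarray):
        z1 = rng.standard_normal((n_pairs, 2)) @ Kroot.T
        znew = rng.standard_normal((n_pairs, 2)) @ Kroot.T
        g = gamma[:, None]
        z2 = g * z1 + np.sqrt(1.0 - g**2) * znew
        return z1, z2

    ya = np.zeros((n_pairs, 2))
    yb = np.zeros((n_pairs, 2))
    for which, gamma in (("A", ga), ("C", gc), ("E", np.zeros(n_pairs))):
        K = params.component_cov(which)
        Kroot = np.linalg.cholesky(K + 1e-12 * np.eye(2))
        z1, z2 = draw(Kroot, gamma)
        ya += z1
        yb += z2
    return pd.DataFrame(
        {
            "pair_rel": rel,
            "gamma_a": ga,
            "gamma_c": gc,
            "trait1_a": ya[:, 0],
            "trait2_a": ya[:, 1],
            "trait1_b": yb[:, 0],
            "trait2_b": yb[:, 1],
        }
    )


# ---------------------------------------------------------------------------
# ordinal item layer (for testing scale scoring)
# ---------------------------------------------------------------------------


def simulate_item_responses(
    latent: np.ndarray,
    scale: ScaleDefinition | str,
    *,
    loading: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Likert item responses consistent with a latent score.

    Each item is a thresholded Gaussian: ``loading * z(latent) + noise``
    cut at equal-probability normal quantiles into the scale's response
    levels.  Returns an (n, n_items) integer matrix.
    """
    from scipy.stats import norm

    if isinstance(scale, str):
        scale = SCALES[scale]
    rng = np.random.default_rng(seed)
    z = np.asarray(latent, dtype=float)
    z = (z - np.nanmean(z)) / (np.nanstd(z) or 1.0)
    n = z.shape[0]
    noise = rng.standard_normal((n, scale.n_items)) * np.sqrt(1 - loading**2)
    y = loading * z[:, None] + noise
    cuts = norm.ppf(np.linspace(0, 1, scale.likert_levels + 1)[1:-1])
    return np.searchsorted(cuts, y).astype(int)


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------


def save_config(config: CohortConfig, params: GenerativeParams, path) -> None:
    """Write generator settings to a YAML key-value file."""
    def plain(obj):
        if isinstance(obj, dict):
            return {plain(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    doc = plain({
        "cohort": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
    })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[CohortConfig, GenerativeParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cohort = doc.get("cohort", {})
    for key in ("maternal_age", "birth_year_range"):
        if key in cohort:
            cohort[key] = tuple(cohort[key])
    for key in ("children_per_mother", "parity_probs"):
        if key in cohort:
            cohort[key] = {int(k): float(v) for k, v in cohort[key].items()}
    pars = doc.get("params", {})
    if "outcomes" in pars:
        pars["outcomes"] = {
            k: OutcomeParams(**v) for k, v in pars["outcomes"].items()
        }
    return CohortConfig(**cohort), GenerativeParams(**pars)
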