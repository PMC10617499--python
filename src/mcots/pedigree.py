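"""Extended-family structures and kinship algebra.

An *extended family* links two nuclear units: a pair of adult sisters
(monozygotic or dizygotic twins, full siblings, half-siblings or cousins),
each with her own children.  Every biometric model in this package builds
its expected phenotypic covariance from two ingredients defined here:

* the additive-genetic relatedness ``gamma_A`` of each within-family dyad
  (1 for MZ co-twins, 0.5 for DZ twins and full siblings, 0.25 for
  half-siblings, 0.125 for cousins, halving with each parent-child step), and
* a shared-household indicator ``gamma_C`` (cousins and paternal
  half-siblings are treated as not sharing a rearing household, so their
  shared-environment correlation is constrained to zero).

Fathers are unmeasured and treated as independent founders: one father per
nuclear unit, unrelated to everyone else.  Children within a nuclear unit
are therefore full siblings by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AdultPairRelationship",
    "ChildPairRelationship",
    "KinshipSpec",
    "PersonRecord",
    "ExtendedFamily",
    "kinship_coefficient",
    "build_relatedness_matrices",
    "child_pair_gammas",
    "allele_drop_relatedness",
    "SCHEMA_COLUMNS",
    "read_family_table",
    "write_family_table",
]


class AdultPairRelationship(str, Enum):
    """Relationship between the two mothers of an extended family."""

    MZ = "MZ"
    DZ = "DZ"
    FULL_SIB = "FULL_SIB"
    MAT_HALF_SIB = "MAT_HALF_SIB"
    PAT_HALF_SIB = "PAT_HALF_SIB"
    COUSIN = "COUSIN"
    SINGLETON = "SINGLETON"


class ChildPairRelationship(str, Enum):
    """Relationship between two children (the extended twin model's groups)."""

    FULL_SIB = "FULL_SIB"
    MAT_HALF_SIB = "MAT_HALF_SIB"
    PAT_HALF_SIB = "PAT_HALF_SIB"
    COUSIN = "COUSIN"


# additive-genetic correlation between the two adults of a pair
ADULT_GAMMA_A: dict[AdultPairRelationship, float] = {
    AdultPairRelationship.MZ: 1.0,
    AdultPairRelationship.DZ: 0.5,
    AdultPairRelationship.FULL_SIB: 0.5,
    AdultPairRelationship.MAT_HALF_SIB: 0.25,
    AdultPairRelationship.PAT_HALF_SIB: 0.25,
    AdultPairRelationship.COUSIN: 0.125,
    AdultPairRelationship.SINGLETON: 0.0,
}

# shared-rearing-household indicator for the adult pair; cousins and paternal
# half-siblings typically grew up in different households
ADULT_GAMMA_C: dict[AdultPairRelationship, float] = {
    AdultPairRelationship.MZ: 1.0,
    AdultPairRelationship.DZ: 1.0,
    AdultPairRelationship.FULL_SIB: 1.0,
    AdultPairRelationship.MAT_HALF_SIB: 1.0,
    AdultPairRelationship.PAT_HALF_SIB: 0.0,
    AdultPairRelationship.COUSIN: 0.0,
    AdultPairRelationship.SINGLETON: 0.0,
}

CHILD_GAMMA_A: dict[ChildPairRelationship, float] = {
    ChildPairRelationship.FULL_SIB: 0.5,
    ChildPairRelationship.MAT_HALF_SIB: 0.25,
    ChildPairRelationship.PAT_HALF_SIB: 0.25,
    ChildPairRelationship.COUSIN: 0.125,
}

CHILD_GAMMA_C: dict[ChildPairRelationship, float] = {
    ChildPairRelationship.FULL_SIB: 1.0,
    ChildPairRelationship.MAT_HALF_SIB: 1.0,
    ChildPairRelationship.PAT_HALF_SIB: 0.0,
    ChildPairRelationship.COUSIN: 0.0,
}


@dataclass(frozen=True)
class KinshipSpec:
    """Dyad-type sharing coefficients used to assemble expected covariances.

    ``gamma_A`` maps adult-pair codes to additive-genetic correlations;
    ``gamma_C_adult`` / ``gamma_C_child`` are household-sharing indicators
    for the adult pair and for child dyads.  ``c2_cross_share`` optionally
    lets children in different nuclear units share a fraction of the child
    shared environment (0 by default: cousins do not share a household).
    """

    gamma_A: dict[AdultPairRelationship, float] = field(
        default_factory=lambda: dict(ADULT_GAMMA_A)
    )
    gamma_C_adult: dict[AdultPairRelationship, float] = field(
        default_factory=lambda: dict(ADULT_GAMMA_C)
    )
    gamma_C_child: dict[ChildPairRelationship, float] = field(
        default_factory=lambda: dict(CHILD_GAMMA_C)
    )
    c2_cross_share: float = 0.0


def child_pair_gammas(
    rel: ChildPairRelationship | AdultPairRelationship,
    *,
    cross_unit: bool = False,
) -> tuple[float, float]:
    """Return ``(gamma_A, gamma_C)`` for a child dyad.

    For ``cross_unit=True``, ``rel`` is the *adults'* code and the children
    are in different nuclear units: their genetic correlation is
    ``0.25 * gamma_A(adult pair)`` (each child receives half of its mother's
    genome, fathers unrelated) and they never share a household.
    """
    if cross_unit:
        rel = AdultPairRelationship(rel)
        return 0.25 * ADULT_GAMMA_A[rel], 0.0
    rel = ChildPairRelationship(rel)
    return CHILD_GAMMA_A[rel], CHILD_GAMMA_C[rel]


# ---------------------------------------------------------------------------
# family container
# ---------------------------------------------------------------------------

ROLES = ("mother_1", "mother_2", "child_of_1", "child_of_2")


@dataclass
class PersonRecord:
    role: str
    person_id: str
    phenotypes: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)


@dataclass
class ExtendedFamily:
    """Two linked nuclear units; the unit of likelihood evaluation.

    Members are kept in canonical order — mothers first, then children
    grouped by mother — so that covariance rows are unambiguous.
    """

    family_id: str
    adult_rel: AdultPairRelationship
    members: list[PersonRecord]
    max_children_per_mother: int = 4

    def __post_init__(self) -> None:
        self.adult_rel = AdultPairRelationship(self.adult_rel)
        order = {"mother_1": 0, "mother_2": 1, "child_of_1": 2, "child_of_2": 3}
        for mem in self.members:
            if mem.role not in order:
                raise ValueError(f"unknown role {mem.role!r}")
        self.members.sort(key=lambda m: order[m.role])
        n_mothers = sum(m.role.startswith("mother") for m in self.members)
        if n_mothers > 2:
            raise ValueError(f"family {self.family_id}: more than 2 mothers")
        if self.adult_rel is AdultPairRelationship.SINGLETON and n_mothers > 1:
            raise ValueError(f"family {self.family_id}: SINGLETON with 2 mothers")
        for unit in ("1", "2"):
            k = sum(m.role == f"child_of_{unit}" for m in self.members)
            if k > self.max_children_per_mother:
                raise ValueError(
                    f"family {self.family_id}: {k} children in unit {unit} "
                    f"exceeds cap {self.max_children_per_mother}"
                )

    @property
    def roles(self) -> list[str]:
        return [m.role for m in self.members]

    def n_children(self, unit: int) -> int:
        return sum(m.role == f"child_of_{unit}" for m in self.members)


# ---------------------------------------------------------------------------
# kinship algebra
# ---------------------------------------------------------------------------


def kinship_coefficient(
    role_a: str,
    role_b: str,
    adult_rel: AdultPairRelationship | str,
    *,
    same_person: bool = False,
    within_unit_children: ChildPairRelationship = ChildPairRelationship.FULL_SIB,
) -> float:
    """Additive-genetic relatedness for one within-family dyad.

    ``role_a``/``role_b`` are canonical roles (``mother_1``, ``mother_2``,
    ``child_of_1``, ``child_of_2``).  Two distinct persons with the same
    child role are siblings within one nuclear unit (full siblings unless
    ``within_unit_children`` says otherwise).
    """
    adult_rel = AdultPairRelationship(adult_rel)
    gamma = ADULT_GAMMA_A[adult_rel]
    if role_a not in ROLES or role_b not in ROLES:
        raise ValueError(f"unknown dyad ({role_a!r}, {role_b!r})")
    if same_person:
        return 1.0
    a_mother = role_a.startswith("mother")
    b_mother = role_b.startswith("mother")
    ua, ub = role_a[-1], role_b[-1]
    if a_mother and b_mother:
        if ua == ub:
            raise ValueError(f"dyad ({role_a!r}, {role_b!r}): duplicate mother role")
        return gamma
    if a_mother != b_mother:  # cross-generation
        return 0.5 if ua == ub else 0.5 * gamma
    # child-child
    if ua == ub:
        return CHILD_GAMMA_A[ChildPairRelationship(within_unit_children)]
    return 0.25 * gamma


def build_relatedness_matrices(
    family: ExtendedFamily, spec: KinshipSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic and household-sharing matrices over a family's members.

    Returns ``(R_A, R_C)``: ``R_A`` is the symmetric PSD matrix of additive
    relatedness coefficients (unit diagonal); ``R_C`` is the 0/1 indicator
    of shared rearing household (adults per their pair code; a mother with
    her own children and children within one nuclear unit share a
    household; cross-unit child dyads and aunt-child dyads do not).
    """
    spec = spec or KinshipSpec()
    rel = family.adult_rel
    roles = family.roles
    n = len(roles)
    R_A = np.eye(n)
    R_C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = roles[i], roles[j]
            R_A[i, j] = R_A[j, i] = kinship_coefficient(ra, rb, rel)
            a_mother = ra.startswith("mother")
            b_mother = rb.startswith("mother")
            same_unit = ra[-1] == rb[-1]
            if a_mother and b_mother:
                c = spec.gamma_C_adult[rel]
            elif a_mother != b_mother:
                c = 1.0 if same_unit else 0.0
            else:
                c = 1.0 if same_unit else spec.c2_cross_share
            R_C[i, j] = R_C[j, i] = c
    return R_A, R_C


# ---------------------------------------------------------------------------
# allele-dropping oracle
# ---------------------------------------------------------------------------


def _mate(rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Drop alleles: child inherits one random allele from each parent per locus."""
    n = p1.shape[0]
    a = p1[np.arange(n), rng.integers(0, 2, n)]
    b = p2[np.arange(n), rng.integers(0, 2, n)]
    return np.column_stack([a, b])


def allele_drop_relatedness(
    adult_rel: AdultPairRelationship | str,
    n_children: tuple[int, int] = (1, 1),
    n_loci: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo relatedness matrix from gene dropping through the pedigree.

    Builds the explicit pedigree behind one extended family (grandparents,
    the two mothers, unrelated fathers, children), drops founder alleles
    through it at ``n_loci`` independent loci, and estimates each dyad's
    relatedness as twice the realized kinship (probability that two alleles
    drawn at random, one from each person, are identical by descent).
    Member order matches :class:`ExtendedFamily`: mothers first, then
    children grouped by mother.
    """
    adult_rel = AdultPairRelationship(adult_rel)
    rng = np.random.default_rng(seed)
    counter = [0]

    def founder() -> np.ndarray:
        g = np.column_stack(
            [
                np.full(n_loci, counter[0] * 2, dtype=np.int64),
                np.full(n_loci, counter[0] * 2 + 1, dtype=np.int64),
            ]
        )
        counter[0] += 1
        return g

    R = AdultPairRelationship
    if adult_rel is R.MZ:
        gm, gf = founder(), founder()
        m1 = _mate(rng, gm, gf)
        m2 = m1.copy()
    elif adult_rel in (R.DZ, R.FULL_SIB):
        gm, gf = founder(), founder()
        m1 = _mate(rng, gm, gf)
        m2 = _mate(rng, gm, gf)
    elif adult_rel is R.MAT_HALF_SIB:
        gm = founder()
        m1 = _mate(rng, gm, founder())
        m2 = _mate(rng, gm, founder())
    elif adult_rel is R.PAT_HALF_SIB:
        gf = founder()
        m1 = _mate(rng, founder(), gf)
        m2 = _mate(rng, founder(), gf)
    elif adult_rel is R.COUSIN:
        ggm, ggf = founder(), founder()
        aunt1 = _mate(rng, ggm, ggf)
        aunt2 = _mate(rng, ggm, ggf)
        m1 = _mate(rng, aunt1, founder())
        m2 = _mate(rng, aunt2, founder())
    elif adult_rel is R.SINGLETON:
        m1 = _mate(rng, founder(), founder())
        m2 = None
    else:  # pragma: no cover
        raise ValueError(adult_rel)

    people: list[np.ndarray] = [m1] + ([m2] if m2 is not None else [])
    father1 = founder()
    for _ in range(n_children[0]):
        people.append(_mate(rng, m1, father1))
    if m2 is not None:
        father2 = founder()
        for _ in range(n_children[1]):
            people.append(_mate(rng, m2, father2))

    n = len(people)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = people[i], people[j]
            # kinship = mean over loci of P(random allele of i == random allele of j)
            share = np.mean(
                (gi[:, :, None] == gj[:, None, :]).mean(axis=(1, 2))
            )
            out[i, j] = out[j, i] = 2.0 * share
    return out


# ---------------------------------------------------------------------------
# table schema and IO
# ---------------------------------------------------------------------------

#: long-format family table, one row per person; missing values are empty fields
SCHEMA_COLUMNS = [
    "family_id",
    "nuclear_id",
    "role",
    "person_id",
    "mother_id",
    "adult_rel",
    "sex",
    "birth_year",
    "maternal_age",
    "parity",
    "adhd_adult",
    "adhd_age5",
    "adhd_age8",
    "odd_age8",
    "conduct_age8",
    "anxiety_age8",
    "depression_age8",
]

_ID_COLS = ["family_id", "nuclear_id", "role", "person_id", "mother_id", "adult_rel"]


def read_family_table(path_or_buf) -> pd.DataFrame:
    """Read a comma-separated long-format family table (schema above)."""
    df = pd.read_csv(path_or_buf, dtype={c: "string" for c in _ID_COLS})
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"family table missing columns: {missing}")
    return df


def write_family_table(df: pd.DataFrame, path_or_buf) -> None:
    df.to_csv(path_or_buf, index=False)


def families_from_table(
    df: pd.DataFrame,
    phenotype_cols: Iterable[str],
    covariate_cols: Iterable[str] = (),
    max_children_per_mother: int = 4,
) -> list[ExtendedFamily]:
    """Assemble :class:`ExtendedFamily` objects from a long-format table."""
    phenotype_cols = list(phenotype_cols)
    covariate_cols = list(covariate_cols)
    fams = []
    for fid, grp in df.groupby("family_id", sort=True):
        rel = AdultPairRelationship(grp["adult_rel"].iloc[0])
        members = []
        for _, row in grp.iterrows():
            unit = str(row["nuclear_id"])
            role = "mother_" + unit if row["role"] == "mother" else "child_of_" + unit
            phen = {
                c: float(row[c]) for c in phenotype_cols if pd.notna(row[c])
            }
            cov = {c: float(row[c]) for c in covariate_cols if pd.notna(row[c])}
            members.append(PersonRecord(role, str(row["person_id"]), phen, cov))
        fams.append(
            ExtendedFamily(str(fid), rel, members, max_children_per_mother)
        )
    return fams
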