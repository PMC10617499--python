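"""Scale scoring, reliability, residualization and phenotypic correlations.

The symptom measures are questionnaire sum scores: six adult ADHD items on
a five-point scale (ASRS screener), twelve child ADHD items on four points
(CPRS-R short form), eighteen ADHD + eight ODD + eight conduct items on
four points (RS-DBD), five anxiety items on three points (SCARED short) and
thirteen depression items on three points (sMFQ).  Before model fitting,
every score is residualized on maternal age, parity and child birth year
(child measures additionally on child sex), and the residuals are analysed
as continuous traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScaleDefinition",
    "SCALES",
    "score_scale",
    "cronbach_alpha",
    "Residualizer",
    "residualize",
    "phenotypic_correlation",
    "reliability_report",
    "MATERNAL_COVARIATES",
    "CHILD_COVARIATES",
]

MATERNAL_COVARIATES = ["maternal_age", "parity", "birth_year"]
CHILD_COVARIATES = MATERNAL_COVARIATES + ["sex"]


@dataclass(frozen=True)
class ScaleDefinition:
    """A questionnaire scale: item count, response levels, reporting window."""

    name: str
    n_items: int
    likert_levels: int
    window: str = ""

    @property
    def max_score(self) -> int:
        return self.n_items * (self.likert_levels - 1)


SCALES: dict[str, ScaleDefinition] = {
    "asrs": ScaleDefinition("asrs", 6, 5, "past 6 months"),
    "cprs_r": ScaleDefinition("cprs_r", 12, 4, "past month"),
    "rsdbd_adhd": ScaleDefinition("rsdbd_adhd", 18, 4, "past year"),
    "rsdbd_odd": ScaleDefinition("rsdbd_odd", 8, 4, "past year"),
    "rsdbd_cd": ScaleDefinition("rsdbd_cd", 8, 4, "past year"),
    "scared": ScaleDefinition("scared", 5, 3, "recent"),
    "smfq": ScaleDefinition("smfq", 13, 3, "past 2 weeks"),
}

#: which scale produces which phenotype column
SCALE_FOR_MEASURE = {
    "adhd_adult": "asrs",
    "adhd_age5": "cprs_r",
    "adhd_age8": "rsdbd_adhd",
    "odd_age8": "rsdbd_odd",
    "conduct_age8": "rsdbd_cd",
    "anxiety_age8": "scared",
    "depression_age8": "smfq",
}


def score_scale(
    item_responses: np.ndarray,
    scale: ScaleDefinition | str,
    *,
    prorate_threshold: float = 0.8,
) -> np.ndarray:
    """Sum-score item responses, prorating moderate item missingness.

    ``item_responses`` is (n, n_items) with NaN for missing items; codes
    must lie in ``[0, likert_levels - 1]``.  Rows with at least
    ``prorate_threshold`` of items answered are prorated (answered sum
    scaled by ``n_items / n_answered``, rounded half to even); rows below
    the threshold score missing.
    """
    if isinstance(scale, str):
        scale = SCALES[scale]
    X = np.atleast_2d(np.asarray(item_responses, dtype=float))
    if X.shape[1] != scale.n_items:
        raise ValueError(
            f"{scale.name}: expected {scale.n_items} items, got {X.shape[1]}"
        )
    observed = ~np.isnan(X)
    bad = observed & ((X < 0) | (X > scale.likert_levels - 1) | (X % 1 != 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{scale.name}: item {j} response {X[i, j]!r} outside "
            f"[0, {scale.likert_levels - 1}]"
        )
    n_answered = observed.sum(axis=1)
    raw = np.nansum(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prorated = np.round(raw * scale.n_items / n_answered)
    out = np.where(n_answered == scale.n_items, raw, prorated)
    out = np.where(n_answered >= prorate_threshold * scale.n_items, out, np.nan)
    return out


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item variances)/var(sum))``.

    Rows with any missing item are dropped; needs >= 2 items and >= 3
    complete rows, and errors on zero total-score variance.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("cronbach_alpha needs a 2-D matrix with >= 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("cronbach_alpha needs >= 3 complete rows")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def reliability_report(
    items_by_scale: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Internal-consistency table: one row per scale (scale, n, alpha)."""
    rows = []
    for name, X in items_by_scale.items():
        X = np.asarray(X, dtype=float)
        complete = X[~np.isnan(X).any(axis=1)]
        rows.append(
            {"scale": name, "n": complete.shape[0], "alpha": cronbach_alpha(X)}
        )
    return pd.DataFrame(rows)


class Residualizer(BaseEstimator, TransformerMixin):
    """OLS residualization of scores on covariates (a sklearn transformer).

    ``fit(X)`` learns intercept + slopes per target column from the rows
    where target and covariates are all present; ``transform(X)`` returns
    residuals (NaN where the target or a covariate is missing).  Each
    target is fitted on all rows available for it, not listwise across
    measures.
    """

    def __init__(self, covariates: list[str] | None = None,
                 targets: list[str] | None = None) -> None:
        self.covariates = covariates
        self.targets = targets

    def _design(self, X: pd.DataFrame, rows: np.ndarray) -> np.ndarray:
        Z = X.loc[rows, self.covariates].to_numpy(float)
        return np.column_stack([np.ones(Z.shape[0]), Z])

    def fit(self, X: pd.DataFrame, y=None) -> "Residualizer":
        if not self.covariates:
            raise ValueError("covariates must be a non-empty column list")
        if self.targets is None:
            raise ValueError("targets must name the score columns")
        missing = [c for c in self.covariates + self.targets if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.coef_: dict[str, np.ndarray] = {}
        for t in self.targets:
            rows = X[t].notna() & X[self.covariates].notna().all(axis=1)
            if rows.sum() < len(self.covariates) + 2:
                raise ValueError(f"too few complete rows to residualize {t!r}")
            D = self._design(X, rows)
            rank = np.linalg.matrix_rank(D)
            if rank < D.shape[1]:
                raise ValueError(
                    f"collinear covariates for {t!r}: design rank {rank} < "
                    f"{D.shape[1]} columns {['const'] + list(self.covariates)}"
                )
            beta, *_ = np.linalg.lstsq(D, X.loc[rows, t].to_numpy(float), rcond=None)
            self.coef_[t] = beta
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for t, beta in self.coef_.items():
            rows = X[t].notna() & X[self.covariates].notna().all(axis=1)
            resid = np.full(len(X), np.nan)
            if rows.any():
                D = self._design(X, rows)
                resid[np.flatnonzero(rows.to_numpy())] = (
                    X.loc[rows, t].to_numpy(float) - D @ beta
                )
            out[t + "_resid"] = resid
        return out


def residualize(
    df: pd.DataFrame,
    targets: list[str],
    covariates: list[str],
) -> pd.DataFrame:
    """Replace scores by OLS residuals; adds ``<target>_resid`` columns."""
    return Residualizer(covariates=covariates, targets=targets).fit(df).transform(df)


def residualize_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Residualize the standard cohort measures on the standard covariates.

    The adult measure is adjusted for maternal age, parity and birth year;
    child measures additionally for child sex.  Child measures are fitted
    on child rows only (the covariate pattern differs by generation).
    """
    from .pedigree import SCHEMA_COLUMNS  # avoid import cycle at module load

    child_cols = [
        c for c in ("adhd_age5", "adhd_age8", "odd_age8", "conduct_age8",
                    "anxiety_age8", "depression_age8")
        if c in df.columns and df[c].notna().any()
    ]
    out = df.copy()
    mot = out["role"] == "mother"
    if "adhd_adult" in out.columns and out.loc[mot, "adhd_adult"].notna().any():
        sub = residualize(out.loc[mot], ["adhd_adult"], MATERNAL_COVARIATES)
        out.loc[mot, "adhd_adult_resid"] = sub["adhd_adult_resid"]
    kid = out["role"] == "child"
    if child_cols:
        sub = residualize(out.loc[kid], child_cols, CHILD_COVARIATES)
        for c in child_cols:
            out.loc[kid, c + "_resid"] = sub[c + "_resid"]
    return out


def phenotypic_correlation(
    x: np.ndarray,
    y: np.ndarray,
    *,
    level: float = 0.95,
    clusters: np.ndarray | None = None,
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation of paired residual scores with a Fisher-z CI.

    Pairs with a missing member are dropped (>= 10 complete pairs
    required).  With ``clusters`` given (e.g. family ids), the Fisher-z
    standard error uses the number of distinct clusters as the effective
    sample size — a conservative correction for non-independent pairs.
    """
    from scipy.stats import norm, pearsonr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 complete pairs, have {int(ok.sum())}")
    xv, yv = x[ok], y[ok]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(pearsonr(xv, yv).statistic)
    n_eff = ok.sum()
    if clusters is not None:
        n_eff = len(np.unique(np.asarray(clusters)[ok]))
    if n_eff < 4:
        raise ValueError("too few clusters for a Fisher-z interval")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se = 1.0 / np.sqrt(n_eff - 3)
    q = norm.ppf(0.5 + level / 2.0)
    lo, hi = np.tanh(z - q * se), np.tanh(z + q * se)
    return r, (float(lo), float(hi))
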