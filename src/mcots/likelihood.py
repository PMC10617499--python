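"""Full-information maximum-likelihood machinery for family-block models.

Each observation unit is a family (or child pair) whose phenotype vector
follows a multivariate normal with an expected covariance determined by the
family's configuration (relationship codes, child counts) and the model
parameters.  Missing phenotypes are handled by marginalising the normal
density to each unit's observed entries (FIML).

For speed, units are grouped by ``(configuration, missingness pattern)``:
every unit in a group shares one expected mean/covariance submatrix, so a
likelihood evaluation touches each distinct pattern once, using the group's
sufficient statistics (n, sum of y, sum of outer products).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "PatternGroup",
    "FitResult",
    "ModelComparison",
    "group_observations",
    "fiml_neg2ll",
    "fit_fiml",
    "profile_ci",
    "lrt",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class PatternGroup:
    """Sufficient statistics for all units sharing one (config, pattern)."""

    config: Hashable
    obs_idx: np.ndarray  # indices of observed entries in the full vector
    n: int
    sum_y: np.ndarray
    sum_yy: np.ndarray

    def __post_init__(self) -> None:
        self.mean_y = self.sum_y / self.n
        # centered scatter: sum_f (y_f - ybar)(y_f - ybar)'
        self.scatter = self.sum_yy - self.n * np.outer(self.mean_y, self.mean_y)


@dataclass
class FitResult:
    """Estimates and diagnostics of one FIML fit."""

    model: str
    estimates: dict[str, float]
    neg2ll: float
    converged: bool
    grad_norm: float
    n_units: int
    n_obs: int
    free_names: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    cis: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_starts: int = 1
    n_iter: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def summary(self) -> str:
        lines = [
            f"model: {self.model}",
            f"-2 log-likelihood: {self.neg2ll:.4f}",
            f"converged: {self.converged} (|grad| = {self.grad_norm:.2e})",
            f"units: {self.n_units}  observations: {self.n_obs}",
            "parameter estimates:",
        ]
        for k, v in self.estimates.items():
            tail = ""
            if k in self.cis:
                lo, hi, level = self.cis[k]
                tail = f"   [{lo:.3f}, {hi:.3f}] ({level:.0%} profile)"
            fx = "  (fixed)" if k in self.fixed else ""
            lines.append(f"  {k:>8s} = {v: .4f}{tail}{fx}")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested fits."""

    full: FitResult
    reduced: FitResult
    delta_neg2ll: float
    delta_df: int
    p_value: float
    boundary: bool = False
    label: str = ""

    def __str__(self) -> str:
        note = " (boundary: naive p conservative)" if self.boundary else ""
        return (
            f"{self.label or self.reduced.model} vs {self.full.model}: "
            f"d(-2LL)={self.delta_neg2ll:.3f}, ddf={self.delta_df}, "
            f"p={self.p_value:.4g}{note}"
        )


def group_observations(
    units: Iterable[tuple[Hashable, np.ndarray]],
) -> tuple[list[PatternGroup], int, int]:
    """Group unit vectors (with NaN for missing) by config and pattern.

    Returns ``(groups, n_units, n_obs)``.  Units with no observed entries
    contribute nothing to the likelihood and are dropped (counted in
    ``n_units`` but not ``n_obs``).
    """
    acc: dict[tuple, list[np.ndarray]] = {}
    n_units = 0
    for config, y in units:
        n_units += 1
        y = np.asarray(y, dtype=float)
        obs = np.flatnonzero(~np.isnan(y))
        if obs.size == 0:
            continue
        acc.setdefault((config, tuple(obs.tolist())), []).append(y[obs])
    groups: list[PatternGroup] = []
    n_obs = 0
    for (config, obs), ys in sorted(acc.items(), key=lambda kv: repr(kv[0])):
        Y = np.vstack(ys)
        # canonical row order: sufficient statistics (and hence the
        # likelihood) are bitwise invariant to the input unit order
        Y = Y[np.lexsort(Y.T[::-1])]
        groups.append(
            PatternGroup(
                config=config,
                obs_idx=np.asarray(obs, dtype=int),
                n=Y.shape[0],
                sum_y=Y.sum(axis=0),
                sum_yy=Y.T @ Y,
            )
        )
        n_obs += Y.size
    return groups, n_units, n_obs


def fiml_neg2ll(
    theta: np.ndarray,
    groups: Sequence[PatternGroup],
    cov_builder: Callable[[np.ndarray, Hashable], tuple[np.ndarray, np.ndarray]],
    *,
    penalty: float = 1e12,
    hard: bool = False,
) -> float:
    """-2 log-likelihood of grouped observations under the model.

    ``cov_builder(theta, config)`` must return the full ``(mean, covariance)``
    for a configuration; the observed submatrix is taken per pattern group.
    A non-positive-definite observed submatrix returns ``penalty`` (keeping
    the optimizer inside the admissible region) unless ``hard=True``.
    """
    total = 0.0
    cache: dict[Hashable, tuple[np.ndarray, np.ndarray]] = {}
    for g in groups:
        if g.config not in cache:
            cache[g.config] = cov_builder(theta, g.config)
        mu_full, sigma_full = cache[g.config]
        idx = g.obs_idx
        p = idx.shape[0]
        if p == mu_full.shape[0]:
            mu, S = mu_full, sigma_full
        else:
            mu = mu_full[idx]
            S = sigma_full[np.ix_(idx, idx)]
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            if hard:
                raise ValueError(
                    f"non-positive-definite covariance for config {g.config!r}"
                )
            return penalty
        logdet = 2.0 * np.sum(np.log(np.diagonal(L)))
        # M = sum_f (y_f - mu)(y_f - mu)' via the centered scatter
        d = g.mean_y - mu
        M = g.scatter + g.n * np.outer(d, d)
        quad = np.trace(linalg.cho_solve((L, True), M, check_finite=False))
        total += g.n * (p * _LOG2PI + logdet) + quad
        if not np.isfinite(total):
            if hard:
                raise ValueError("non-finite likelihood")
            return penalty
    return total


def _pack(
    param_names: Sequence[str], fixed: dict[str, float]
) -> tuple[list[str], list[int]]:
    free_names = [p for p in param_names if p not in fixed]
    free_idx = [i for i, p in enumerate(param_names) if p not in fixed]
    return free_names, free_idx


def fit_fiml(
    groups: Sequence[PatternGroup],
    cov_builder,
    param_names: Sequence[str],
    start: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    *,
    fixed: dict[str, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    jitter: float = 0.15,
    model_name: str = "model",
    n_units: int | None = None,
    n_obs: int | None = None,
    gtol: float = 1e-5,
    ftol: float = 1e-9,
) -> FitResult:
    """Minimise the FIML deviance with a bounded quasi-Newton optimizer.

    Runs ``n_starts`` optimizations (the supplied start plus seed-controlled
    jittered variants) and keeps the best converged solution.
    """
    fixed = dict(fixed or {})
    param_names = list(param_names)
    start = np.asarray(start, dtype=float)
    bounds = [tuple(b) for b in bounds]
    for name, val in fixed.items():
        if name not in param_names:
            raise ValueError(f"unknown fixed parameter {name!r}")
        start[param_names.index(name)] = val
    free_names, free_idx = _pack(param_names, fixed)
    full_theta = start.copy()

    def expand(x: np.ndarray) -> np.ndarray:
        th = full_theta.copy()
        th[free_idx] = x
        return th

    def objective(x: np.ndarray) -> float:
        return fiml_neg2ll(expand(x), groups, cov_builder)

    if not free_idx:  # fully constrained model: nothing to optimize
        val = fiml_neg2ll(full_theta, groups, cov_builder)
        return FitResult(
            model=model_name,
            estimates={p: float(v) for p, v in zip(param_names, full_theta)},
            neg2ll=float(val), converged=True, grad_norm=0.0,
            n_units=n_units if n_units is not None else sum(g.n for g in groups),
            n_obs=n_obs if n_obs is not None else -1,
            free_names=(), fixed=fixed,
        )

    rng = np.random.default_rng(seed)
    lo = np.array([bounds[i][0] for i in free_idx])
    hi = np.array([bounds[i][1] for i in free_idx])
    x0 = np.clip(start[free_idx], lo, hi)

    best = None
    messages: list[str] = []
    for s in range(max(1, n_starts)):
        if s == 0:
            xs = x0
        else:
            span = np.where(np.isfinite(hi - lo), hi - lo, 2.0)
            xs = np.clip(x0 + rng.normal(0.0, jitter, x0.size) * span / 2.0, lo, hi)
        res = optimize.minimize(
            objective,
            xs,
            method="L-BFGS-B",
            bounds=[(l, h) for l, h in zip(lo, hi)],
            options={"maxiter": 500, "ftol": ftol, "gtol": gtol},
        )
        messages.append(f"start {s}: f={res.fun:.6f} status={res.status}")
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(
            "no optimizer start converged to a finite deviance; "
            + "; ".join(messages)
        )
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    theta_hat = expand(best.x)
    estimates = {p: float(v) for p, v in zip(param_names, theta_hat)}
    return FitResult(
        model=model_name,
        estimates=estimates,
        neg2ll=float(best.fun),
        converged=bool(best.success or grad_norm < 1e-2),
        grad_norm=grad_norm,
        n_units=n_units if n_units is not None else sum(g.n for g in groups),
        n_obs=n_obs if n_obs is not None else -1,
        free_names=tuple(free_names),
        fixed=fixed,
        n_starts=max(1, n_starts),
        n_iter=int(best.nit),
        messages=messages,
    )


def profile_ci(
    groups,
    cov_builder,
    param_names: Sequence[str],
    bounds: Sequence[tuple[float, float]],
    fit: FitResult,
    param: str,
    level: float = 0.95,
    *,
    xtol: float = 5e-3,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    Searches on each side of the estimate for the value at which the
    deviance, with all other parameters re-optimized, rises by the
    chi-square(1) critical value (3.84 at 95%).  If the profile stays below
    that rise all the way to a parameter-space bound (e.g. a correlation of
    1), the bound itself is returned, mirroring interval endpoints that
    terminate at 1.  Nuisance refits are warm-started from the nearest
    previously profiled point.
    """
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    param_names = list(param_names)
    crit = stats.chi2.ppf(level, 1)
    target = fit.neg2ll + crit
    i = param_names.index(param)
    lo_b, hi_b = bounds[i]
    hat = fit.estimates[param]

    warm = {p: fit.estimates[p] for p in param_names}

    def dev(v: float) -> float:
        start = [warm[p] for p in param_names]
        sub = fit_fiml(
            groups,
            cov_builder,
            param_names,
            start,
            bounds,
            fixed={**fit.fixed, param: float(v)},
            n_starts=1,
            model_name=fit.model,
            gtol=1e-4,
            ftol=1e-8,
        )
        warm.update(sub.estimates)
        return sub.neg2ll

    out = []
    for bound, direction in ((lo_b, -1.0), (hi_b, +1.0)):
        warm.update(fit.estimates)
        if not np.isfinite(bound):
            bound = hat + direction * 10.0
        span = abs(bound - hat)
        if span < 1e-9:
            out.append(bound)
            continue
        d_bound = dev(bound)
        if d_bound < target:
            # profile never reaches the critical rise before the bound
            out.append(bound)
            continue
        a, b = hat, bound
        try:
            root = optimize.brentq(
                lambda v: dev(v) - target, a, b, xtol=xtol, rtol=1e-4
            )
        except ValueError:  # non-monotone profile; fall back to widest bracket
            fit.messages.append(
                f"profile for {param}: non-monotone on side {direction:+.0f}"
            )
            root = b
        out.append(float(root))
    lower, upper = min(out), max(out)
    fit.cis[param] = (lower, upper, level)
    return lower, upper


def lrt(full: FitResult, reduced: FitResult, *, label: str = "") -> ModelComparison:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if not set(reduced.free_names) <= set(full.free_names) | set(full.fixed):
        raise ValueError("models are not nested: free parameters do not align")
    delta_df = full.n_free - reduced.n_free
    if delta_df <= 0:
        raise ValueError("reduced model must have fewer free parameters")
    delta = reduced.neg2ll - full.neg2ll
    if delta < -0.05:  # beyond optimizer tolerance noise
        raise ValueError(
            f"reduced model fits better than full (d(-2LL) = {delta:.4g}); "
            "check convergence"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, delta_df))
    # variance-type parameters pinned at 0 sit on the boundary of the space
    boundary = any(
        abs(v) < 1e-12 and name not in ("rA", "rG", "m")
        for name, v in reduced.fixed.items()
        if name not in full.fixed
    )
    return ModelComparison(
        full=full,
        reduced=reduced,
        delta_neg2ll=float(delta),
        delta_df=delta_df,
        p_value=p,
        boundary=boundary,
        label=label,
    )
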