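"""Exact and Monte-Carlo false-alarm analysis; speed–accuracy curves.

A *false alarm* is a uniformly random input order driving the readout
neuron's potential to its threshold θ.  Because every scheme's increments
are non-negative, a trajectory that ever reaches θ has final potential
``≥ θ``, so the false-alarm probability is the upper tail of the final
potential.

Three routes to that tail probability, cross-checking one another:

- **exact** — exhaustive enumeration of Λ (guarded; exact rationals), or,
  for NoM, the hypergeometric upper tail ``P(X ≥ θ)`` with
  ``X ~ Hypergeometric(M, W, N)`` at any ``M``;
- **Monte Carlo** — ``n`` uniform orders, a binomial proportion with a
  Clopper–Pearson 95% interval;
- **Gaussian** — a normal tail with the closed-form mean and variance of
  the potential (accurate in the bulk, optimistic in the far right tail).

The speed–accuracy trade-off pairs each preferred-pattern latency ``L``
with the largest threshold reaching it, ``θ = S_pref(L)``, and the
false-alarm probability at that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np
from scipy import stats

from .errors import ValidationError
from .patterns import (
    ENUMERATION_GUARD,
    check_enumeration_guard,
    enumerate_orders_array,
    sample_uniform_many,
)
from .schemes import (
    THRESHOLD_TOL,
    SchemeSpec,
    batch_potentials,
    preferred_pattern,
    trajectory,
)
from . import analytics

ExactPolicy = Literal["auto", "always", "never"]


@dataclass(frozen=True)
class FAEstimate:
    """False-alarm probability at one threshold, with uncertainty."""

    theta: float
    n: int
    hits: int
    p_hat: float
    ci_low: float
    ci_high: float
    p_gauss: float | None
    p_exact: Fraction | None
    seed: int | None


@dataclass(frozen=True)
class SpeedAccuracyPoint:
    """(latency on the preferred pattern, false-alarm estimate) pair."""

    theta: float
    latency_pref: int
    fa: FAEstimate


def exact_potential_distribution(
    spec: SchemeSpec, I: int | None = None, limit: int = ENUMERATION_GUARD
) -> dict[int | float, Fraction]:
    """Exact distribution of the depth-``I`` potential over all ``M!`` orders.

    Probabilities are exact rationals summing to 1.  Integer-valued schemes
    key by int; ROC keys by the float potential rounded to 9 decimals to
    merge round-off duplicates.
    """
    if I is None:
        I = spec.i_max
    check_enumeration_guard(spec.M, limit)
    total = math.factorial(spec.M)
    counts: dict[int | float, int] = {}
    for orders in enumerate_orders_array(spec.M, limit):
        pots = batch_potentials(spec, orders, I)
        if spec.kind == "roc":
            values, c = np.unique(np.round(pots, 9), return_counts=True)
            for v, k in zip(values, c):
                key = float(v)
                counts[key] = counts.get(key, 0) + int(k)
        else:
            values, c = np.unique(pots.astype(np.int64), return_counts=True)
            for v, k in zip(values, c):
                counts[int(v)] = counts.get(int(v), 0) + int(k)
    return {v: Fraction(k, total) for v, k in sorted(counts.items())}


def _nom_tail(spec: SchemeSpec, theta: float) -> Fraction:
    # Hypergeometric upper tail: exact at any M, no enumeration needed.
    k_min = math.ceil(theta - THRESHOLD_TOL)
    lo = max(k_min, 0)
    hi = min(spec.N, spec.W)
    if lo > hi:
        return Fraction(0)
    num = sum(
        math.comb(spec.W, k) * math.comb(spec.M - spec.W, spec.N - k)
        for k in range(lo, hi + 1)
    )
    return Fraction(num, math.comb(spec.M, spec.N))


def exact_fa(
    spec: SchemeSpec, theta: float, limit: int = ENUMERATION_GUARD
) -> Fraction:
    """Exact false-alarm probability ``P(S_final ≥ θ)`` as a rational.

    NoM uses the hypergeometric tail at any ``M``; ROC/R-NoM enumerate Λ
    (guarded — ROC at ``M = 10`` means all 10! = 3 628 800 orders).
    """
    if theta <= 0:
        return Fraction(1)
    if spec.kind == "nom":
        return _nom_tail(spec, theta)
    return exact_fa_multi(spec, [theta], limit)[0]


def exact_fa_multi(
    spec: SchemeSpec, thetas: list[float], limit: int = ENUMERATION_GUARD
) -> list[Fraction]:
    """Exact FA at several thresholds from a single pass over Λ."""
    if spec.kind == "nom":
        return [_nom_tail(spec, t) for t in thetas]
    check_enumeration_guard(spec.M, limit)
    total = math.factorial(spec.M)
    hits = np.zeros(len(thetas), dtype=np.int64)
    th = np.asarray(thetas, dtype=float) - THRESHOLD_TOL
    for orders in enumerate_orders_array(spec.M, limit):
        pots = batch_potentials(spec, orders)
        hits += (pots[:, None] >= th[None, :]).sum(axis=0)
    return [Fraction(int(h), total) for h in hits]


def _clopper_pearson(hits: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    lo = 0.0 if hits == 0 else float(stats.beta.ppf(a, hits, n - hits + 1))
    hi = 1.0 if hits == n else float(stats.beta.ppf(1 - a, hits + 1, n - hits))
    return lo, hi


def gaussian_fa(spec: SchemeSpec, theta: float, I: int | None = None) -> float:
    """Normal-approximation false alarm: upper tail of N(E[S_I], Var[S_I])."""
    if I is None:
        I = spec.i_max
    var = analytics.var_potential(spec, I)
    if var <= 0:
        raise ValidationError("zero potential variance: Gaussian tail undefined")
    mean = analytics.mean_potential(spec, I)
    return float(stats.norm.sf(theta, loc=float(mean), scale=math.sqrt(float(var))))


def mc_estimate_fa(
    spec: SchemeSpec,
    theta: float,
    n: int = 200_000,
    seed: int | np.random.Generator = 0,
    exact: ExactPolicy = "auto",
    exact_limit: int = ENUMERATION_GUARD,
) -> FAEstimate:
    """Monte-Carlo false-alarm estimate over ``n`` uniform random orders.

    Fully reproducible under ``seed``; carries a Clopper–Pearson 95%
    interval, the Gaussian approximation, and (policy permitting) the exact
    probability.  ``exact="auto"`` attaches it when enumeration is within
    the guard or the NoM closed form applies.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), int(seed)
    orders = sample_uniform_many(spec.M, n, rng)
    pots = batch_potentials(spec, orders)
    hits = int((pots >= theta - THRESHOLD_TOL).sum())
    lo, hi = _clopper_pearson(hits, n)
    try:
        p_gauss = gaussian_fa(spec, theta)
    except ValidationError:
        p_gauss = None
    p_exact = _maybe_exact(spec, theta, exact, exact_limit)
    return FAEstimate(
        theta=float(theta),
        n=n,
        hits=hits,
        p_hat=hits / n,
        ci_low=lo,
        ci_high=hi,
        p_gauss=p_gauss,
        p_exact=p_exact,
        seed=seed_out,
    )


def _maybe_exact(
    spec: SchemeSpec, theta: float, policy: ExactPolicy, limit: int
) -> Fraction | None:
    if policy == "never":
        return None
    if spec.kind == "nom":
        return _nom_tail(spec, theta)
    if policy == "always" or math.factorial(spec.M) <= limit:
        # "always" does not lift the guard: an oversized M still refuses.
        return exact_fa(spec, theta, limit=limit)
    return None


def threshold_interval_for_latency(
    spec: SchemeSpec, L: int
) -> tuple[float, float]:
    """Thresholds for which the preferred pattern fires exactly at spike ``L``.

    The half-open interval ``(S_pref(L−1), S_pref(L)]`` under the ≥ firing
    rule; its upper endpoint minimizes the false-alarm rate at latency
    ``L``.
    """
    if not 1 <= L <= spec.i_max:
        raise ValidationError(f"latency {L} out of range [1, {spec.i_max}]")
    pref = preferred_pattern(spec)
    traj = trajectory(spec, pref)
    low = 0.0 if L == 1 else float(traj[L - 2])
    return low, float(traj[L - 1])


def verify_closed_forms(
    max_M: int = 7,
    m_values: tuple[float, ...] = (0.5, 0.8),
    limit: int = ENUMERATION_GUARD,
):
    """Cross-check closed-form moments against exhaustive enumeration.

    For every scheme, every ``M ≤ max_M`` (with ``N = W = ⌈M/2⌉`` for
    NoM/R-NoM and each ``m`` for ROC) and every valid depth, compares the
    enumeration oracle's exact mean, variance, and maximum of the potential
    with the closed-form pipeline.  Returns a DataFrame of relative errors;
    integer schemes must agree exactly (error 0), ROC to float round-off.
    """
    import pandas as pd

    rows = []
    for M in range(2, max_M + 1):
        half = (M + 1) // 2
        specs = [
            SchemeSpec("nom", M, half, half),
            SchemeSpec("rnom", M, half, half),
        ] + [SchemeSpec("roc", M, m=m) for m in m_values]
        for spec in specs:
            for I in range(1, spec.i_max + 1):
                dist = exact_potential_distribution(spec, I, limit)
                mean = sum(Fraction(v) * p for v, p in dist.items())
                var = (
                    sum(Fraction(v) ** 2 * p for v, p in dist.items())
                    - mean * mean
                )
                mx = max(dist)
                cf_mean = analytics.mean_potential(spec, I)
                cf_var = analytics.var_potential(spec, I)
                cf_max = analytics.max_potential(spec, I)
                rows.append(
                    {
                        "scheme": spec.kind,
                        "M": M,
                        "m": spec.m,
                        "I": I,
                        "err_mean": _rel_err(mean, cf_mean),
                        "err_var": _rel_err(var, cf_var),
                        "err_max": _rel_err(Fraction(mx), cf_max),
                    }
                )
    return pd.DataFrame(rows)


def _rel_err(exact_value: Fraction, closed_form) -> float:
    a, b = float(exact_value), float(closed_form)
    denom = max(abs(a), abs(b), 1e-30)
    return abs(a - b) / denom


def speed_accuracy_curve(
    spec: SchemeSpec,
    n: int = 200_000,
    seed: int = 0,
    exact: ExactPolicy = "auto",
    exact_limit: int = ENUMERATION_GUARD,
) -> list[SpeedAccuracyPoint]:
    """False alarm versus preferred-pattern latency, one point per depth.

    For each target latency ``L = 1 … I_max`` the threshold is set to
    ``θ = S_pref(L)`` (the largest value still yielding latency ``L``, which
    minimizes the false-alarm rate).  Each point carries the Monte-Carlo
    estimate (independent substream per ``L``), the Gaussian approximation,
    and the exact probability when feasible — computed in one enumeration
    pass shared across all thresholds.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    pref = preferred_pattern(spec)
    traj = trajectory(spec, pref)
    thetas = [float(t) for t in traj]
    exacts: list[Fraction | None]
    if exact != "never" and (
        spec.kind == "nom" or math.factorial(spec.M) <= exact_limit
    ):
        exacts = list(exact_fa_multi(spec, thetas, exact_limit))
    elif exact == "always":
        exacts = list(exact_fa_multi(spec, thetas, exact_limit))
    else:
        exacts = [None] * len(thetas)
    children = np.random.SeedSequence(seed).spawn(len(thetas))
    points = []
    for L, (theta, ss, p_exact) in enumerate(zip(thetas, children, exacts), start=1):
        est = mc_estimate_fa(
            spec, theta, n=n, seed=np.random.default_rng(ss), exact="never"
        )
        est = FAEstimate(
            theta=est.theta,
            n=est.n,
            hits=est.hits,
            p_hat=est.p_hat,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
            p_gauss=est.p_gauss,
            p_exact=p_exact,
            seed=seed,
        )
        points.append(SpeedAccuracyPoint(theta=theta, latency_pref=L, fa=est))
    return points
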