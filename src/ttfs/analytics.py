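"""Closed-form statistics of the membrane potential under random inputs.

With all ``M!`` input orders equiprobable, the potential after ``I`` spikes,
``S_I = Σ_{i≤I} v_i · W'_i`` (modulation × score), has moments that follow
from finite-population sampling without replacement: the per-rank scores
``W'_i`` are exchangeable, identically distributed and negatively
correlated, with ``Cov(W'_i, W'_j) = −Var(W'_i)/(M−1)``.

This module evaluates, per scheme and depth:

- the per-component score moments ``μ_W``, ``Var_W``, ``Cov_W``;
- the integration coefficients ``λ = Σ v_i``, ``α = Σ v_i²``,
  ``β = λ² − α``;
- ``E[S_I] = λ·μ_W`` and ``Var[S_I] = α·Var_W + β·Cov_W``;
- the maximal potential (largest scores paired with largest modulations —
  optimal by the rearrangement inequality since both are non-increasing);
- the discriminability ``D(I) = (max S_I − E S_I) / SD(S_I)``, a
  signal-to-noise ratio of the preferred response against random inputs.

Integer schemes (NoM, R-NoM) are evaluated in exact rational arithmetic
(:class:`fractions.Fraction`); floats appear only for ROC's geometric sums
and in the final square root of ``D``.

Asymptotics: with ``N = W = M/2`` the maximal discriminability of NoM and
R-NoM is exactly ``√(M−1)`` — unbounded in ``M`` — while ROC saturates at
``√(3(1+m)/(1−m))`` regardless of ``M``.

Closed forms for NoM/R-NoM are stated for ``W ≥ N`` and refuse other
parameterizations; direct summation in :mod:`ttfs.schemes` stays general.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Union

from .errors import ValidationError
from .schemes import SchemeSpec

Number = Union[int, float, Fraction]


@dataclass(frozen=True)
class MomentSet:
    """All closed-form quantities for one scheme at one depth."""

    I: int
    lam: Number
    alpha: Number
    beta: Number
    mu_W: Number
    var_W: Number
    cov_W: Number | None
    mean_S: Number
    var_S: Number
    max_S: Number
    D: float


def _require_closed_form(spec: SchemeSpec) -> None:
    if spec.kind in ("nom", "rnom") and spec.W < spec.N:
        raise ValidationError(
            f"closed-form analytics for {spec.kind} are stated for W >= N "
            f"(got W={spec.W}, N={spec.N}); use direct summation instead"
        )


def _check_depth(spec: SchemeSpec, I: int, allow_zero: bool = True) -> None:
    lo = 0 if allow_zero else 1
    if not lo <= I <= spec.i_max:
        raise ValidationError(
            f"depth {I} out of range [{lo}, {spec.i_max}] for {spec.kind}"
        )


def score_moments(spec: SchemeSpec) -> tuple[Fraction, Fraction, Fraction | None]:
    """Mean, variance, and cross-covariance of a single rank's score.

    Exact rationals for every scheme.  Covariance is ``None`` at ``M = 1``
    (undefined).  For all schemes the finite-population identity
    ``Cov = −Var/(M−1)`` holds.
    """
    M, N, W = spec.M, spec.N, spec.W
    if spec.kind == "rnom":
        mu = Fraction(W * (W + 1), 2 * M)
        var = mu * (Fraction(2 * W + 1, 3) - mu)
    elif spec.kind == "nom":
        mu = Fraction(W, M)
        var = mu * (1 - mu)
    else:
        mu = Fraction(M + 1, 2)
        var = mu * Fraction(M - 1, 6)
    if M == 1:
        return mu, var, None
    cov = -var / (M - 1)
    return mu, var, cov


def integration_coefficients(
    spec: SchemeSpec, I: int
) -> tuple[Number, Number, Number]:
    """``(λ, α, β)``: sums of gated modulations, their squares, and pairs.

    ``λ = Σ_{i≤I} v_i``, ``α = Σ_{i≤I} v_i²``, ``β = λ² − α`` (the
    coefficient multiplying the score covariance in ``Var[S_I]``).
    """
    _require_closed_form(spec)
    _check_depth(spec, I, allow_zero=False)
    if spec.kind == "rnom":
        N = spec.N
        lam = Fraction(I * (2 * N - I + 1), 2)
        alpha = N * I * (N - I + 1) + Fraction(I * (I - 1) * (2 * I - 1), 6)
        beta = lam * lam - alpha
        return lam, alpha, beta
    if spec.kind == "nom":
        return I, I, I * (I - 1)
    m = float(spec.m)
    lam = (1.0 - m**I) / (1.0 - m)
    alpha = (1.0 - m ** (2 * I)) / (1.0 - m * m)
    return lam, alpha, lam * lam - alpha


def max_potential(spec: SchemeSpec, I: int) -> Number:
    """Maximal potential at depth ``I``, attained by the preferred pattern.

    R-NoM: ``Σ_{i≤I} (N−i+1)(W−i+1)``; NoM: ``I``; ROC:
    ``Σ_{i≤I} m^{i−1}(M−i+1)``.
    """
    _require_closed_form(spec)
    _check_depth(spec, I)
    if spec.kind == "rnom":
        return sum((spec.N - i + 1) * (spec.W - i + 1) for i in range(1, I + 1))
    if spec.kind == "nom":
        return I
    m = float(spec.m)
    return float(
        sum(m ** (i - 1) * (spec.M - i + 1) for i in range(1, I + 1))
    )


def max_potential_final_closed_form(spec: SchemeSpec) -> Number:
    """The final-depth maximum in its closed algebraic form.

    R-NoM: ``W·N(N+1)/2 + N(1−N²)/6``; NoM: ``N``; ROC:
    ``((1−m)(1+M) − (1−m^{M+1})) / (1−m)²``.  Equals
    ``max_potential(spec, i_max)``.
    """
    _require_closed_form(spec)
    if spec.kind == "rnom":
        return Fraction(spec.W * spec.N * (spec.N + 1), 2) + Fraction(
            spec.N * (1 - spec.N**2), 6
        )
    if spec.kind == "nom":
        return spec.N
    m, M = float(spec.m), spec.M
    return ((1 - m) * (1 + M) - (1 - m ** (M + 1))) / (1 - m) ** 2


def mean_potential(spec: SchemeSpec, I: int) -> Number:
    """Expected potential at depth ``I`` over uniform random orders: λ·μ_W."""
    if I == 0:
        return 0
    mu, _, _ = score_moments(spec)
    lam, _, _ = integration_coefficients(spec, I)
    out = lam * mu
    return float(out) if spec.kind == "roc" else out


def var_potential(spec: SchemeSpec, I: int) -> Number:
    """Variance of the potential at depth ``I``: α·Var_W + β·Cov_W."""
    if I == 0:
        return 0
    if spec.M < 2:
        raise ValidationError("variance needs M >= 2 (covariance undefined)")
    _, var, cov = score_moments(spec)
    _, alpha, beta = integration_coefficients(spec, I)
    out = alpha * var + beta * cov
    return float(out) if spec.kind == "roc" else out


def discriminability(spec: SchemeSpec, I: int) -> float:
    """Signal-to-noise ratio ``D(I) = (max S_I − E S_I) / SD(S_I)``.

    For NoM/R-NoM the curve is defined up to ``I = N``; for ``N < I ≤ M``
    the final value ``D(N)`` is retained (propagation has stopped).
    """
    if spec.kind in ("nom", "rnom") and spec.N < I <= spec.M:
        I = spec.N
    _check_depth(spec, I, allow_zero=False)
    var = var_potential(spec, I)
    if var <= 0:
        raise ValidationError(
            f"potential variance is zero for {spec.kind} at I={I} "
            "(e.g., NoM with W=M): discriminability is undefined"
        )
    gap = max_potential(spec, I) - mean_potential(spec, I)
    return float(gap) / math.sqrt(float(var))


def rnom_nom_max_discriminability(M: int) -> float:
    """Maximal discriminability of NoM and R-NoM at ``N = W = M/2``: √(M−1).

    Both schemes saturate to the same value, strictly increasing and
    unbounded in ``M``.
    """
    if M < 4 or M % 2:
        nearest = max(4, M + (M % 2))
        raise ValidationError(
            f"M must be even and >= 4 so that N = W = M/2 is integral "
            f"(got {M}; nearest valid is {nearest})"
        )
    return math.sqrt(M - 1)


def roc_asymptotic_discriminability(m: float) -> float:
    """Large-``M`` limit of ROC discriminability: ``√(3(1+m)/(1−m))``.

    The geometric modulation discards late spikes so quickly that extra
    afferents stop helping; at ``m = 0.8`` the ceiling is ``√27 ≈ 5.196``.
    """
    if not 0 < m < 1:
        raise ValidationError(f"modulation ratio must satisfy 0 < m < 1, got {m}")
    return math.sqrt(3 * (1 + m) / (1 - m))


def moment_set(spec: SchemeSpec, I: int) -> MomentSet:
    """Bundle every closed-form quantity at depth ``I`` (for tables/CSV)."""
    mu, var, cov = score_moments(spec)
    lam, alpha, beta = integration_coefficients(spec, I)
    return MomentSet(
        I=I,
        lam=lam,
        alpha=alpha,
        beta=beta,
        mu_W=mu,
        var_W=var,
        cov_W=cov,
        mean_S=mean_potential(spec, I),
        var_S=var_potential(spec, I),
        max_S=max_potential(spec, I),
        D=discriminability(spec, I),
    )
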