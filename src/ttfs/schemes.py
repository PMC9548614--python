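"""The three rank-based coding schemes and membrane-potential integration.

A readout neuron assigns synaptic weights ``M, M−1, …, 1`` to its afferents
in preferred order.  When the afferents fire in order ``p`` (a
:class:`~ttfs.patterns.SpikePattern`), the spike arriving at rank ``i``
carries weight ``M − p.order[i−1]``.  Each scheme then transforms the
weights into *scores* and multiplies them by a rank-dependent *modulation*:

- **ROC** (rank-order coding): all ``M`` spikes propagate; scores are the
  raw weights; modulation decreases geometrically, ``m^(i−1)`` at rank
  ``i`` with ratio ``0 < m < 1``.
- **NoM** (N-of-M): only the first ``N`` spikes propagate (k-WTA gate);
  binary scores (1 on the ``W`` strongest weights, 0 elsewhere); constant
  modulation 1 up to the cut-off.
- **R-NoM** (ranked N-of-M): N-of-M gating with graded integer scores
  ``W, W−1, …, 1, 0, …`` and linearly decreasing integer modulation
  ``N, N−1, …, 1, 0, …``.

The membrane potential after ``I`` spikes is the gated inner product
``S(I) = Σ_{i≤I} v_i · score_i``.  It is an exact integer for NoM/R-NoM and
a float for ROC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ValidationError
from .patterns import SpikePattern

SchemeKind = Literal["roc", "nom", "rnom"]

_KINDS = ("roc", "nom", "rnom")


@dataclass(frozen=True)
class SchemeSpec:
    """Parameterization of one coding scheme.

    Parameters
    ----------
    kind : {"roc", "nom", "rnom"}
    M : int
        Number of afferents.
    N : int, optional
        Propagation cut-off (count of first spikes kept).  Forced to ``M``
        for ROC; required for NoM/R-NoM.
    W : int, optional
        Count of non-zero weights.  Forced to ``M`` for ROC.
    m : float, optional
        Geometric modulation ratio, ROC only, ``0 < m < 1``.
    """

    kind: SchemeKind
    M: int
    N: int | None = None
    W: int | None = None
    m: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown scheme kind {self.kind!r}")
        if self.M < 1:
            raise ValidationError("M must be >= 1")
        if self.kind == "roc":
            object.__setattr__(self, "N", self.M)
            object.__setattr__(self, "W", self.M)
            if self.m is None or not 0 < self.m < 1:
                raise ValidationError("ROC requires a modulation ratio 0 < m < 1")
        else:
            if self.N is None or self.W is None:
                raise ValidationError(f"{self.kind} requires N and W")
            if not 1 <= self.N <= self.M:
                raise ValidationError("need 1 <= N <= M")
            if not 1 <= self.W <= self.M:
                raise ValidationError("need 1 <= W <= M")
            if self.m is not None:
                raise ValidationError("m is only meaningful for ROC")

    @property
    def i_max(self) -> int:
        """Depth at which the potential is final: M for ROC, N otherwise."""
        return self.M if self.kind == "roc" else self.N  # type: ignore[return-value]


def weights_from_pattern(p: SpikePattern) -> np.ndarray:
    """Weight received at each arrival rank: component i is ``M − order[i]``.

    The result is a permutation of ``{1, …, M}``; the preferred pattern
    yields the decreasing sequence ``M, M−1, …, 1``.
    """
    return p.M - p.as_array()


def score_transform(spec: SchemeSpec, w: np.ndarray) -> np.ndarray:
    """Apply the scheme's score map to a weight vector (rank-ordered).

    ROC keeps the weights; R-NoM shifts and clips, ``max(0, w − M + W)``,
    keeping the top ``W`` weights as ``W … 1``; NoM binarizes those.
    """
    w = np.asarray(w, dtype=np.int64)
    if spec.kind == "roc":
        return w.copy()
    shifted = np.maximum(0, w - spec.M + spec.W)
    if spec.kind == "rnom":
        return shifted
    return (shifted > 0).astype(np.int64)


def modulation_vector(spec: SchemeSpec) -> np.ndarray:
    """Rank-dependent modulation ``v`` (length M, non-increasing).

    ROC: ``(1, m, m², …, m^{M−1})``; R-NoM: ``(N, N−1, …, 1, 0, …)``;
    NoM: ``N`` ones then zeros.
    """
    i = np.arange(spec.M)
    if spec.kind == "roc":
        return np.power(float(spec.m), i)
    if spec.kind == "rnom":
        return np.maximum(0, spec.N - i).astype(np.int64)
    return (i < spec.N).astype(np.int64)


def support_cardinality(spec: SchemeSpec) -> int:
    """Exact number of distinct score vectors the scheme can produce.

    ROC: ``M!`` (scores are permutations); R-NoM: ``M!/(M−W)!`` (the zero
    block is order-free); NoM: ``C(M, W)`` (binary, order-free).
    """
    if spec.kind == "roc":
        return math.factorial(spec.M)
    if spec.kind == "rnom":
        return math.factorial(spec.M) // math.factorial(spec.M - spec.W)
    return math.comb(spec.M, spec.W)


def _check_depth(spec: SchemeSpec, I: int) -> None:
    if not 0 <= I <= spec.i_max:
        raise ValidationError(
            f"integration depth {I} out of range [0, {spec.i_max}] "
            f"for {spec.kind} with M={spec.M}, N={spec.N}"
        )


def potential(spec: SchemeSpec, p: SpikePattern, I: int) -> float | int:
    """Membrane potential after the first ``I`` spikes of pattern ``p``.

    Exact integer for NoM/R-NoM, float for ROC.  ``I = 0`` gives 0.
    """
    if p.M != spec.M:
        raise ValidationError(f"pattern has M={p.M}, scheme has M={spec.M}")
    _check_depth(spec, I)
    if I == 0:
        return 0 if spec.kind != "roc" else 0.0
    scores = score_transform(spec, weights_from_pattern(p))[:I]
    v = modulation_vector(spec)[:I]
    total = (v * scores).sum()
    return float(total) if spec.kind == "roc" else int(total)


def trajectory(spec: SchemeSpec, p: SpikePattern) -> np.ndarray:
    """Potential values ``S(1), …, S(I_max)``: the membrane trajectory.

    Non-decreasing for every pattern (all increments are ≥ 0) and maximal
    pointwise for the preferred pattern.
    """
    if p.M != spec.M:
        raise ValidationError(f"pattern has M={p.M}, scheme has M={spec.M}")
    scores = score_transform(spec, weights_from_pattern(p))[: spec.i_max]
    v = modulation_vector(spec)[: spec.i_max]
    out = np.cumsum(v * scores)
    return out.astype(float) if spec.kind == "roc" else out


#: Absolute guard when comparing float (ROC) potentials to thresholds, so
#: interval endpoints are not lost to round-off.
THRESHOLD_TOL = 1e-9


def crossing_latency(
    spec: SchemeSpec, p: SpikePattern, theta: float
) -> int | None:
    """Smallest depth ``I`` with ``S(I) ≥ θ``; ``None`` if never reached.

    Fire-at-threshold uses ≥ semantics with a small absolute tolerance for
    ROC floats.
    """
    if theta <= 0:
        raise ValidationError("threshold must be positive")
    traj = trajectory(spec, p)
    hit = np.nonzero(traj >= theta - THRESHOLD_TOL)[0]
    return int(hit[0]) + 1 if hit.size else None


def preferred_pattern(spec: SchemeSpec) -> SpikePattern:
    """The identity order ``(0, 1, …, M−1)`` — maximizes S at every depth."""
    return SpikePattern(tuple(range(spec.M)))


def reversed_pattern(spec: SchemeSpec) -> SpikePattern:
    """The reversed order — weakest weights arrive first."""
    return SpikePattern(tuple(range(spec.M - 1, -1, -1)))


def perturbed_pattern(
    spec: SchemeSpec, k_swaps: int, rng: np.random.Generator
) -> SpikePattern:
    """Preferred pattern after ``k_swaps`` uniformly random transpositions.

    A fixture for selectivity curves: the expected final potential decreases
    as the perturbation count grows.
    """
    if k_swaps < 0:
        raise ValidationError("k_swaps must be >= 0")
    order = np.arange(spec.M)
    for _ in range(k_swaps):
        i, j = rng.choice(spec.M, size=2, replace=False)
        order[i], order[j] = order[j], order[i]
    return SpikePattern(tuple(int(v) for v in order))


# ---------------------------------------------------------------------------
# Vectorized potentials for Monte-Carlo / exhaustive work.
# ---------------------------------------------------------------------------

def batch_potentials(
    spec: SchemeSpec, orders: np.ndarray, I: int | None = None
) -> np.ndarray:
    """Final (or depth-``I``) potentials for a batch of orders.

    ``orders`` is an ``(n, M)`` array of permutations (one per row); returns
    the length-``n`` potential vector.  Row validity is not re-checked —
    rows must come from the pattern samplers/enumerators.
    """
    if I is None:
        I = spec.i_max
    _check_depth(spec, I)
    if I == 0:
        return np.zeros(len(orders))
    orders = orders[:, :I].astype(np.int64)
    if spec.kind == "roc":
        scores = spec.M - orders
    elif spec.kind == "rnom":
        scores = np.maximum(0, spec.W - orders)
    else:
        scores = (orders < spec.W).astype(np.int64)
    v = modulation_vector(spec)[:I]
    return scores @ v
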