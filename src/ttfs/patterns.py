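"""The space of input spike orders.

Each of the ``M`` afferents of a readout neuron fires exactly one spike per
stimulus, so an input is fully described by the order in which the afferents
fire: a permutation of ``{0, …, M−1}``.  Entry ``i`` of a pattern is the
preferred-order index of the afferent that fires ``i``-th (0 = the afferent
that should fire first for a maximal response).

The full pattern space Λ holds ``M!`` orders, taken here as equiprobable.
This module represents patterns, ranks/unranks them against the ascending
lexicographic enumeration of Λ, samples them uniformly, and reads/writes a
plain-text ``.patterns`` file format.

Ranks into Λ are 1-based (``1 … M!``) and computed in exact integer
arithmetic via the factorial number system (Lehmer code), so arbitrarily
large ``M`` round-trips without overflow.  All sampling goes through
:class:`numpy.random.Generator` (PCG64 when created by
:func:`numpy.random.default_rng`); a single seed determines every draw.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GuardError, ValidationError

#: Default ceiling on M! for exhaustive enumeration (admits M ≤ 11).
ENUMERATION_GUARD = 40_000_000


@dataclass(frozen=True)
class SpikePattern:
    """An input spike order: a permutation of ``{0, …, M−1}``.

    ``order[i]`` is the preferred-order index of the afferent firing at
    arrival rank ``i+1`` (ranks are 1-based in formulas, 0-based in storage).
    """

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        m = len(self.order)
        if m < 1:
            raise ValidationError("a spike pattern needs at least one afferent")
        if sorted(self.order) != list(range(m)):
            raise ValidationError(
                f"order {self.order!r} is not a permutation of 0..{m - 1}"
            )

    @property
    def M(self) -> int:
        """Number of afferents."""
        return len(self.order)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.order, dtype=np.int64)


def lex_unrank(k: int, M: int) -> SpikePattern:
    """Return the ``k``-th permutation of ``{0, …, M−1}`` in lexicographic order.

    ``k`` runs over ``1 … M!``; the map is a bijection onto Λ. Uses the
    factorial number system, exact for any ``M``.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    total = math.factorial(M)
    if not 1 <= k <= total:
        raise ValidationError(
            f"rank {k} out of range: valid interval is [1, {total}] for M={M}"
        )
    residue = k - 1
    digits = []
    for radix in range(M, 0, -1):
        place = math.factorial(radix - 1)
        digits.append(residue // place)
        residue %= place
    pool = list(range(M))
    return SpikePattern(tuple(pool.pop(d) for d in digits))


def lex_rank(p: SpikePattern) -> int:
    """Inverse of :func:`lex_unrank`: 1-based lexicographic rank of ``p``."""
    order = list(p.order)
    m = p.M
    rank = 0
    pool = sorted(order)
    for i, value in enumerate(order):
        idx = pool.index(value)
        rank += idx * math.factorial(m - 1 - i)
        pool.pop(idx)
    return rank + 1


def sample_uniform(M: int, rng: np.random.Generator) -> SpikePattern:
    """Draw one pattern uniformly over all ``M!`` orders (Fisher–Yates)."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    return SpikePattern(tuple(int(v) for v in rng.permutation(M)))


def sample_uniform_many(M: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` uniform patterns as an ``(n, M)`` integer array.

    Vectorized counterpart of :func:`sample_uniform` for Monte-Carlo work;
    each row is an independent uniform permutation.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    if n < 0:
        raise ValidationError("n must be >= 0")
    base = np.tile(np.arange(M, dtype=np.int64), (n, 1))
    return rng.permuted(base, axis=1)


def enumerate_all(
    M: int, limit: int = ENUMERATION_GUARD
) -> Iterator[SpikePattern]:
    """Yield every pattern of Λ exactly once, in lexicographic order.

    Refuses when ``M! > limit`` — raise the limit explicitly to go bigger.
    """
    check_enumeration_guard(M, limit)
    for perm in itertools.permutations(range(M)):
        yield SpikePattern(perm)


def check_enumeration_guard(M: int, limit: int = ENUMERATION_GUARD) -> None:
    if M < 1:
        raise ValidationError("M must be >= 1")
    total = math.factorial(M)
    if total > limit:
        raise GuardError(
            f"enumeration of M={M} needs {total} patterns, above the guard "
            f"of {limit}; pass a larger limit to allow it"
        )


def enumerate_orders_array(
    M: int, limit: int = ENUMERATION_GUARD, batch: int = 500_000
) -> Iterator[np.ndarray]:
    """Stream Λ as ``(batch, M)`` integer arrays, lexicographic order.

    Batched so that 10! = 3 628 800 orders never materialize at once as
    Python tuples; intended for vectorized exhaustive statistics.
    """
    check_enumeration_guard(M, limit)
    it = itertools.permutations(range(M))
    while chunk := list(itertools.islice(it, batch)):
        yield np.array(chunk, dtype=np.int8 if M < 128 else np.int64)


# ---------------------------------------------------------------------------
# Plain-text ".patterns" file format: "#" comments, first payload line
# "M=<int>", then one comma-separated 0-based permutation per line.
# ---------------------------------------------------------------------------

def write_patterns(
    path: str | Path,
    patterns: Iterable[SpikePattern],
    M: int,
    header_comments: Sequence[str] = (),
) -> None:
    path = Path(path)
    try:
        with path.open("w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write(f"M={M}\n")
            for p in patterns:
                if p.M != M:
                    raise ValidationError(
                        f"pattern of size {p.M} in a file declared M={M}"
                    )
                fh.write(",".join(str(v) for v in p.order) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write pattern file {path}: {exc}") from exc


def read_patterns(path: str | Path) -> tuple[int, list[SpikePattern]]:
    """Read a ``.patterns`` file; every line is validated as a permutation."""
    path = Path(path)
    M: int | None = None
    out: list[SpikePattern] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read pattern file {path}: {exc}") from exc
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if M is None:
            if not line.startswith("M="):
                raise ValidationError(
                    f"{path}:{lineno}: first payload line must be 'M=<int>'"
                )
            M = int(line[2:])
            continue
        try:
            order = tuple(int(v) for v in line.split(","))
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad integer list") from exc
        if len(order) != M:
            raise ValidationError(
                f"{path}:{lineno}: expected {M} entries, got {len(order)}"
            )
        out.append(SpikePattern(order))
    if M is None:
        raise ValidationError(f"{path}: no 'M=<int>' line found")
    return M, out
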