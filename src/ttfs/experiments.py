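"""End-to-end experiment tables: discriminability scaling, propagation
curves, speed–accuracy trade-off, and fixture generation.

Each table function is a pure function of its configuration (plus a seed
where Monte Carlo is involved) and returns a :class:`pandas.DataFrame`.
:func:`write_table` persists any of them as CSV with a commented metadata
header (package version, configuration, n, seed) so a rerun with the same
config is bit-identical.

Default configurations:

- ``fig3_data`` — maximal discriminability versus population size ``M``,
  with ``N = W = M/2`` for NoM/R-NoM and the ROC asymptote at ``m``;
- ``fig4_data`` — discriminability during propagation at ``M = 31``,
  ``N = W = 15``, ``m = 0.8`` (the NoM/R-NoM ``W`` is exposed as a
  parameter: only ``N`` is pinned by the propagation cut-off);
- ``fig5_data`` — false alarm versus latency at ``M = 20``,
  ``N = W = 10`` for NoM/R-NoM, and ROC with ``M = 10``, ``m = 0.8`` — ten
  non-zero weights, so all three schemes propagate ten spikes.  The ROC
  population size is a reconstruction: its preferred five-spike potential
  (28.3616) and exhaustive false-alarm rate (≈0.1) match the worked
  operating point, which a 20-afferent ROC neuron cannot.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import discriminability, roc_asymptotic_discriminability
from .errors import ValidationError
from .patterns import SpikePattern, sample_uniform, write_patterns
from .schemes import (
    SchemeSpec,
    perturbed_pattern,
    preferred_pattern,
    reversed_pattern,
)
from .simulation import ExactPolicy, speed_accuracy_curve

#: Fig-5 reference configuration (see module docstring for the ROC choice).
FIG5_SCHEMES: dict[str, SchemeSpec] = {
    "rnom": SchemeSpec("rnom", M=20, N=10, W=10),
    "nom": SchemeSpec("nom", M=20, N=10, W=10),
    "roc": SchemeSpec("roc", M=10, m=0.8),
}


def fig3_data(
    M_grid: Sequence[int] = tuple(range(4, 65, 2)), m: float = 0.8
) -> pd.DataFrame:
    """Maximal discriminability versus ``M`` at ``N = W = M/2``.

    Columns: ``M, D_rnom, D_nom, D_roc_final, D_roc_asymptote``.  The
    NoM/R-NoM columns both equal ``√(M−1)``; the ROC column stays below its
    asymptote.
    """
    rows = []
    for M in M_grid:
        if M < 4 or M % 2:
            raise ValidationError(f"M grid must hold even values >= 4, got {M}")
        half = M // 2
        rows.append(
            {
                "M": M,
                "D_rnom": discriminability(SchemeSpec("rnom", M, half, half), half),
                "D_nom": discriminability(SchemeSpec("nom", M, half, half), half),
                "D_roc_final": discriminability(SchemeSpec("roc", M, m=m), M),
                "D_roc_asymptote": roc_asymptotic_discriminability(m),
            }
        )
    return pd.DataFrame(rows)


def fig4_data(
    M: int = 31, N: int = 15, W: int = 15, m: float = 0.8
) -> pd.DataFrame:
    """Discriminability as input spikes accumulate, ``I = 1 … M``.

    Columns: ``I, D_roc, D_nom, D_rnom``; the NoM/R-NoM columns hold their
    final value ``D(N)`` once propagation has stopped (``I > N``).
    """
    roc = SchemeSpec("roc", M, m=m)
    nom = SchemeSpec("nom", M, N, W)
    rnom = SchemeSpec("rnom", M, N, W)
    rows = [
        {
            "I": I,
            "D_roc": discriminability(roc, I),
            "D_nom": discriminability(nom, I),
            "D_rnom": discriminability(rnom, I),
        }
        for I in range(1, M + 1)
    ]
    return pd.DataFrame(rows)


def fig5_data(
    n: int = 200_000,
    seed: int = 0,
    schemes: Mapping[str, SchemeSpec] = FIG5_SCHEMES,
    exact: ExactPolicy = "auto",
) -> pd.DataFrame:
    """Speed–accuracy curves for the three reference schemes, long format.

    Columns: ``scheme, L, theta, p_mc, ci_low, ci_high, p_gauss, p_exact,
    n, seed``.  ``p_exact`` is the exact enumeration/closed-form value where
    feasible (NoM everywhere; ROC at ``M = 10``), else NaN.
    """
    frames = []
    for label, spec in schemes.items():
        pts = speed_accuracy_curve(spec, n=n, seed=seed, exact=exact)
        frames.append(
            pd.DataFrame(
                {
                    "scheme": label,
                    "L": [p.latency_pref for p in pts],
                    "theta": [p.theta for p in pts],
                    "p_mc": [p.fa.p_hat for p in pts],
                    "ci_low": [p.fa.ci_low for p in pts],
                    "ci_high": [p.fa.ci_high for p in pts],
                    "p_gauss": [p.fa.p_gauss for p in pts],
                    "p_exact": [
                        float(p.fa.p_exact) if p.fa.p_exact is not None else np.nan
                        for p in pts
                    ],
                    "n": n,
                    "seed": seed,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Persistence with embedded provenance.
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object]) -> None:
    """Write a CSV with '#'-commented metadata lines before the header.

    Always embeds the package version; floats round-trip at full precision.
    Read back with ``pandas.read_csv(path, comment='#')``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# ttfs {__version__}\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def spec_meta(spec: SchemeSpec) -> str:
    parts = [f"scheme={spec.kind}", f"M={spec.M}", f"N={spec.N}", f"W={spec.W}"]
    if spec.m is not None:
        parts.append(f"m={spec.m}")
    return " ".join(parts)


def load_config(path: str | Path) -> dict:
    """Load a flat YAML experiment configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def spec_from_config(cfg: Mapping[str, object]) -> SchemeSpec:
    """Build a SchemeSpec from config keys scheme/M/N/W/m.

    Omitted ``N``/``W`` default to ``M`` (the ROC convention); ``m`` is
    required iff the scheme is ROC.
    """
    kind = str(cfg.get("scheme", "")).lower()
    if "M" not in cfg:
        raise ValidationError("config needs key 'M'")
    M = int(cfg["M"])  # type: ignore[arg-type]
    N = int(cfg.get("N", M))  # type: ignore[arg-type]
    W = int(cfg.get("W", M))  # type: ignore[arg-type]
    m = cfg.get("m")
    if kind == "roc":
        return SchemeSpec("roc", M, m=float(m) if m is not None else None)
    return SchemeSpec(kind, M, N, W)  # type: ignore[arg-type]


def generate_fixtures(
    M: int,
    path: str | Path,
    n_uniform: int = 0,
    swap_counts: Sequence[int] = (),
    n_per_swap: int = 1,
    include_preferred: bool = True,
    include_reversed: bool = True,
    seed: int = 0,
) -> int:
    """Write a labelled ``.patterns`` fixture file; returns pattern count.

    Categories (preferred, reversed, k-swap perturbations of the preferred
    order, uniform random orders) are announced in comment lines, in this
    order; fully deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    spec = SchemeSpec("nom", M, N=M, W=M)  # only M matters for patterns
    patterns: list[SpikePattern] = []
    sections: list[str] = [f"seed={seed}"]
    if include_preferred:
        sections.append("category preferred: 1 pattern")
        patterns.append(preferred_pattern(spec))
    if include_reversed:
        sections.append("category reversed: 1 pattern")
        patterns.append(reversed_pattern(spec))
    for k in swap_counts:
        sections.append(f"category swap k={k}: {n_per_swap} patterns")
        for _ in range(n_per_swap):
            patterns.append(perturbed_pattern(spec, k, rng))
    if n_uniform:
        sections.append(f"category uniform: {n_uniform} patterns")
        for _ in range(n_uniform):
            patterns.append(sample_uniform(M, rng))
    write_patterns(path, patterns, M, header_comments=sections)
    return len(patterns)
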