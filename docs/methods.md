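# Methods

## Model

Each of `M` afferents fires exactly one spike per (static) stimulus; the
input is the firing order, a permutation of `{0, …, M−1}` drawn uniformly
from the `M!`-element space Λ. Patterns are stored 0-based; arrival ranks
are 1-based in every formula. A readout neuron fixes weights by preferred
order (`M` for the afferent that should fire first, down to 1), so the
spike arriving at rank `i` under pattern `p` carries weight
`w_i = M − p[i]`. Neurons are non-leaky, with no refractoriness and one
spike per afferent; continuous spike *times* never enter — only ranks.

Scheme `C` maps weights to scores `Φ_C(w)` and fixes a non-increasing
modulation vector `v`; the membrane potential after `I` spikes is the
gated inner product `S_C(I) = Σ_{i≤I} v_i Φ_C(w_i)`:

- **ROC**: `Φ` identity, `v_i = m^{i−1}`, `0 < m < 1`, `I` up to `M`.
- **NoM**: `Φ(w) = 1[w > M − W]`, `v_i = 1[i ≤ N]`, `I` up to `N`.
- **R-NoM**: `Φ(w) = max(0, w − M + W)`, `v_i = max(0, N − i + 1)`.

Two notational choices here are deliberate reconstructions of ambiguous
source notation, pinned by the closed-form maxima they must reproduce:
the R-NoM modulation runs `N…1` (not `W…1`) — only this choice yields
`max S = W·N(N+1)/2 + N(1−N²)/6` at `I = N` — and the ROC modulation has
`M` entries starting at `m⁰`, which is what the closed form
`((1−m)(1+M) − (1−m^{M+1}))/(1−m)²` expands to. Any `m ∈ (0, 1)` is
accepted (the geometric family is not restricted to `1/n`).

Preferred pattern = identity order; since scores and modulations are both
non-increasing there, the rearrangement inequality makes it the pointwise
maximizer of `S` at every depth, which is also how intermediate-depth
maxima are computed (`i`-th largest score × `i`-th largest modulation).

## Moments and discriminability

Scores at different ranks form a sample without replacement from a fixed
finite multiset, so they are exchangeable with
`Cov(W'_i, W'_j) = −Var(W'_i)/(M−1)`. With `λ = Σ_{i≤I} v_i`,
`α = Σ_{i≤I} v_i²`, `β = λ² − α`:

```
E[S_I] = λ·μ_W        Var[S_I] = α·Var_W + β·Cov_W
D(I)   = (max S_I − E[S_I]) / sqrt(Var[S_I])
```

The standard-deviation denominator makes `D` the usual signal-to-noise
ratio; it is confirmed by two independent anchors (`D = √(M−1)` at
`N = W = M/2`, and the ROC ceiling `√27 ≈ 5.196` at `m = 0.8`). For
NoM/R-NoM and `N < I ≤ M` the curve is held at `D(N)` (propagation has
stopped). Degenerate cases are surfaced, not silently patched: `Var = 0`
(e.g. NoM with `W = M`) raises, covariance is `None` at `M = 1`.

NoM/R-NoM quantities are evaluated in exact rational arithmetic
(`fractions.Fraction`); floats appear only in ROC's geometric sums and in
the final square root. Closed forms for NoM/R-NoM are stated for
`W ≥ N` and refuse other parameterizations, while direct summation of
potentials stays fully general.

## Exact oracles and simulation

Because all increments are non-negative, "the trajectory ever crosses θ"
is equivalent to "final potential ≥ θ"; false alarms are therefore upper
tails of the final potential. Three routes are implemented and
cross-checked:

1. **Exhaustive enumeration** of Λ (guarded at `M! ≤ 4·10⁷`, i.e.
   `M ≤ 11`; raising the guard is explicit). Probabilities are exact
   rationals. For NoM the final potential is `Hypergeometric(M, W, N)` —
   the count of the `N` earliest spikes landing on the `W` non-zero
   weights — so its exact tail needs no enumeration at any `M`.
2. **Monte Carlo**: `n` uniform orders via Fisher–Yates
   (`numpy.random.Generator.permuted`, PCG64); one 64-bit seed
   determines every draw and is echoed into all result records. The
   binomial proportion carries a Clopper–Pearson 95% interval (the
   standard asymmetric choice for small proportions; zero hits report a
   one-sided upper bound). Default `n = 2·10⁵`.
3. **Gaussian approximation**: normal upper tail with the closed-form
   mean and variance. Accurate in the bulk; in the far right tail at
   small `M` it misestimates (at the R-NoM operating point it gives
   4.3·10⁻⁴ against a Monte-Carlo ≈ 2.9·10⁻⁴).

Thresholds are compared with `≥` after an absolute guard of `10⁻⁹` for
ROC floats, so interval endpoints are not lost to round-off. The set of
thresholds firing the preferred pattern exactly at spike `L` is the
half-open interval `(S_pref(L−1), S_pref(L)]`; its upper endpoint
minimizes the false-alarm rate at that latency.

## Reference experiment configurations

- **Discriminability vs population size** (`fig3_data`): even `M ≥ 4`,
  `N = W = M/2`, ROC at `m = 0.8` with its asymptote.
- **Discriminability during propagation** (`fig4_data`): `M = 31`,
  `N = 15`, `m = 0.8`. The NoM/R-NoM `W` is not independently pinned by
  the reference setting; the default `W = N = 15` matches the
  speed–accuracy configuration and `W` is an explicit parameter rather
  than a constant.
- **Speed–accuracy** (`fig5_data`): R-NoM and NoM at `M = 20`,
  `N = W = 10`; ROC at `M = 10`, `m = 0.8`. The ROC population size is a
  reconstruction: its five-spike preferred potential is exactly
  `Σ_{i≤5} 0.8^{i−1}(10−i+1) = 28.3616` (printed 28.36) and its
  exhaustive false-alarm rate at that threshold is 0.0784 (printed 0.1 on
  a one-decimal scale), while a 20-afferent ROC readout reaches 61.98 by
  spike 5 and cannot produce either number. The choice also keeps ten
  propagated non-zero-weight spikes across all three schemes. Exact ROC
  false alarms come from one enumeration pass over all 10! orders shared
  across the ten thresholds; exact R-NoM values at `M = 20` are not
  computed (20! is far beyond enumeration) and the column is left empty.

## Synthetic data

The generator produces exactly the inputs the model assumes: uniform
random permutations, the preferred and reversed orders, and k-transposition
perturbations of the preferred order. It emulates nothing about real
stimuli — no rate variability, latency jitter, missing spikes, or
correlated afferents — so passing tests certify the combinatorial and
statistical machinery under the model's own assumptions, not performance
on recorded spike trains.

## Problem sizes and numerical checks

Exhaustive verification of the closed forms runs at `M ≤ 7` over every
scheme and depth (exact equality for the integer schemes, `10⁻¹²`-level
float agreement for ROC); Monte-Carlo calibration uses 100 seeded
replicates at `M = 6` against enumerated truth, requiring ≥ 93/100
coverage of the 95% intervals. The chi-square uniformity check of the
pattern sampler runs at `M = 4`, `n = 10⁵`, rejecting only below
`α = 10⁻³`. ROC's finite-`M` discriminability approaches its asymptote
at rate `O(1/M)` — about 2.5% short at `M = 200` and inside 1% by
`M = 1000` — so convergence assertions are made at `M = 1000`.

## Known limitations

- No learning rules, leak, refractoriness, or multi-spike afferents; no
  continuous-time modulation kernels.
- Non-uniform input-order distributions are not supported anywhere in the
  analytics (the uniformity assumption is load-bearing for the moments).
- Exact enumeration beyond `M = 11` is refused rather than approximated;
  no rare-event machinery beyond plain Monte Carlo is provided.
- The Gaussian tail is a diagnostic companion, not a calibrated
  approximation in the extreme tail.
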