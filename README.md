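# ttfs — rank-based time-to-first-spike coding schemes

In time-to-first-spike (TTFS) codes, each of `M` input neurons (afferents)
fires at most one spike per stimulus, and information is carried by the
*order* in which they fire rather than by firing rates or precise spike
times. A readout neuron with weights `M, M−1, …, 1` integrates each
incoming spike scaled by a rank-dependent *modulation* that makes early
spikes count more; its membrane potential after `I` spikes is

```
S(I) = Σ_{i=1..I} v_i · Φ(w_i)
```

where `w_i` is the weight of the `i`-th arriving spike, `Φ` is the
scheme's score transform, and `v` the modulation vector. The package
implements three schemes in one framework:

| scheme | propagated spikes | scores | modulation |
|--------|-------------------|--------|------------|
| ROC (rank-order coding) | all `M` | raw weights `M..1` | geometric, `m^(i−1)` |
| NoM (N-of-M) | first `N` (k-WTA gate) | binary, `W` ones | constant 1 up to `N` |
| R-NoM (ranked N-of-M) | first `N` | graded integers `W..1` | linear integers `N..1` |

With all `M!` input orders equiprobable, the per-rank scores are an
exchangeable sample drawn without replacement, which gives closed forms
for `E[S_I]`, `Var[S_I]` and hence the **discriminability**

```
D(I) = (max S_I − E[S_I]) / SD(S_I)
```

a signal-to-noise ratio measuring how much more the neuron responds to its
preferred order than to random input. Key results the library computes
(and verifies against exhaustive enumeration at small `M`):

- at `N = W = M/2`, NoM and R-NoM both saturate at `D = √(M−1)` —
  unbounded in `M`;
- ROC saturates at `√(3(1+m)/(1−m))` (≈ 5.2 for `m = 0.8`) no matter how
  many afferents are added;
- the NoM final potential is `Hypergeometric(M, W, N)`, giving exact
  false-alarm probabilities at any `M`;
- speed–accuracy trade-offs: each threshold θ pairs a preferred-pattern
  latency with a false-alarm probability `P(S_final ≥ θ)`, estimated by
  seeded Monte Carlo, by a Gaussian approximation, and exactly by
  enumeration where `M!` is tractable.

Intended users: computational neuroscientists and neuromorphic-hardware
designers comparing order-based spike codes before committing to an
implementation.

## Worked example

An R-NoM readout with `M = 20` afferents, `N = W = 10`:

```python
from ttfs import (SchemeSpec, preferred_pattern, trajectory,
                  threshold_interval_for_latency, discriminability,
                  mc_estimate_fa)

rnom = SchemeSpec("rnom", 20, 10, 10)
pref = preferred_pattern(rnom)

print(list(trajectory(rnom, pref)))
# [100, 181, 245, 294, 330, 355, 371, 380, 384, 385]

print(threshold_interval_for_latency(rnom, 5))
# (294.0, 330.0)

print(round(discriminability(rnom, 5), 4), round(discriminability(rnom, 10), 4))
# 3.9669 4.3589

est = mc_estimate_fa(rnom, theta=330, n=200_000, seed=42)
print(est.p_hat, est.hits)
# 0.000315 63
```

Reading: the preferred input order drives the potential to 330 by the
fifth spike, so any threshold in `(294, 330]` makes the neuron fire
exactly on spike 5; choosing 330 minimizes false alarms. The
discriminability is already 3.97 after five spikes (final value
`√19 ≈ 4.36`), and a 200 000-sample Monte Carlo run puts the false-alarm
probability at threshold 330 near 3·10⁻⁴ — three orders of magnitude
below the equal-latency NoM operating point (exact hypergeometric value
0.672), and well below ROC's ≈ 0.08 at its matching threshold 28.36.

The same analyses are available from the shell:

```
ttfs analytic --scheme rnom -M 20 -N 10 -W 10 --I all --format csv
ttfs simulate fa --scheme rnom -M 20 -N 10 -W 10 --theta 330 -n 200000 --seed 42 --json
ttfs figure fig3 --out results/   # discriminability vs M
ttfs figure fig5 --out results/ --seed 1 -n 200000   # speed-accuracy curves
ttfs oracle verify --max-M 7      # closed forms vs exhaustive enumeration
ttfs fixtures -M 20 --out demo.patterns --uniform 1000 --swaps 1,2,4 --seed 0
```

Exit codes: 0 success, 2 validation error, 3 enumeration-guard refusal.

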