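"""Closed-form moments, discriminability, and asymptotics."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttfs import (
    SchemeSpec,
    SpikePattern,
    ValidationError,
    discriminability,
    integration_coefficients,
    max_potential,
    max_potential_final_closed_form,
    mean_potential,
    moment_set,
    potential,
    rnom_nom_max_discriminability,
    roc_asymptotic_discriminability,
    score_moments,
    var_potential,
)


def brute_force_score_moments(spec):
    """Independent oracle: exact per-rank score moments by enumerating Λ."""
    from ttfs import enumerate_all, score_transform, weights_from_pattern

    total = math.factorial(spec.M)
    first, first_sq, cross = Fraction(0), Fraction(0), Fraction(0)
    for p in enumerate_all(spec.M):
        s = score_transform(spec, weights_from_pattern(p))
        first += int(s[0])
        first_sq += int(s[0]) ** 2
        cross += int(s[0]) * int(s[1])
    mu = first / total
    var = first_sq / total - mu**2
    cov = cross / total - mu**2
    return mu, var, cov


class TestScoreMoments:
    def test_rnom_reference_values(self, rnom20):
        mu, var, cov = score_moments(rnom20)
        assert mu == Fraction(11, 4)
        assert var == Fraction(187, 16)
        assert cov == -var / 19
        assert float(cov) == pytest.approx(-0.6151315789473685, rel=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [
            SchemeSpec("roc", 4, m=0.5),
            SchemeSpec("rnom", 5, 2, 3),
            SchemeSpec("nom", 5, 2, 3),
            SchemeSpec("rnom", 4, 2, 2),
        ],
    )
    def test_matches_enumeration_oracle(self, spec):
        mu, var, cov = score_moments(spec)
        omu, ovar, ocov = brute_force_score_moments(spec)
        assert (mu, var, cov) == (omu, ovar, ocov)

    def test_roc_m4_closed_values(self):
        mu, var, cov = score_moments(SchemeSpec("roc", 4, m=0.5))
        assert (mu, var, cov) == (Fraction(5, 2), Fraction(5, 4), Fraction(-5, 12))

    def test_degenerate_nom_w_equals_m(self):
        mu, var, cov = score_moments(SchemeSpec("nom", 6, 6, 6))
        assert (mu, var, cov) == (1, 0, 0)

    def test_m1_covariance_undefined(self):
        assert score_moments(SchemeSpec("roc", 1, m=0.5))[2] is None

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(2, 40), st.sampled_from(["roc", "nom", "rnom"]),
           st.integers(0, 2**31 - 1))
    def test_finite_population_covariance_identity(self, M, kind, seed):
        """Sampling without replacement forces Cov = -Var/(M-1)."""
        rng = np.random.default_rng(seed)
        if kind == "roc":
            spec = SchemeSpec("roc", M, m=float(rng.uniform(0.1, 0.95)))
        else:
            W = int(rng.integers(1, M + 1))
            spec = SchemeSpec(kind, M, min(W, M), W)
        _, var, cov = score_moments(spec)
        assert cov == -var / (M - 1)


class TestIntegrationCoefficients:
    def test_rnom_direct_sums(self):
        # lambda/alpha are Σ v_i and Σ v_i^2 with v_i = N-i+1 over i<=I
        spec = SchemeSpec("rnom", 20, 10, 10)
        lam, alpha, beta = integration_coefficients(spec, 5)
        v = [10 - i for i in range(5)]
        assert lam == sum(v) == 40
        assert alpha == sum(x * x for x in v) == 330
        assert beta == lam**2 - alpha == 1270

    def test_nom_depth_one(self):
        assert integration_coefficients(SchemeSpec("nom", 8, 4, 4), 1) == (1, 1, 0)

    def test_roc_geometric_partial_sums(self):
        lam, alpha, beta = integration_coefficients(SchemeSpec("roc", 8, m=0.8), 2)
        assert lam == pytest.approx(1.8, rel=1e-12)
        assert alpha == pytest.approx(1 + 0.8**2, rel=1e-12)
        assert beta == pytest.approx(1.8**2 - 1.64, rel=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(2, 25), st.sampled_from(["roc", "nom", "rnom"]),
           st.integers(0, 2**31 - 1))
    def test_beta_identity_and_gated_sums(self, M, kind, seed):
        """beta = lambda^2 - alpha, and lambda/alpha equal the direct gated
        modulation sums, for random specs and depths."""
        from ttfs import modulation_vector

        rng = np.random.default_rng(seed)
        if kind == "roc":
            spec = SchemeSpec("roc", M, m=float(rng.uniform(0.1, 0.95)))
        else:
            N = int(rng.integers(1, M + 1))
            spec = SchemeSpec(kind, M, N, int(rng.integers(N, M + 1)))
        I = int(rng.integers(1, spec.i_max + 1))
        lam, alpha, beta = integration_coefficients(spec, I)
        v = modulation_vector(spec)[:I].astype(float)
        assert float(lam) == pytest.approx(v.sum(), rel=1e-10)
        assert float(alpha) == pytest.approx((v**2).sum(), rel=1e-10)
        assert float(beta) == pytest.approx(float(lam) ** 2 - float(alpha), abs=1e-8)

    def test_rnom_requires_w_ge_n(self):
        with pytest.raises(ValidationError, match="W >= N"):
            integration_coefficients(SchemeSpec("rnom", 8, 5, 3), 2)

    def test_but_potential_allows_w_lt_n(self):
        spec = SchemeSpec("rnom", 8, 5, 3)
        pref = SpikePattern(tuple(range(8)))
        assert potential(spec, pref, 5) == 5 * 3 + 4 * 2 + 3 * 1


class TestMaxPotential:
    def test_rnom_final_both_forms(self, rnom20):
        direct = max_potential(rnom20, 10)
        closed = max_potential_final_closed_form(rnom20)
        assert direct == closed == 385

    def test_nom_final_is_n(self):
        spec = SchemeSpec("nom", 12, 5, 7)
        assert max_potential(spec, 5) == 5
        assert max_potential_final_closed_form(spec) == 5

    def test_roc_closed_form_equals_sum(self):
        spec = SchemeSpec("roc", 10, m=0.8)
        assert max_potential(spec, 10) == pytest.approx(
            max_potential_final_closed_form(spec), rel=1e-12
        )

    def test_attained_by_preferred_pattern(self, rnom20):
        from ttfs import preferred_pattern

        pref = preferred_pattern(rnom20)
        for I in range(11):
            assert potential(rnom20, pref, I) == max_potential(rnom20, I)


class TestPotentialMoments:
    def test_rnom_reference(self, rnom20):
        assert mean_potential(rnom20, 10) == Fraction(605, 4)  # 151.25
        assert float(var_potential(rnom20, 10)) == pytest.approx(
            2875.7401315789475, rel=1e-12
        )

    def test_nom_reference(self, nom20):
        assert mean_potential(nom20, 10) == 5
        assert var_potential(nom20, 10) == Fraction(25, 19)
        assert float(var_potential(nom20, 10)) == pytest.approx(1.3157894736, rel=1e-9)

    def test_depth_zero_degenerate(self, rnom20):
        assert mean_potential(rnom20, 0) == 0
        assert var_potential(rnom20, 0) == 0

    def test_monte_carlo_agreement_m20(self, rng, rnom20):
        from ttfs import batch_potentials, sample_uniform_many

        n = 200_000
        pots = batch_potentials(rnom20, sample_uniform_many(20, n, rng))
        se_mean = math.sqrt(float(var_potential(rnom20, 10)) / n)
        assert pots.mean() == pytest.approx(151.25, abs=3 * se_mean)
        assert pots.var() == pytest.approx(2875.74, rel=0.05)


class TestDiscriminability:
    def test_reference_sqrt19(self, rnom20, nom20):
        assert discriminability(rnom20, 10) == pytest.approx(math.sqrt(19), rel=1e-12)
        assert discriminability(nom20, 10) == pytest.approx(math.sqrt(19), rel=1e-12)

    def test_small_instance_sqrt3_via_enumeration(self):
        """M=4, N=W=2: exhaustive distribution over 24 orders gives the
        same D as the closed-form pipeline, equal to sqrt(3)."""
        spec = SchemeSpec("rnom", 4, 2, 2)
        pots = [float(potential(spec, p, 2)) for p in
                (SpikePattern(q) for q in itertools.permutations(range(4)))]
        arr = np.array(pots)
        d_oracle = (arr.max() - arr.mean()) / arr.std()
        assert discriminability(spec, 2) == pytest.approx(d_oracle, rel=1e-12)
        assert d_oracle == pytest.approx(math.sqrt(3), rel=1e-12)

    def test_held_flat_past_cutoff(self, rnom20):
        assert discriminability(rnom20, 15) == discriminability(rnom20, 10)

    def test_zero_variance_reported(self):
        with pytest.raises(ValidationError, match="undefined"):
            discriminability(SchemeSpec("nom", 6, 6, 6), 6)

    def test_rnom_nom_scaling_law(self):
        assert rnom_nom_max_discriminability(20) == pytest.approx(math.sqrt(19))
        values = [rnom_nom_max_discriminability(M) for M in range(4, 41, 2)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_odd_m_rejected_with_suggestion(self):
        with pytest.raises(ValidationError, match="even"):
            rnom_nom_max_discriminability(21)

    def test_roc_asymptote(self):
        assert roc_asymptotic_discriminability(0.8) == pytest.approx(
            math.sqrt(27), rel=1e-12
        )
        assert roc_asymptotic_discriminability(1e-9) == pytest.approx(
            math.sqrt(3), rel=1e-6
        )
        with pytest.raises(ValidationError):
            roc_asymptotic_discriminability(1.2)

    def test_roc_finite_m_below_and_near_asymptote(self):
        # Convergence is O(1/M): ~2.5% short at M=200, inside 1% by M=1000.
        asym = roc_asymptotic_discriminability(0.8)
        d200 = discriminability(SchemeSpec("roc", 200, m=0.8), 200)
        d1000 = discriminability(SchemeSpec("roc", 1000, m=0.8), 1000)
        assert d200 < d1000 < asym
        assert d1000 > 0.99 * asym

    def test_moment_set_is_consistent(self, rnom20):
        ms = moment_set(rnom20, 5)
        assert ms.beta == ms.lam**2 - ms.alpha
        assert ms.cov_W == -ms.var_W / 19
        assert ms.max_S >= ms.mean_S
        assert ms.var_S > 0
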