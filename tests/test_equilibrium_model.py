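import itertools
import math

import numpy as np
import pytest

from hbshape import equilibrium_model as eq
from hbshape.equilibrium_model import GRFPolynomial, HOCParams


def brute_force_grf(params: HOCParams, x: float) -> float:
    """Independent oracle: explicit sum over all 2^(n+1) microstates."""
    total = 0.0
    bound = 0.0
    for subset, pol in eq.enumerate_microstates(params.n_sites):
        w = x ** len(subset)
        for i in subset:
            w *= params.K[i - 1]
        for r in range(2, len(subset) + 1):
            for s in itertools.combinations(subset, r):
                w *= params.omega.get(frozenset(s), 1.0)
        if pol:
            w *= params.q
            for r in range(1, len(subset) + 1):
                for s in itertools.combinations(subset, r):
                    w *= params.gamma.get(frozenset(s), 1.0)
            bound += w
        total += w
    return bound / total


class TestMicrostates:
    @pytest.mark.parametrize("n,count", [(1, 4), (2, 8), (6, 128)])
    def test_counts(self, n, count):
        assert len(eq.enumerate_microstates(n)) == count

    def test_full_polbound_state_unique(self):
        states = eq.enumerate_microstates(2)
        assert states.count(((1, 2), 1)) == 1

    @pytest.mark.parametrize("n", [0, 13])
    def test_out_of_range_rejected(self, n):
        with pytest.raises(ValueError):
            eq.enumerate_microstates(n)


class TestGrfPolynomial:
    def test_one_site_hand_enumeration(self):
        # K=1, q=1, gamma({1})=9: numer = 1 + 9x, denom = 2 + 10x
        poly = eq.build_grf_polynomial(
            HOCParams(n_sites=1, K=(1.0,), q=1.0, gamma={frozenset({1}): 9.0})
        )
        np.testing.assert_allclose(poly.numer, [1.0, 9.0])
        np.testing.assert_allclose(poly.denom, [2.0, 10.0])
        assert poly.f0 == pytest.approx(0.5)
        assert poly.finf == pytest.approx(0.9)

    def test_trivial_cooperativities_are_unresponsive(self):
        poly = eq.build_grf_polynomial(HOCParams(n_sites=3, K=(1.0, 2.0, 0.5), q=2.0))
        # without any HOC, Pol binding is independent of TF occupancy
        assert poly.finf == pytest.approx(poly.f0, abs=1e-12)
        assert not eq.is_responsive(poly)
        with pytest.raises(ValueError, match="non-activating"):
            eq.normalized_grf(poly, np.array([1.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_two_site_matches_brute_force(self, seed):
        params = eq.sample_hoc(2, "full", rng_seed=seed)
        poly = eq.build_grf_polynomial(params)
        rng = np.random.default_rng(seed + 100)
        for x in 10.0 ** rng.uniform(-4, 4, size=20):
            assert poly(np.array([x]))[0] == pytest.approx(
                brute_force_grf(params, x), rel=1e-12
            )

    def test_numer_never_exceeds_denom(self):
        # f < 1 strictly; float saturation can round f up to exactly 1
        for seed in range(20):
            poly = eq.build_grf_polynomial(eq.sample_hoc(6, "full", rng_seed=seed))
            assert np.all(poly.log_numer <= poly.log_denom)
            x = np.logspace(-6, 6, 50)
            assert np.all(poly(x) <= 1.0)

    def test_invalid_polynomial_rejected(self):
        with pytest.raises(ValueError, match="numer"):
            GRFPolynomial(
                log_numer=np.array([0.0, 1.0]), log_denom=np.array([0.5, 0.5]), n_sites=1
            )


class TestNormalizedGrf:
    def test_endpoints_map_to_zero_and_one(self):
        poly = eq.build_grf_polynomial(
            HOCParams(n_sites=1, K=(1.0,), q=1.0, gamma={frozenset({1}): 9.0})
        )
        F = eq.normalized_grf(poly, np.array([1e-12, 1e12]))
        assert F[0] == pytest.approx(0.0, abs=1e-9)
        assert F[1] == pytest.approx(1.0, abs=1e-9)

    def test_affine_map_halfway(self):
        poly = eq.build_grf_polynomial(
            HOCParams(n_sites=1, K=(1.0,), q=1.0, gamma={frozenset({1}): 9.0})
        )
        # f = 0.7 is halfway between f0 = 0.5 and finf = 0.9;
        # solving (1+9x)/(2+10x) = 0.7 gives x = 0.2
        x = (0.7 * 2 - 1) / (9 - 0.7 * 10)
        assert eq.normalized_grf(poly, np.array([x]))[0] == pytest.approx(0.5, rel=1e-9)

    def test_monotone_draw_stays_in_unit_interval(self):
        rng = np.random.default_rng(8)
        found = 0
        while found < 5:
            logn, logd = eq.sample_log_coefficients(4, "full", 64, rng)
            res = eq.batch_shapes(logn, logd)
            for i in np.flatnonzero(res["responsive"] & res["monotone"]):
                poly = GRFPolynomial(logn[i], logd[i], 4)
                F = eq.normalized_grf(poly, np.logspace(-9, 9, 200))
                assert np.all(F > -1e-9) and np.all(F < 1 + 1e-9)
                found += 1

    def test_nonmonotone_draws_can_overshoot(self):
        rng = np.random.default_rng(9)
        overshoot = False
        for _ in range(20):
            logn, logd = eq.sample_log_coefficients(6, "full", 256, rng)
            res = eq.batch_shapes(logn, logd)
            for i in np.flatnonzero(res["responsive"] & ~res["monotone"]):
                poly = GRFPolynomial(logn[i], logd[i], 6)
                F = eq.normalized_grf(poly, np.logspace(-9, 9, 400))
                if F.max() > 1 + 1e-6 or F.min() < -1e-6:
                    overshoot = True
                    break
            if overshoot:
                break
        assert overshoot


class TestModelShape:
    def test_one_site_is_hyperbolic_point(self):
        for seed in range(5):
            params = eq.sample_hoc(1, "full", rng_seed=seed)
            poly = eq.build_grf_polynomial(params)
            if not eq.is_responsive(poly):
                continue
            with pytest.warns(RuntimeWarning, match="grid"):
                sp = eq.model_shape(poly)
            assert sp.P == pytest.approx(0.0, abs=1e-5)
            assert sp.S == pytest.approx(1.0, abs=1e-4)

    def test_all_or_none_limit_approaches_hill_point(self):
        from hbshape.region_analysis import hill_shape

        # overwhelming full-subset cooperativity makes occupancy all-or-none
        n = 6
        params = HOCParams(
            n_sites=n,
            K=tuple([1.0] * n),
            q=1.0,
            omega={frozenset(range(1, n + 1)): 1e12},
            gamma={frozenset(range(1, n + 1)): 1e12},
        )
        sp = eq.model_shape(eq.build_grf_polynomial(params))
        hill = hill_shape(n)
        assert sp.P == pytest.approx(hill.P, rel=1e-3)
        assert sp.S == pytest.approx(hill.S, rel=1e-3)

    def test_unresponsive_rejected(self):
        poly = eq.build_grf_polynomial(HOCParams(n_sites=2, K=(1.0, 1.0), q=1.0))
        with pytest.raises(ValueError):
            eq.model_shape(poly)


class TestSampleHoc:
    def test_values_within_range(self):
        p = eq.sample_hoc(4, "full", rng_seed=0)
        values = list(p.K) + [p.q] + list(p.omega.values()) + list(p.gamma.values())
        assert all(1e-3 <= v <= 1e3 for v in values)

    @pytest.mark.parametrize(
        "mode,expected",
        [("full", 127), ("pairwise_tf_tf", 6 + 1 + 15 + 6), ("pairwise_tf_pol", 13)],
    )
    def test_free_parameter_counts(self, mode, expected):
        assert eq.n_free_parameters(6, mode) == expected
        p = eq.sample_hoc(6, mode, rng_seed=1)
        n_free = (
            len(p.K)
            + 1
            + sum(v != 1.0 for v in p.omega.values())
            + sum(v != 1.0 for v in p.gamma.values())
        )
        # sampled values are continuous, so equality with 1 has measure zero
        assert n_free == expected

    def test_pairwise_modes_respect_constraints(self):
        p = eq.sample_hoc(5, "pairwise_tf_tf", rng_seed=3)
        assert all(len(s) == 2 for s, v in p.omega.items() if v != 1.0)
        assert all(len(s) == 1 for s, v in p.gamma.items() if v != 1.0)
        p = eq.sample_hoc(5, "pairwise_tf_pol", rng_seed=3)
        assert not any(v != 1.0 for v in p.omega.values())

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            eq.sample_hoc(3, "full", rng_seed=0, exponent_range=(3.0, -3.0))

    def test_json_round_trip(self):
        p = eq.sample_hoc(3, "full", rng_seed=5)
        q = HOCParams.from_json(p.to_json())
        assert q == p

    def test_batch_matches_scalar_distribution(self):
        """The vectorized sampler spans the same coefficient law as
        build_grf_polynomial over sample_hoc draws (moment check)."""
        rng = np.random.default_rng(11)
        logn, logd = eq.sample_log_coefficients(3, "full", 4000, rng)
        scal = np.array(
            [
                eq.build_grf_polynomial(eq.sample_hoc(3, "full", rng_seed=s)).log_denom
                for s in range(400)
            ]
        )
        assert np.allclose(
            logd.mean(axis=0), scal.mean(axis=0), atol=4 * scal.std(0).max() / math.sqrt(400)
        )
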