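import numpy as np
import pytest

from hbshape import region_analysis as ra
from hbshape import shape_metrics as sm
from hbshape.shape_metrics import KDEModel, RawShape, ShapeDistribution, ShapePoint
from hbshape.trace_processing import GRFSamples


def hill_grf(nh, ka=1.0, n=4000, decades=6, embryo_id="h"):
    bcd = ka * np.logspace(-decades / 2, decades / 2, n)
    expr = bcd**nh / (ka**nh + bcd**nh)
    return GRFSamples(embryo_id, bcd, expr)


class TestAverageGrf:
    def test_identical_embryos_average_to_either(self):
        g = hill_grf(4.0)
        avg = sm.average_grf([g, g])
        np.testing.assert_allclose(avg.expr, g.expr)

    def test_binwise_mean(self):
        bcd = np.logspace(-1, 0, 10)
        a = GRFSamples("a", bcd, np.ones(10))
        b = GRFSamples("b", bcd, np.full(10, 3.0))
        np.testing.assert_allclose(sm.average_grf([a, b]).expr, 2.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sm.average_grf([hill_grf(2.0)], subset=[])


class TestBcd05:
    def test_exact_hill_returns_ka(self):
        assert sm.compute_bcd05(hill_grf(4.0, ka=0.1)) == pytest.approx(0.1, abs=1e-3)

    def test_linear_table(self):
        g = GRFSamples("e", np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert sm.compute_bcd05(g) == pytest.approx(0.5)

    def test_all_zero_rejected(self):
        g = GRFSamples("e", np.array([0.0, 1.0]), np.zeros(2))
        with pytest.raises(ValueError):
            sm.compute_bcd05(g)


class TestRawShape:
    def test_hill2_closed_form(self):
        # x* = ((n-1)/(n+1))^(1/n), S* = x*^(n-1) (n+1)^2/(4n) for Ka = 1;
        # clean dense samples, so the noise spacing floor is disabled
        raw = sm.raw_shape(hill_grf(2.0), min_log_spacing=0)
        assert raw.rP == pytest.approx(1.0 / np.sqrt(3.0), rel=2e-3)
        assert raw.rS == pytest.approx(0.6495, rel=2e-3)

    def test_linear_grf_tie_breaks_to_smallest_bcd(self):
        bcd = np.linspace(0.0, 1.0, 11)
        g = GRFSamples("e", bcd, bcd.copy())
        raw = sm.raw_shape(g)
        assert raw.rP == pytest.approx(0.0)
        assert raw.rS == pytest.approx(1.0)

    def test_hyperbolic_limit_max_at_low_end(self):
        raw = sm.raw_shape(hill_grf(1.0, n=2000), min_log_spacing=0)
        assert raw.rP == pytest.approx(hill_grf(1.0, n=2000).bcd.min())

    def test_too_few_points_rejected(self):
        g = GRFSamples("e", np.array([0.1, 0.2]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            sm.raw_shape(g)


class TestNormalizeShape:
    def test_arithmetic(self):
        p = sm.normalize_shape(RawShape(rP=0.05, rS=60.0, bcd05=0.072))
        assert p.P == pytest.approx(0.694, abs=1e-3)
        assert p.S == pytest.approx(4.32, abs=1e-2)

    @pytest.mark.parametrize("ka", [0.01, 1.0, 3.0])
    def test_hill_shape_invariant_to_ka(self, ka):
        ref = sm.shape_of(hill_grf(3.0, ka=1.0))
        other = sm.shape_of(hill_grf(3.0, ka=ka))
        assert other.P == pytest.approx(ref.P, rel=1e-6)
        assert other.S == pytest.approx(ref.S, rel=1e-6)

    def test_emax_invariance(self):
        g = hill_grf(3.0)
        scaled = GRFSamples("e", g.bcd, 7.5 * g.expr)
        ref, got = sm.shape_of(g), sm.shape_of(scaled)
        assert got.P == pytest.approx(ref.P) and got.S == pytest.approx(ref.S)

    def test_zero_bcd05_rejected(self):
        with pytest.raises(ValueError):
            sm.normalize_shape(RawShape(rP=0.1, rS=1.0, bcd05=0.0))

    def test_noiseless_hill_cohort_on_hill_line(self, noiseless_grfs, noiseless_cohort):
        # the 100-bin AP grid spaces Bcd samples ~0.022 decades apart, which
        # quantizes the central-difference argmax; tolerance reflects that
        point = sm.shape_of(sm.average_grf(noiseless_grfs))
        expected = ra.hill_shape(noiseless_cohort.truth["nh"])
        assert point.P == pytest.approx(expected.P, abs=0.02)
        assert point.S == pytest.approx(expected.S, rel=0.02)


class TestSubsampleShapes:
    def test_identical_embryos_give_identical_points(self):
        g = hill_grf(4.0, n=500)
        dist = sm.subsample_shapes([g, g, g, g], n_subsamples=20, seed=0)
        xy = dist.as_array()
        assert np.allclose(xy, xy[0])

    def test_count_and_determinism(self, wt_grfs):
        a = sm.subsample_shapes(wt_grfs, n_subsamples=100, seed=5)
        b = sm.subsample_shapes(wt_grfs, n_subsamples=100, seed=5)
        assert a.n_subsamples == 100
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_single_embryo_rejected(self):
        with pytest.raises(ValueError):
            sm.subsample_shapes([hill_grf(2.0)], seed=0)


class TestKde:
    def test_silverman_bandwidth_2d(self):
        rng = np.random.default_rng(0)
        pts = ShapeDistribution(
            points=[
                ShapePoint(P=p, S=s)
                for p, s in zip(0.02 * rng.standard_normal(100) + 0.9,
                                0.05 * rng.standard_normal(100) + 1.3)
            ]
        )
        kde = sm.fit_kde(pts)
        sigma = pts.as_array().std(axis=0, ddof=1)
        np.testing.assert_allclose(kde.bandwidth, sigma * 100 ** (-1 / 6))

    def test_bandwidth_scale_equivariance(self):
        rng = np.random.default_rng(1)
        xy = rng.random((50, 2))
        d1 = ShapeDistribution(points=[ShapePoint(*p) for p in xy])
        d2 = ShapeDistribution(points=[ShapePoint(*(2 * p)) for p in xy])
        np.testing.assert_allclose(sm.fit_kde(d2).bandwidth, 2 * sm.fit_kde(d1).bandwidth)

    def test_degenerate_distribution_rejected(self):
        d = ShapeDistribution(points=[ShapePoint(0.5, 1.0)] * 10)
        with pytest.raises(ValueError, match="identical"):
            sm.fit_kde(d)


def square_region(p_lo, p_hi, s_lo, s_hi, n_bins=20):
    edges = np.linspace(p_lo, p_hi, n_bins + 1)
    return ra.RegionBoundary(
        n_sites=6,
        mode="full",
        position_bins=edges,
        s_upper=np.full(n_bins, s_hi),
        s_lower=np.full(n_bins, s_lo),
        n_samples=1,
        seed=0,
    )


class TestPInsideRegion:
    def _kde_at(self, center, spread=0.005, n=50, seed=0):
        rng = np.random.default_rng(seed)
        xy = center + spread * rng.standard_normal((n, 2))
        return sm.fit_kde(ShapeDistribution(points=[ShapePoint(*p) for p in xy]))

    def test_mass_deep_inside_gives_one(self):
        kde = self._kde_at(np.array([0.5, 1.0]))
        p, se = sm.p_inside_region(kde, square_region(0, 1, 0, 2), 20000, seed=1)
        assert p > 0.999

    def test_mass_far_outside_gives_zero(self):
        kde = self._kde_at(np.array([5.0, 10.0]))
        p, se = sm.p_inside_region(kde, square_region(0, 1, 0, 2), 20000, seed=1)
        assert p < 0.001

    def test_straddling_symmetric_boundary_gives_half(self):
        # mixture mirrored across the region's upper steepness edge: exactly
        # half the KDE mass lies inside
        rng = np.random.default_rng(3)
        half = np.column_stack(
            [0.5 + 0.005 * rng.standard_normal(100), 2.0 + 0.01 * rng.random(100)]
        )
        mirrored = half.copy()
        mirrored[:, 1] = 4.0 - half[:, 1]
        xy = np.vstack([half, mirrored])
        kde = sm.fit_kde(ShapeDistribution(points=[ShapePoint(*p) for p in xy]))
        p, se = sm.p_inside_region(kde, square_region(0, 1, 0, 2), 100_000, seed=2)
        assert abs(p - 0.5) < 3 * se

    def test_monotone_in_depth(self):
        region = square_region(0, 1, 0, 2)
        kde = self._kde_at(np.array([0.5, 2.05]), spread=0.02)
        ps = []
        for shift in (0.0, 0.1, 0.2, 0.4):
            shifted = KDEModel(kde.centers - [0, shift], kde.bandwidth)
            ps.append(sm.p_inside_region(shifted, region, 30000, seed=4)[0])
        assert all(b >= a - 1e-9 for a, b in zip(ps, ps[1:]))
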