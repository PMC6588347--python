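"""Normalized position and steepness of a GRF, with subsample-KDE p-values.

A GRF's shape is reduced to two dimensionless coordinates. On an averaged
GRF (expression vs Bcd):

1. Bcd05 — the Bcd concentration at half-maximal expression;
2. the maximal derivative of the max-normalized GRF (raw steepness rS) and
   the Bcd concentration where it occurs (raw position rP);
3. normalization: P = rP / Bcd05, S = rS * Bcd05.

Both coordinates are invariant to rescaling either axis, so they measure
intrinsic shape. Sampling variability is quantified by averaging GRFs over
random half-cohorts (100 subsamples by default), fitting a 2-D Gaussian KDE
(Silverman bandwidth) to the resulting (P, S) cloud, and reporting the
proportion of KDE mass that falls inside a model-achievable region as a
p-value for compatibility with that model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hbshape.trace_processing import GRFSamples


@dataclass(frozen=True)
class RawShape:
    """Raw (unnormalized) shape of an averaged GRF."""

    rP: float
    rS: float
    bcd05: float


@dataclass(frozen=True)
class ShapePoint:
    """Normalized position P = rP/Bcd05 and steepness S = rS*Bcd05."""

    P: float
    S: float


@dataclass(frozen=True)
class ShapeDistribution:
    points: list
    condition: str = ""
    subsample_fraction: float = 0.5

    @property
    def n_subsamples(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.array([[p.P, p.S] for p in self.points])


@dataclass(frozen=True)
class KDEModel:
    """Product-Gaussian kernel density over (P, S) shape points."""

    centers: np.ndarray
    bandwidth: np.ndarray

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, len(self.centers), size=n)
        return self.centers[idx] + rng.normal(0.0, 1.0, size=(n, 2)) * self.bandwidth


def average_grf(cohort: Sequence[GRFSamples], subset: Sequence[int] | None = None) -> GRFSamples:
    """Bin-wise mean expression over a subset of embryos sharing a Bcd grid."""
    if subset is None:
        subset = range(len(cohort))
    chosen = [cohort[i] for i in subset]
    if not chosen:
        raise ValueError("cannot average an empty subset of embryos")
    bcd = chosen[0].bcd
    for g in chosen[1:]:
        if not np.array_equal(g.bcd, bcd):
            raise ValueError("embryos do not share a common Bcd grid")
    expr = np.mean([g.expr for g in chosen], axis=0)
    return GRFSamples("average", bcd, expr)


def _sorted_by_bcd(grf: GRFSamples) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(grf.bcd, kind="stable")
    return grf.bcd[order], grf.expr[order]


def compute_bcd05(grf: GRFSamples) -> float:
    """Smallest Bcd at which the linearly interpolated, Bcd-sorted expression
    crosses half of its maximum."""
    bcd, expr = _sorted_by_bcd(grf)
    emax = expr.max()
    if emax <= 0:
        raise ValueError("expression is non-positive everywhere; Bcd05 undefined")
    half = emax / 2.0
    above = expr >= half
    if above.all() or not above.any():
        raise ValueError("expression does not straddle half-max; Bcd05 undefined")
    # first segment (ascending bcd) on which the linear interpolant hits half
    for i in range(len(bcd) - 1):
        y0, y1 = expr[i], expr[i + 1]
        if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
            t = (half - y0) / (y1 - y0)
            if 0.0 <= t <= 1.0:
                return float(bcd[i] + t * (bcd[i + 1] - bcd[i]))
        if y0 == half:
            return float(bcd[i])
    raise ValueError("no half-max crossing found")  # pragma: no cover


#: finite-difference spacing floor in ln(Bcd): measurement noise on the Bcd
#: axis leaves near-duplicate concentrations whose expression difference is
#: pure noise divided by a vanishing increment; samples closer than this are
#: pooled before differencing (half the 100-bin trace format's nominal
#: spacing of 1/lambda = 0.05 per bin)
MIN_LOG_SPACING = 0.025


def _pool_close_points(bcd: np.ndarray, expr: np.ndarray, min_dln: float):
    """Pool Bcd-sorted samples whose ln(bcd) lies within min_dln of the
    running group start; returns group means."""
    positive = bcd > 0
    lead_b, lead_e = bcd[~positive], expr[~positive]
    bcd, expr = bcd[positive], expr[positive]
    if len(bcd) == 0:
        return lead_b, lead_e
    logb = np.log(bcd)
    starts = [0]
    for j in range(1, len(bcd)):
        if logb[j] - logb[starts[-1]] >= min_dln:
            starts.append(j)
    bounds = np.array(starts)
    pooled_b = np.array([g.mean() for g in np.split(bcd, bounds[1:])])
    pooled_e = np.array([g.mean() for g in np.split(expr, bounds[1:])])
    if len(lead_b):  # keep an exact-zero sample as its own point
        pooled_b = np.concatenate([[lead_b.mean()], pooled_b])
        pooled_e = np.concatenate([[lead_e.mean()], pooled_e])
    return pooled_b, pooled_e


def raw_shape(grf: GRFSamples, min_log_spacing: float = MIN_LOG_SPACING) -> RawShape:
    """Raw position/steepness by central differences on the max-normalized,
    Bcd-sorted GRF; ties in the maximal derivative break toward smaller Bcd.

    Samples closer than ``min_log_spacing`` in ln(Bcd) are pooled first so
    the finite-difference denominator never collapses below the Bcd
    measurement resolution.
    """
    bcd, expr = _sorted_by_bcd(grf)
    if len(np.unique(bcd)) < 3:
        raise ValueError("need >= 3 distinct bcd values for a derivative estimate")
    if min_log_spacing > 0:
        bcd, expr = _pool_close_points(bcd, expr, min_log_spacing)
    if np.any(np.diff(bcd) <= 0):
        keep = np.concatenate([[True], np.diff(bcd) > 0])
        bcd, expr = bcd[keep], expr[keep]
    if len(bcd) < 3:
        raise ValueError("fewer than 3 usable bcd values after pooling")
    emax = expr.max()
    if emax <= 0:
        raise ValueError("expression is non-positive everywhere")
    f = expr / emax
    deriv = np.gradient(f, bcd)
    # ties (within float noise of the max) break toward the smallest bcd
    dmax = deriv.max()
    tol = 1e-12 * max(abs(dmax), 1.0)
    i = int(np.flatnonzero(deriv >= dmax - tol)[0])
    bcd05 = compute_bcd05(GRFSamples(grf.embryo_id, bcd, expr))
    return RawShape(rP=float(bcd[i]), rS=float(deriv[i]), bcd05=bcd05)


def normalize_shape(raw: RawShape) -> ShapePoint:
    if raw.bcd05 <= 0:
        raise ValueError("bcd05 must be > 0 to normalize shape")
    return ShapePoint(P=raw.rP / raw.bcd05, S=raw.rS * raw.bcd05)


def shape_of(grf: GRFSamples) -> ShapePoint:
    """Convenience: normalized shape of a single averaged GRF."""
    return normalize_shape(raw_shape(grf))


def subsample_shapes(
    cohort: Sequence[GRFSamples],
    n_subsamples: int = 100,
    fraction: float = 0.5,
    seed: int | None = None,
    condition: str = "",
) -> ShapeDistribution:
    """Distribution of (P, S) over random half-cohort averages.

    Each of ``n_subsamples`` draws picks ceil(fraction * n) embryos without
    replacement, averages their GRFs, and computes the normalized shape.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("subsampling requires a cohort of >= 2 embryos")
    k = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    points = []
    for _ in range(n_subsamples):
        subset = rng.choice(n, size=k, replace=False)
        points.append(shape_of(average_grf(cohort, subset)))
    return ShapeDistribution(points=points, condition=condition, subsample_fraction=fraction)


def fit_kde(points: ShapeDistribution) -> KDEModel:
    """2-D Gaussian KDE with per-dimension Silverman bandwidth.

    For d = 2 the Gaussian-optimal rule h_j = sigma_j * (4/(d+2))^(1/(d+4))
    * n^(-1/(d+4)) reduces to h_j = sigma_j * n^(-1/6).
    """
    xy = points.as_array()
    n = len(xy)
    if n < 2 or np.allclose(xy, xy[0]):
        raise ValueError(
            "all shape points identical; KDE bandwidth degenerates — report the "
            "point mass directly instead"
        )
    sigma = xy.std(axis=0, ddof=1)
    h = sigma * n ** (-1.0 / 6.0)
    if np.any(h <= 0):
        raise ValueError("zero variance along one shape dimension; KDE undefined")
    return KDEModel(centers=xy, bandwidth=h)


def p_inside_region(
    kde: KDEModel,
    boundary,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Proportion of KDE mass inside a model-achievable (P, S) region.

    Monte-Carlo: draw ``n_draws`` points from the Gaussian-mixture KDE and
    return (p, standard error) where p is the fraction inside ``boundary``.
    """
    from hbshape.region_analysis import points_in_region

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = kde.sample(n_draws, rng)
    inside = points_in_region(draws, boundary)
    p = float(inside.mean())
    se = float(np.sqrt(p * (1.0 - p) / n_draws))
    return p, se
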