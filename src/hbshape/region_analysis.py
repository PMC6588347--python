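"""Monte-Carlo delimitation of the model-achievable position-steepness region.

For a given number of TF binding sites and cooperativity mode, parameter
sets are sampled at random (each free parameter 10^u, u ~ U[-3, 3] by
default), non-activating draws are discarded, and the normalized (P, S)
shape of every responsive GRF is computed. The achievable region is
summarized as upper/lower steepness envelopes over position bins — the true
region need not be convex, and membership tests only need the envelopes.

The Hill line — the (P, S) locus of pure Hill functions as nH varies — is
the classical reference: an equilibrium model with n sites can approach the
nH = n point only with strong higher-order cooperativity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from hbshape.equilibrium_model import batch_shapes, sample_log_coefficients
from hbshape.shape_metrics import ShapePoint

DEFAULT_N_BINS = 200


@dataclass(frozen=True)
class RegionBoundary:
    """Binned steepness envelopes of the achievable (P, S) region."""

    n_sites: int
    mode: str
    position_bins: np.ndarray  # bin edges over P, length n_bins + 1
    s_upper: np.ndarray  # per-bin max achieved steepness (NaN where empty)
    s_lower: np.ndarray  # per-bin min achieved steepness
    n_samples: int
    seed: int | None
    exponent_range: tuple = (-3.0, 3.0)
    n_discarded: int = 0  # net non-activating draws
    n_nonmonotone: int = 0  # activating but non-monotone draws (excluded)
    n_multistep: int = 0  # monotone but multi-scale staircase draws (excluded)
    n_hyperbolic: int = 0  # concave draws with no interior inflection
    hyperbolic_fallback: bool = False  # region built from concave draws only

    def __post_init__(self) -> None:
        edges = np.asarray(self.position_bins, dtype=float)
        su = np.asarray(self.s_upper, dtype=float)
        sl = np.asarray(self.s_lower, dtype=float)
        if len(edges) != len(su) + 1 or su.shape != sl.shape:
            raise ValueError("position_bins must have one more entry than the envelopes")
        occ = np.isfinite(su)
        if not np.all(su[occ] >= sl[occ]):
            raise ValueError("s_upper must dominate s_lower on occupied bins")
        object.__setattr__(self, "position_bins", edges)
        object.__setattr__(self, "s_upper", su)
        object.__setattr__(self, "s_lower", sl)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.position_bins[:-1] + self.position_bins[1:])

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.s_upper)

    @property
    def max_steepness(self) -> float:
        return float(np.nanmax(self.s_upper))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_bin_center": self.bin_centers,
                "s_lower": self.s_lower,
                "s_upper": self.s_upper,
            }
        )

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "n_sites": self.n_sites,
            "mode": self.mode,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "exponent_range": list(self.exponent_range),
            "n_discarded": self.n_discarded,
            "n_nonmonotone": self.n_nonmonotone,
            "n_multistep": self.n_multistep,
            "n_hyperbolic": self.n_hyperbolic,
            "hyperbolic_fallback": self.hyperbolic_fallback,
            "p_min": float(self.position_bins[0]),
            "p_max": float(self.position_bins[-1]),
        }
        csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, csv_path: str | Path) -> "RegionBoundary":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".meta.json").read_text())
        centers = df["p_bin_center"].to_numpy()
        half = np.diff(centers).mean() / 2.0 if len(centers) > 1 else 0.5
        edges = np.concatenate([[centers[0] - half], centers + half])
        edges[0], edges[-1] = meta["p_min"], meta["p_max"]
        return cls(
            n_sites=meta["n_sites"],
            mode=meta["mode"],
            position_bins=edges,
            s_upper=df["s_upper"].to_numpy(),
            s_lower=df["s_lower"].to_numpy(),
            n_samples=meta["n_samples"],
            seed=meta["seed"],
            exponent_range=tuple(meta["exponent_range"]),
            n_discarded=meta["n_discarded"],
            n_nonmonotone=meta.get("n_nonmonotone", 0),
            n_multistep=meta.get("n_multistep", 0),
            n_hyperbolic=meta.get("n_hyperbolic", 0),
            hyperbolic_fallback=meta.get("hyperbolic_fallback", False),
        )


def compute_region(
    n_sites: int,
    mode: str = "full",
    n_draws: int = 200_000,
    seed: int | None = None,
    exponent_range: tuple[float, float] = (-3.0, 3.0),
    n_bins: int = DEFAULT_N_BINS,
    chunk: int = 4096,
) -> RegionBoundary:
    """Sample the achievable (P, S) region and return its binned envelopes.

    The region delimits single-boundary GRFs comparable to measured
    expression boundaries. Draws are screened: net non-activating draws
    (``n_discarded``), activating but non-monotone ones (``n_nonmonotone``)
    and monotone multi-scale "staircase" GRFs (``n_multistep``) are
    excluded — both have ill-defined or unbounded steepness under the
    affine normalization. Concave draws whose derivative is maximal in the
    y -> 0 limit (``n_hyperbolic``: hyperbola-like GRFs with no interior
    inflection, hence no expression boundary) are likewise excluded, unless
    the whole model class is hyperbolic (one binding site), in which case
    the region degenerates to the hyperbolic point (0, 1) and is built from
    those draws (``hyperbolic_fallback``). Remaining shapes are binned over
    the occupied P range into ``n_bins`` bins with per-bin min/max
    steepness envelopes.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    P_all: list = []
    S_all: list = []
    P_hyp: list = []
    S_hyp: list = []
    n_discarded = 0
    n_nonmonotone = 0
    n_multistep = 0
    n_hyperbolic = 0
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        logn, logd = sample_log_coefficients(n_sites, mode, m, rng, exponent_range)
        res = batch_shapes(logn, logd)
        finite = res["responsive"] & np.isfinite(res["P"]) & np.isfinite(res["S"])
        clean = finite & res["monotone"] & res["unimodal"]
        keep = clean & ~res["edge"]
        hyp = clean & res["edge"]
        n_discarded += int(m - finite.sum())
        n_nonmonotone += int((finite & ~res["monotone"]).sum())
        n_multistep += int((finite & res["monotone"] & ~res["unimodal"]).sum())
        n_hyperbolic += int(hyp.sum())
        P_all.append(res["P"][keep])
        S_all.append(res["S"][keep])
        P_hyp.append(res["P"][hyp])
        S_hyp.append(res["S"][hyp])
        done += m
    P = np.concatenate(P_all)
    S = np.concatenate(S_all)
    hyperbolic_fallback = False
    if P.size == 0:
        P = np.concatenate(P_hyp)
        S = np.concatenate(S_hyp)
        hyperbolic_fallback = True
    if P.size == 0:
        raise ValueError(
            f"no responsive draws out of {n_draws} for n_sites={n_sites}, mode={mode}"
        )
    lo, hi = float(P.min()), float(P.max())
    if hi - lo < 1e-12:  # degenerate region (hyperbolic point)
        lo, hi, n_bins = lo - 1e-9, hi + 1e-9, 1
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(P, edges) - 1, 0, n_bins - 1)
    s_upper = np.full(n_bins, np.nan)
    s_lower = np.full(n_bins, np.nan)
    np.fmax.at(s_upper, idx, S)
    np.fmin.at(s_lower, idx, S)
    return RegionBoundary(
        n_sites=n_sites,
        mode=mode,
        position_bins=edges,
        s_upper=s_upper,
        s_lower=s_lower,
        n_samples=n_draws,
        seed=seed,
        exponent_range=tuple(exponent_range),
        n_discarded=n_discarded,
        n_nonmonotone=n_nonmonotone,
        n_multistep=n_multistep,
        n_hyperbolic=n_hyperbolic,
        hyperbolic_fallback=hyperbolic_fallback,
    )


def hill_shape(nh: float) -> ShapePoint:
    """Closed-form (P, S) of a normalized Hill GRF with coefficient nh.

    With Ka = Bcd05 = 1 the maximal derivative of x^n/(1+x^n) sits at
    x* = ((n-1)/(n+1))^(1/n) with value x*^(n-1) (n+1)^2 / (4n); the
    hyperbolic case n = 1 degenerates to (P, S) = (0, 1).
    """
    if nh < 1:
        raise ValueError("Hill coefficient must be >= 1")
    if nh == 1:
        return ShapePoint(P=0.0, S=1.0)
    p = ((nh - 1.0) / (nh + 1.0)) ** (1.0 / nh)
    s = p ** (nh - 1.0) * (nh + 1.0) ** 2 / (4.0 * nh)
    return ShapePoint(P=float(p), S=float(s))


def hill_line(nh_values: Sequence[float]) -> list:
    """The Hill line: (P, S) points for a sequence of Hill coefficients."""
    return [hill_shape(nh) for nh in nh_values]


def points_in_region(points: np.ndarray, boundary: RegionBoundary) -> np.ndarray:
    """Vectorized membership test for an (m, 2) array of (P, S) points.

    A point is inside iff its P falls within the occupied position range and
    its S lies between the envelopes, linearly interpolated between occupied
    bin centers.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (m, 2) array")
    occ = boundary.occupied
    if not occ.any():
        raise ValueError("boundary has no occupied bins")
    centers = boundary.bin_centers[occ]
    su = boundary.s_upper[occ]
    sl = boundary.s_lower[occ]
    P, S = pts[:, 0], pts[:, 1]
    lo_p = min(centers[0], boundary.position_bins[0])
    hi_p = max(centers[-1], boundary.position_bins[-1])
    in_range = (P >= lo_p) & (P <= hi_p)
    upper = np.interp(P, centers, su)
    lower = np.interp(P, centers, sl)
    return in_range & (S >= lower) & (S <= upper)


def point_in_region(point: ShapePoint, boundary: RegionBoundary) -> bool:
    """True iff the shape point lies inside the sampled region envelopes."""
    return bool(points_in_region(np.array([[point.P, point.S]]), boundary)[0])
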