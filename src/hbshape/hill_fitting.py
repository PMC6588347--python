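"""Per-embryo Hill fits of the Bcd -> lacZ GRF and cohort summaries.

The GRF shape is conventionally summarized by fitting

    E(b) = Emax * b^nH / (Ka^nH + b^nH)

where nH (Hill coefficient) measures sharpness and Ka — the generalized
Michaelis-Menten (gMM) constant — is the Bcd concentration at half-maximal
expression and sets the boundary position along the AP axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from hbshape.trace_processing import GRFSamples

log = logging.getLogger(__name__)

NH_BOUNDS = (0.5, 20.0)
KA_BOUNDS = (1e-4, 10.0)


@dataclass(frozen=True)
class HillFit:
    embryo_id: str
    emax: float
    nh: float
    ka: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class CohortSummary:
    """Across-embryo mean +/- sample SD of the Hill parameters, over
    converged fits only."""

    mean_nh: float
    sd_nh: float
    mean_gmm: float
    sd_gmm: float
    n_embryos: int
    n_excluded: int = 0


def hill(b: np.ndarray, emax: float, nh: float, ka: float) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    bn = np.power(b, nh)
    return emax * bn / (ka**nh + bn)


def _default_init(bcd: np.ndarray, expr: np.ndarray) -> tuple[float, float, float]:
    emax0 = float(expr.max())
    half = emax0 / 2.0
    # Ka init: bcd of the sample closest to half-max expression
    ka0 = float(bcd[np.argmin(np.abs(expr - half))])
    ka0 = float(np.clip(ka0, *KA_BOUNDS))
    return emax0, 4.0, ka0


def fit_hill(
    samples: GRFSamples,
    init: tuple[float, float, float] | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> HillFit:
    """Unweighted least-squares Hill fit of one embryo's GRF samples.

    Requires at least 5 distinct Bcd values with expression on both sides of
    half-max, otherwise the three parameters are not identifiable and the
    fit is refused rather than silently returned.
    """
    bcd, expr = samples.bcd, samples.expr
    if len(np.unique(bcd)) < 5:
        raise ValueError(
            f"embryo {samples.embryo_id}: need >= 5 distinct bcd values to fit a Hill"
        )
    emax0 = expr.max()
    if emax0 <= 0 or np.ptp(expr) < 1e-12 * max(emax0, 1.0):
        raise ValueError(f"embryo {samples.embryo_id}: expression is flat, Hill fit is degenerate")
    half = emax0 / 2.0
    if not ((expr < half).any() and (expr >= half).any()):
        raise ValueError(
            f"embryo {samples.embryo_id}: samples do not straddle half-max expression"
        )

    if init is None:
        init = _default_init(bcd, expr)
    if bounds is None:
        lo = np.array([1e-12, NH_BOUNDS[0], KA_BOUNDS[0]])
        hi = np.array([10.0 * emax0, NH_BOUNDS[1], KA_BOUNDS[1]])
        bounds = (lo, hi)
    x0 = np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return hill(bcd, *theta) - expr

    res = least_squares(residuals, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
    emax, nh, ka = (float(v) for v in res.x)
    return HillFit(
        embryo_id=samples.embryo_id,
        emax=emax,
        nh=nh,
        ka=ka,
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.success),
    )


def fit_cohort(grfs: list, pooled: bool = False) -> list:
    """Fit each embryo independently (default) or one pooled fit over all
    samples (``pooled=True``)."""
    if pooled:
        all_bcd = np.concatenate([g.bcd for g in grfs])
        all_expr = np.concatenate([g.expr for g in grfs])
        return [fit_hill(GRFSamples("pooled", all_bcd, all_expr))]
    return [fit_hill(g) for g in grfs]


def summarize_cohort(fits: list) -> CohortSummary:
    """Mean and sample SD of nH and Ka across converged fits."""
    ok = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(ok)
    if not ok:
        raise ValueError("no converged Hill fits to summarize")
    if n_excluded:
        log.warning("summarize_cohort: excluded %d non-converged fit(s)", n_excluded)
    nh = np.array([f.nh for f in ok])
    ka = np.array([f.ka for f in ok])
    ddof = 1 if len(ok) > 1 else 0
    return CohortSummary(
        mean_nh=float(nh.mean()),
        sd_nh=float(nh.std(ddof=ddof)),
        mean_gmm=float(ka.mean()),
        sd_gmm=float(ka.std(ddof=ddof)),
        n_embryos=len(ok),
        n_excluded=n_excluded,
    )


def write_fits(fits: list, path: str | Path) -> None:
    pd.DataFrame(
        {
            "embryo_id": [f.embryo_id for f in fits],
            "Emax": [f.emax for f in fits],
            "nH": [f.nh for f in fits],
            "Ka": [f.ka for f in fits],
            "rss": [f.rss for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).to_csv(path, index=False)
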