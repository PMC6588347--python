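"""From raw line traces to per-embryo GRF samples.

Mirrors the image-analysis conventions of quantitative blastoderm staining:
subtract the along-axis minimum to remove background, divide lacZ by the 95%
quantile of the hkb costain over the posterior 10% of the axis to remove
batch staining-intensity variation, then pair each embryo's expression trace
with the cohort-averaged Bcd profile to obtain (Bcd, expression) samples of
the gene regulatory function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hbshape.synthetic_embryo import APTrace, BcdProfile, Cohort

POSTERIOR_AP = 90.0  # posterior 10% of the axis: ap_percent >= 90
COSTAIN_QUANTILE = 0.95


@dataclass(frozen=True)
class GRFSamples:
    """Paired (Bcd concentration, expression) points for one embryo or an
    averaged cohort, ordered by ascending AP position (descending Bcd)."""

    embryo_id: str
    bcd: np.ndarray
    expr: np.ndarray

    def __post_init__(self) -> None:
        bcd = np.asarray(self.bcd, dtype=float)
        expr = np.asarray(self.expr, dtype=float)
        if bcd.shape != expr.shape or bcd.ndim != 1:
            raise ValueError("bcd and expr must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(bcd)) and np.all(np.isfinite(expr))):
            raise ValueError("GRF samples must be finite")
        if np.any(bcd < 0):
            raise ValueError("bcd must be >= 0")
        object.__setattr__(self, "bcd", bcd)
        object.__setattr__(self, "expr", expr)

    def __len__(self) -> int:
        return len(self.bcd)


def subtract_background(trace: APTrace) -> APTrace:
    """Subtract the minimum value along the AP axis (background removal)."""
    finite = np.isfinite(trace.value)
    if not finite.any():
        raise ValueError(f"trace {trace.embryo_id}/{trace.channel} is all-NaN")
    return trace.replace_values(trace.value - np.nanmin(trace.value))


def normalize_costain(lacz: APTrace, hkb: APTrace) -> APTrace:
    """Divide lacZ by the 95% quantile of hkb over the posterior 10%.

    The quantile uses linear interpolation between order statistics.
    """
    if not np.array_equal(lacz.ap_percent, hkb.ap_percent):
        raise ValueError("lacZ and hkb traces must share the AP bin grid")
    posterior = hkb.ap_percent >= POSTERIOR_AP
    normalizer = float(np.quantile(hkb.value[posterior], COSTAIN_QUANTILE))
    if normalizer <= 0:
        raise ValueError(
            f"embryo {lacz.embryo_id}: hkb posterior quantile is {normalizer}, "
            "cannot normalize"
        )
    return lacz.replace_values(lacz.value / normalizer)


def pair_grf(
    lacz: APTrace,
    avg_bcd: BcdProfile,
    ap_window: tuple[float, float] | None = None,
) -> GRFSamples:
    """Pair an expression trace with the averaged Bcd profile bin by bin.

    ``ap_window`` restricts pairing to bins with lo <= ap_percent < hi
    (default: full axis). Samples are ordered by ascending AP, i.e.
    descending Bcd.
    """
    if not np.array_equal(lacz.ap_percent, avg_bcd.ap_percent):
        raise ValueError("trace and Bcd profile must share the AP bin grid")
    if ap_window is None:
        mask = np.ones(len(lacz.ap_percent), dtype=bool)
    else:
        lo, hi = ap_window
        mask = (lacz.ap_percent >= lo) & (lacz.ap_percent < hi)
    return GRFSamples(lacz.embryo_id, avg_bcd.value[mask], lacz.value[mask])


def extract_grfs(
    cohort: Cohort,
    ap_window: tuple[float, float] | None = None,
) -> list:
    """Full per-embryo extraction: background-subtract, costain-normalize,
    pair with the cohort-averaged Bcd profile."""
    hkb_by_embryo = {t.embryo_id: t for t in cohort.channel("hkb")}
    out = []
    for lacz in cohort.channel("lacZ"):
        lacz = subtract_background(lacz)
        if lacz.embryo_id in hkb_by_embryo:
            lacz = normalize_costain(lacz, hkb_by_embryo[lacz.embryo_id])
        out.append(pair_grf(lacz, cohort.avg_bcd, ap_window))
    return out


def write_grfs(grfs: list, path: str | Path) -> None:
    frames = [
        pd.DataFrame({"embryo_id": g.embryo_id, "bcd": g.bcd, "expr": g.expr})
        for g in grfs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_grfs(path: str | Path) -> list:
    df = pd.read_csv(path)
    return [
        GRFSamples(str(eid), grp["bcd"].to_numpy(), grp["expr"].to_numpy())
        for eid, grp in df.groupby("embryo_id", sort=False)
    ]
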