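"""Synthetic Drosophila blastoderm line-trace cohorts.

Emulates the data structure produced by quantitative imaging of stained
blastoderm embryos: per-embryo expression traces binned into 100 bins along
the anterior-posterior (AP) axis, with a lacZ reporter channel driven by a
known ("truth") gene regulatory function of the Bicoid gradient, an hkb
costain channel used for staining-intensity normalization, and an
exponentially graded Bcd channel averaged over a small cohort.

The generator exists so every downstream stage (background subtraction,
costain normalization, GRF pairing, Hill fitting, shape metrics) can be
exercised and validated against known ground truth without any imaging data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

N_BINS = 100
#: Bin centers in % egg length, anterior = 0: 0.5, 1.5, ..., 99.5.
AP_BIN_CENTERS = np.arange(N_BINS, dtype=float) + 0.5

CHANNELS = ("lacZ", "bcd", "hkb")


@dataclass(frozen=True)
class BcdProfile:
    """Bicoid concentration per AP bin, in units where the cohort-average
    profile has maximum 1."""

    ap_percent: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        ap = np.asarray(self.ap_percent, dtype=float)
        val = np.asarray(self.value, dtype=float)
        if ap.shape != (N_BINS,) or val.shape != (N_BINS,):
            raise ValueError(f"BcdProfile requires exactly {N_BINS} bins")
        if not np.all(np.isfinite(val)) or np.any(val < 0):
            raise ValueError("Bcd values must be finite and nonnegative")
        if np.any(np.diff(ap) <= 0):
            raise ValueError("ap_percent must be strictly increasing")
        object.__setattr__(self, "ap_percent", ap)
        object.__setattr__(self, "value", val)


@dataclass(frozen=True)
class APTrace:
    """One embryo's 100-bin expression trace for one channel."""

    embryo_id: str
    channel: str
    ap_percent: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        ap = np.asarray(self.ap_percent, dtype=float)
        val = np.asarray(self.value, dtype=float)
        if ap.shape != (N_BINS,) or val.shape != (N_BINS,):
            raise ValueError(f"APTrace requires exactly {N_BINS} bins")
        if np.any(np.diff(ap) <= 0) or ap[0] < 0 or ap[-1] >= 100:
            raise ValueError("ap_percent must be strictly increasing within [0, 100)")
        if not np.all(np.isfinite(val)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "ap_percent", ap)
        object.__setattr__(self, "value", val)

    def replace_values(self, value: np.ndarray) -> "APTrace":
        return dataclasses.replace(self, value=np.asarray(value, dtype=float))


@dataclass(frozen=True)
class HillTruth:
    """Hill gene regulatory function E(b) = emax * b^nh / (ka^nh + b^nh)."""

    emax: float = 1.0
    nh: float = 5.2
    ka: float = 0.072

    def __post_init__(self) -> None:
        if self.emax <= 0 or self.nh <= 0 or self.ka <= 0:
            raise ValueError("Hill parameters must be positive")

    def __call__(self, bcd: np.ndarray) -> np.ndarray:
        b = np.asarray(bcd, dtype=float)
        bn = np.power(b, self.nh)
        return self.emax * bn / (self.ka**self.nh + bn)


@dataclass
class SimConfig:
    """Free parameters of the cohort simulator.

    lambda_decay
        Bcd gradient length constant in %EL (exponential decay).
    truth_grf
        Ground-truth GRF mapping normalized Bcd concentration to expression;
        a :class:`HillTruth` or any callable.
    noise_cv
        Per-bin multiplicative lognormal coefficient of variation.
    bcd_noise_cv
        Per-bin CV of the individual Bcd gradients before averaging; the
        gradient is highly reproducible embryo to embryo, so this stays small.
    amp_sd
        Embryo-to-embryo lognormal amplitude SD (in log space).
    background
        Additive staining background on the lacZ channel.
    costain_level
        hkb posterior plateau level (the normalizer's expected value).
    """

    lambda_decay: float = 20.0
    n_embryos: int = 6
    truth_grf: Callable[[np.ndarray], np.ndarray] = field(default_factory=HillTruth)
    noise_cv: float = 0.05
    bcd_noise_cv: float = 0.1
    amp_sd: float = 0.1
    background: float = 0.1
    costain_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be > 0")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        for name in ("noise_cv", "bcd_noise_cv", "amp_sd", "background", "costain_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def truth_dict(self) -> dict:
        t = self.truth_grf
        if isinstance(t, HillTruth):
            return {"kind": "hill", "emax": t.emax, "nh": t.nh, "ka": t.ka}
        return {"kind": "callable", "repr": repr(t)}


@dataclass(frozen=True)
class Cohort:
    """Simulated cohort: lacZ + hkb traces per embryo, the averaged Bcd
    profile they respond to, and the generator's truth metadata."""

    traces: list
    avg_bcd: BcdProfile
    truth: dict
    seed: int

    def channel(self, channel: str) -> list:
        return [t for t in self.traces if t.channel == channel]

    @property
    def embryo_ids(self) -> list:
        seen: list = []
        for t in self.traces:
            if t.embryo_id not in seen:
                seen.append(t.embryo_id)
        return seen


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


def make_bcd_profiles(
    lambda_decay: float,
    n_embryos: int,
    noise_cv: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list, BcdProfile]:
    """Generate per-embryo exponential Bcd gradients and their cohort average.

    Each embryo's profile is exp(-ap/lambda) with per-bin multiplicative
    lognormal noise; the bin-wise mean over embryos is rescaled so its
    maximum is 1, and the same scale is applied to the individual profiles
    (the gradient is highly reproducible, so one average profile serves as
    the concentration standard for the whole cohort).

    Returns (list of per-embryo BcdProfile, averaged BcdProfile).
    """
    if lambda_decay <= 0:
        raise ValueError("lambda_decay must be > 0")
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    clean = np.exp(-AP_BIN_CENTERS / lambda_decay)
    values = clean[None, :] * _lognormal_factors(rng, noise_cv, (n_embryos, N_BINS))
    avg = values.mean(axis=0)
    scale = avg.max()
    values /= scale
    avg /= scale
    profiles = [BcdProfile(AP_BIN_CENTERS, v) for v in values]
    return profiles, BcdProfile(AP_BIN_CENTERS, avg)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate one cohort of embryos under a known truth GRF.

    Per embryo e and AP bin:

        lacZ(ap) = (A_e * GRF(bcd_avg(ap)) + background) * eta(ap)
        hkb(ap)  = plateau(ap) * eta'(ap)

    with A_e lognormal across embryos (log-SD ``amp_sd``), eta unit-mean
    lognormal per bin (CV ``noise_cv``), and the hkb plateau equal to
    ``costain_level`` in the posterior 10% of the axis (a dim nonspecific
    baseline of 0.1 * costain_level elsewhere). The truth GRF is evaluated on
    the cohort-averaged Bcd profile, the same concentration standard the
    downstream analysis pairs expression against.
    """
    rng = np.random.default_rng(config.seed)
    _, avg_bcd = make_bcd_profiles(
        config.lambda_decay, config.n_embryos, config.bcd_noise_cv, rng=rng
    )
    signal = np.asarray(config.truth_grf(avg_bcd.value), dtype=float)
    if signal.shape != (N_BINS,) or not np.all(np.isfinite(signal)):
        raise ValueError(
            f"truth GRF returned invalid values for truth={config.truth_dict()}"
        )
    if signal.max() - signal.min() < 1e-12:
        raise ValueError(
            f"truth GRF is unresponsive over the Bcd range (truth={config.truth_dict()})"
        )

    posterior = AP_BIN_CENTERS >= 90.0
    plateau = np.where(posterior, config.costain_level, 0.1 * config.costain_level)

    traces: list = []
    for e in range(config.n_embryos):
        embryo_id = f"embryo{e:02d}"
        amp = float(np.exp(rng.normal(0.0, config.amp_sd))) if config.amp_sd else 1.0
        lacz = (amp * signal + config.background) * _lognormal_factors(
            rng, config.noise_cv, N_BINS
        )
        hkb = plateau * _lognormal_factors(rng, config.noise_cv, N_BINS)
        traces.append(APTrace(embryo_id, "lacZ", AP_BIN_CENTERS, lacz))
        traces.append(APTrace(embryo_id, "hkb", AP_BIN_CENTERS, hkb))
    return Cohort(traces=traces, avg_bcd=avg_bcd, truth=config.truth_dict(), seed=config.seed)


# ---------------------------------------------------------------------------
# TSV round trip


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for t in cohort.traces:
        rows.append(
            pd.DataFrame(
                {
                    "embryo_id": t.embryo_id,
                    "channel": t.channel,
                    "ap_bin": np.arange(N_BINS),
                    "ap_percent": t.ap_percent,
                    "value": t.value,
                }
            )
        )
    rows.append(
        pd.DataFrame(
            {
                "embryo_id": "cohort_average",
                "channel": "bcd",
                "ap_bin": np.arange(N_BINS),
                "ap_percent": cohort.avg_bcd.ap_percent,
                "value": cohort.avg_bcd.value,
            }
        )
    )
    return pd.concat(rows, ignore_index=True)


def write_cohort(cohort: Cohort, tsv_path: str | Path) -> None:
    """Write a cohort as TSV plus a JSON sidecar holding truth metadata."""
    tsv_path = Path(tsv_path)
    cohort_to_frame(cohort).to_csv(tsv_path, sep="\t", index=False)
    sidecar = tsv_path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps({"truth": cohort.truth, "seed": cohort.seed}, indent=2))


def read_cohort(tsv_path: str | Path) -> Cohort:
    """Read a cohort TSV written by :func:`write_cohort`."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    traces = []
    avg_bcd = None
    for (embryo_id, channel), grp in df.groupby(["embryo_id", "channel"], sort=False):
        grp = grp.sort_values("ap_bin")
        if embryo_id == "cohort_average" and channel == "bcd":
            avg_bcd = BcdProfile(grp["ap_percent"].to_numpy(), grp["value"].to_numpy())
        else:
            traces.append(
                APTrace(str(embryo_id), channel, grp["ap_percent"].to_numpy(), grp["value"].to_numpy())
            )
    if avg_bcd is None:
        raise ValueError(f"{tsv_path} has no cohort_average bcd channel")
    sidecar = tsv_path.with_suffix(".truth.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {"truth": {}, "seed": -1}
    return Cohort(traces=traces, avg_bcd=avg_bcd, truth=meta["truth"], seed=meta["seed"])
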