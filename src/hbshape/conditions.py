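"""Reference cohort conditions for parameter-recovery experiments.

Each condition parameterizes the synthetic generator with a reported Hill
fit of the Bcd -> reporter GRF (WT HbP2, endogenous hb, and two RNAi
knockdowns that shift the boundary anteriorly), at the cohort size imaged
for that condition. Running the full extraction + per-embryo fitting on
such a cohort and comparing the recovered cohort mean against the
generator truth exercises every stage of the measurement pipeline under
realistic noise.

Boundary positions are converted to gMM values through the exponential
gradient: an anterior shift of d %EL corresponds to multiplying Ka by
e^(d/lambda); a boundary at position a %EL corresponds to Ka = e^(-a/lambda)
in normalized Bcd units (lambda = 20 %EL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from hbshape import hill_fitting, trace_processing
from hbshape.hill_fitting import CohortSummary
from hbshape.synthetic_embryo import HillTruth, SimConfig, simulate_cohort

LAMBDA_EL = 20.0


@dataclass(frozen=True)
class CohortCondition:
    name: str
    truth: HillTruth
    n_embryos: int
    noise_cv: float
    amp_sd: float = 0.1

    def config(self, seed: int) -> SimConfig:
        return SimConfig(
            lambda_decay=LAMBDA_EL,
            n_embryos=self.n_embryos,
            truth_grf=self.truth,
            noise_cv=self.noise_cv,
            amp_sd=self.amp_sd,
            seed=seed,
        )


#: WT HbP2 reporter: nH 5.2, gMM 0.072 (10 embryos imaged across batches)
WT_HBP2 = CohortCondition("WTHbP2", HillTruth(1.0, 5.2, 0.072), 10, 0.05)

#: endogenous hb pattern: nH 6.2, gMM 0.063, six embryos
ENDOGENOUS_HB = CohortCondition("endogenous_hb", HillTruth(1.0, 6.2, 0.063), 6, 0.08)

#: maternal hb RNAi: nH 5.9, boundary shifted 8 %EL anteriorly from WT
HB_RNAI = CohortCondition(
    "hb_RNAi",
    HillTruth(1.0, 5.9, 0.072 * math.exp(8.0 / LAMBDA_EL)),
    11,
    0.08,
)

#: CBP (nejire) RNAi: nH 4.5, boundary at 34 %EL
CBP_RNAI = CohortCondition(
    "CBP_RNAi", HillTruth(1.0, 4.5, math.exp(-34.0 / LAMBDA_EL)), 8, 0.08
)

CONDITIONS = {c.name: c for c in (WT_HBP2, ENDOGENOUS_HB, HB_RNAI, CBP_RNAI)}


def recover_cohort(condition: CohortCondition, seed: int) -> CohortSummary:
    """Simulate the condition's cohort, run extraction and per-embryo Hill
    fitting, and return the across-embryo summary."""
    cohort = simulate_cohort(condition.config(seed))
    grfs = trace_processing.extract_grfs(cohort)
    fits = hill_fitting.fit_cohort(grfs)
    return hill_fitting.summarize_cohort(fits)
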