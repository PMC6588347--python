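import numpy as np
import pytest

from hbshape import region_analysis, synthetic_embryo, trace_processing
from hbshape.synthetic_embryo import HillTruth, SimConfig


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free WT-like cohort; the truth Ka is interior enough that the
    min-subtraction truncation of the posterior tail is below 1e-7."""
    cfg = SimConfig(
        truth_grf=HillTruth(emax=1.0, nh=5.2, ka=0.2),
        n_embryos=4,
        noise_cv=0.0,
        bcd_noise_cv=0.0,
        amp_sd=0.0,
        background=0.1,
        seed=7,
    )
    return synthetic_embryo.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def wt_cohort():
    """WT-like cohort at the reported fit (nH 5.2, gMM 0.072) with
    realistic noise."""
    cfg = SimConfig(
        truth_grf=HillTruth(emax=1.0, nh=5.2, ka=0.072),
        n_embryos=10,
        noise_cv=0.05,
        amp_sd=0.1,
        seed=1,
    )
    return synthetic_embryo.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def wt_grfs(wt_cohort):
    return trace_processing.extract_grfs(wt_cohort)


@pytest.fixture(scope="session")
def noiseless_grfs(noiseless_cohort):
    return trace_processing.extract_grfs(noiseless_cohort)


# -- Monte-Carlo regions shared across the region/acceptance tests.
#    One sampling per condition at the scale the analyses use.

N_REGION_DRAWS = 100_000
REGION_BINS = 25


def _region(n_sites, mode, seed, exponent_range=(-3.0, 3.0)):
    return region_analysis.compute_region(
        n_sites=n_sites,
        mode=mode,
        n_draws=N_REGION_DRAWS,
        seed=seed,
        exponent_range=exponent_range,
        n_bins=REGION_BINS,
    )


@pytest.fixture(scope="session")
def region_full6():
    return _region(6, "full", seed=601)


@pytest.fixture(scope="session")
def region_pairwise_tf_pol():
    return _region(6, "pairwise_tf_pol", seed=602)


@pytest.fixture(scope="session")
def region_pairwise_tf_tf():
    return _region(6, "pairwise_tf_tf", seed=603)


@pytest.fixture(scope="session")
def regions_by_sites():
    return {n: _region(n, "full", seed=600 + 10 * n) for n in (2, 3, 4, 5)}


@pytest.fixture(scope="session")
def region_full6_wide():
    return _region(6, "full", seed=604, exponent_range=(-4.0, 4.0))


def envelope_at(boundary, p):
    """Upper envelope interpolated at positions p (helper shared by tests)."""
    occ = boundary.occupied
    c = boundary.bin_centers[occ]
    return np.interp(p, c, boundary.s_upper[occ])
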