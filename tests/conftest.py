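import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from deqct import (
    BeamCalibration,
    build_lookup,
    cirs_inserts,
    fit_alpha_from_attenuation,
    fit_n,
    load_dual_kvp_benchmark,
)


@pytest.fixture(scope="session")
def insert_set():
    return cirs_inserts()


@pytest.fixture(scope="session")
def benchmark():
    return load_dual_kvp_benchmark()


@pytest.fixture(scope="session")
def beam(insert_set, benchmark) -> BeamCalibration:
    """Beam calibrated on the bundled seven-insert benchmark (80/130 kVp)."""
    mats = [insert_set[m] for m in benchmark.material]
    nfit = fit_n(mats)
    a_low, se_low = fit_alpha_from_attenuation(
        mats, benchmark.mu_m_star_80.to_numpy(), nfit.n
    )
    a_high, se_high = fit_alpha_from_attenuation(
        mats, benchmark.mu_m_star_130.to_numpy(), nfit.n
    )
    return BeamCalibration(
        kvp_low=80.0,
        kvp_high=130.0,
        n=nfit.n,
        alpha_low=a_low,
        alpha_high=a_high,
        alpha_low_se=se_low,
        alpha_high_se=se_high,
    )


@pytest.fixture(scope="session")
def lut(beam):
    return build_lookup(beam)
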