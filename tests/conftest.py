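import pytest

from osmoflux import (PhysicalConstants, ProbeGeometry, SimulationConfig,
                      simulate_cohort)


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def noisefree_cohort_dir(tmp_path_factory):
    """A noise-free synthetic cohort written to disk: the pipeline must
    recover its ground truth exactly."""
    cfg = SimulationConfig(flux_rel_sd=0.0, sodium_rel_sd=0.0,
                           mass_rel_sd=0.0, excision_mass_rel_sd=0.0)
    cohort = simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("noisefree")
    cohort.write(out)
    return out, cohort


@pytest.fixture(scope="session")
def default_cohort_dir(tmp_path_factory):
    """The default-noise cohort (5 pressures x 5 samples, seed 0)."""
    cohort = simulate_cohort(SimulationConfig())
    out = tmp_path_factory.mktemp("default")
    cohort.write(out)
    return out, cohort
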