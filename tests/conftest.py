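import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import staturepgs as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def growth_ref():
    return sp.references.synthetic_growth_reference()


@pytest.fixture(scope="session")
def adult_ref():
    return sp.references.synthetic_adult_reference()


@pytest.fixture(scope="session")
def sim_config():
    return sp.SimulationConfig(n_families=3000, n_snps=60, n_adult_reference=800, seed=11)


@pytest.fixture(scope="session")
def trio_cohort(sim_config):
    """One referred trio cohort shared across the suite."""
    return sp.simulate_trios(sim_config)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, trio_cohort):
    """The same cohort emitted to disk in the CSV dialect."""
    out = tmp_path_factory.mktemp("study")
    paths = sp.simulate.emit(trio_cohort, out)
    return paths


@pytest.fixture(scope="session")
def pipeline_result(study_dir):
    """A full pipeline run (modest bootstrap) on the shared synthetic study."""
    cfg = sp.RunConfig.from_yaml(study_dir["run_config"])
    cfg.n_boot = 200
    report, frame = sp.run_pipeline(cfg)
    return report, frame
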