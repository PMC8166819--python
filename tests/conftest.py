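import dataclasses

import pytest

from tmedissect import SimulationConfig, simulate_cohort, simulate_scrna

#: ground-truth stratum name -> pipeline phenotype name
PHENOTYPE = {"hot": "inflamed", "median": "median", "cold": "noninflamed"}


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def sc_default(default_cfg):
    """Default single-cell simulation (shared; treat as read-only)."""
    return simulate_scrna(default_cfg)


@pytest.fixture(scope="session")
def cohort_default(default_cfg):
    """Default bulk cohort simulation (shared; treat as read-only)."""
    return simulate_cohort(default_cfg)


@pytest.fixture()
def make_cfg():
    def _make(**overrides) -> SimulationConfig:
        return dataclasses.replace(SimulationConfig(), **overrides)

    return _make
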