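import dataclasses

import pytest

from cernet import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at the study-like defaults (4-fold effects)."""
    return simulate_dataset(SimulationConfig(lfc_de=2.0, seed=42))


@pytest.fixture(scope="session")
def small_sim_config():
    """A desk-scale config for fast pipeline-level tests."""
    return SimulationConfig(n_circ=20, n_mirna=30, n_mrna=80, n_circuits=2,
                            n_de_circ=6, n_de_mirna=21, n_de_mrna=20,
                            lfc_de=2.0, seed=7)


@pytest.fixture()
def replace_cfg():
    def _replace(cfg, **kw):
        return dataclasses.replace(cfg, **kw)
    return _replace
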