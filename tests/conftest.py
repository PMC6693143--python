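import numpy as np
import pytest

from lactrr.mme import VarianceComponents
from lactrr.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_leg1():
    """A few dozen records from an order-1 truth, for dense-oracle checks."""
    cfg = SimulationConfig(
        n_sires=2, daughters_per_sire=2, n_dams=3, n_herds=1, order=1,
        k_g=np.diag([0.4, 0.04]), k_p=np.diag([0.3, 0.03]))
    return simulate_dataset(cfg, seed=5)


@pytest.fixture(scope="session")
def small_leg1():
    """~350 records, order-1 truth: cheap REML-capable dataset."""
    cfg = SimulationConfig(
        n_sires=6, daughters_per_sire=8, n_dams=24, n_herds=4, order=1,
        k_g=np.diag([0.4, 0.04]), k_p=np.diag([0.3, 0.03]))
    return simulate_dataset(cfg, seed=9)


@pytest.fixture(scope="session")
def filterable_data():
    """Dataset whose sires satisfy the 20-progeny retention rule."""
    cfg = SimulationConfig(
        n_sires=5, daughters_per_sire=20, n_dams=30, n_herds=3, order=1,
        k_g=np.diag([0.4, 0.04]), k_p=np.diag([0.3, 0.03]))
    return simulate_dataset(cfg, seed=21)


@pytest.fixture(scope="session")
def tiny_components():
    return VarianceComponents(k_g=np.diag([0.4, 0.04]),
                              residual=np.full(9, 0.3),
                              k_p=np.diag([0.3, 0.03]))
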