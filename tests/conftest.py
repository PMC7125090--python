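import math

import numpy as np
import pytest

from occabund.model import ModelParams
from occabund.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small integrated-model dataset with auxiliary data."""
    cfg = SimulationConfig(
        n_species=6, n_cells=10, plots_per_cell=8, seed=101,
        aux_presence_coverage=0.5, aux_absence_coverage=0.4,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_e3_dataset():
    """Tiny dataset whose only random effect is the species-by-cell term."""
    params = ModelParams(mu=math.log(1500), beta1=0.4, eta=0.3, gamma1=-0.3, sigma3=0.5)
    cfg = SimulationConfig(
        n_species=2, n_cells=2, plots_per_cell=2, true_params=params, seed=11,
        aux_presence_coverage=0.3, aux_absence_coverage=0.3,
    )
    return simulate_dataset(cfg)


def integer_partitions(n, mx=None):
    """All partitions of n into positive parts (non-increasing order)."""
    if mx is None:
        mx = n
    if n == 0:
        yield []
        return
    for k in range(min(n, mx), 0, -1):
        for rest in integer_partitions(n - k, k):
            yield [k] + rest
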