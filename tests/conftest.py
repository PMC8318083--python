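import numpy as np
import pytest

import semcomp as sc


@pytest.fixture(scope="session")
def space():
    """80-source lattice with analysis mask, two fROIs and two control regions."""
    return sc.demo_space(8, 10)


@pytest.fixture(scope="session")
def small_design():
    return sc.DesignSpec(n_subjects=4, trials_per_condition=8)


@pytest.fixture(scope="session")
def noiseless_interaction(space, small_design):
    """Noiseless dataset with a planted interaction effect in roi_A, 650-850 ms."""
    eff = sc.PlantedEffect(
        "interaction", space.mask("roi_A"), (650.0, 850.0), amplitude=0.7
    )
    tensors, truth = sc.simulate_dataset(
        small_design, space, [eff], noise=sc.NoiseSpec(sensor_sd=0.0), seed=3
    )
    return tensors, truth, eff


@pytest.fixture(scope="session")
def noisy_dataset(space, small_design):
    tensors, _ = sc.simulate_dataset(
        small_design, space, noise=sc.NoiseSpec(sensor_sd=1.0), seed=9
    )
    return tensors


def condition_mean_contrast(tensor, weights):
    """Weighted sum of condition means, e.g. the 2x2 interaction contrast."""
    out = np.zeros(tensor.data.shape[1:])
    for cond, w in weights.items():
        out += w * tensor.data[tensor.trials_of(cond)].mean(axis=0)
    return out


INTERACTION_WEIGHTS = {"HA-comp": 1.0, "LA-comp": -1.0, "HA-list": -1.0, "LA-list": 1.0}
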