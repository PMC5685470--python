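import numpy as np
import pytest

from refframe.core_io import ConditionGrid, build_tuning
from refframe.synthetic_data import NeuronSpec, NoiseSpec

EYES = (-20.0, 0.0, 20.0)


@pytest.fixture
def noiseless_spec():
    return NeuronSpec(theta_p_deg=90.0, lambda_frame=1.0, noise=NoiseSpec("none"))


@pytest.fixture
def noisy_spec():
    return NeuronSpec(
        theta_p_deg=135.0, lambda_frame=1.0, noise=NoiseSpec("gaussian_fano", 1.5)
    )


@pytest.fixture
def standard_grid():
    return ConditionGrid.standard()


def eccentric_curves(table, neuron_id="syn0", modality="visual", eyes=EYES):
    return {
        e: build_tuning(table, neuron_id, modality, eye_pos_deg=e) for e in eyes
    }


def pursuit_curves(table, neuron_id="syn0"):
    return {
        d: build_tuning(
            table, neuron_id, "visual", protocol="pursuit", pursuit_dir=d
        )
        for d in ("none", "leftward", "rightward")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
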