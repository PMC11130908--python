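import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tetflux as tf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def unit_enzymes():
    """All enzyme levels equal to one."""
    return tf.EnzymeProfile(dnmt1=1, tet1=1, tet2=1, tet3=1, aid=1, smug1=1, tdg=1)


@pytest.fixture
def unit_params():
    """All rate coefficients equal to one."""
    return tf.RateParameters(
        k_dnmt1=1, k1_tet1=1, k1_tet2=1, k1_tet3=1,
        k2_tet1=1, k2_tet2=1, k2_tet3=1,
        k3_tet1=1, k3_tet2=1, k3_tet3=1,
        k4=1, k5=1, k_aid_hmdc=1, k_aid_c=1, k_smug=1, k_tdg=1,
    )


@pytest.fixture
def full_structure():
    return tf.ModelStructure.full()


def random_instance(rng, low=0.05, high=5.0):
    """A random strictly-positive model instance (enzymes, params, structure)."""
    def draw():
        return float(rng.uniform(low, high))

    enzymes = tf.EnzymeProfile(
        dnmt1=draw(), tet1=draw(), tet2=draw(), tet3=draw(),
        aid=draw(), smug1=draw(), tdg=draw(),
    )
    params = tf.RateParameters(
        k_dnmt1=draw(),
        k1_tet1=draw(), k1_tet2=draw(), k1_tet3=draw(),
        k2_tet1=draw(), k2_tet2=draw(), k2_tet3=draw(),
        k3_tet1=draw(), k3_tet2=draw(), k3_tet3=draw(),
        k4=draw(), k5=draw(),
        k_aid_hmdc=draw(), k_aid_c=draw(), k_smug=draw(), k_tdg=draw(),
    )
    structure = tf.decode(int(rng.integers(0, tf.N_STRUCTURES)))
    return enzymes, params, structure


@pytest.fixture
def noiseless_dataset():
    """Five-line noiseless dataset generated from the preset ground truth."""
    config = tf.GeneratorConfig(noise_cv=0.0, seed=11)
    return tf.generate_dataset(config)
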