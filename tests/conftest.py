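import numpy as np
import pytest

from spontlfp import (EffectSpec, StimulusTrainConfig, generate_protocol,
                      simulate_lfp_session)


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced block protocol: one airflow block (11 x 3 = 33 stimuli) and
    one touch block (20 x 2 = 40 stimuli), short inter-block gap."""
    airflow = StimulusTrainConfig(sequence_length=11, repetitions=3)
    touch = StimulusTrainConfig(sequence_length=20, repetitions=2, jitter=0.75)
    return generate_protocol(airflow, touch, n_block_pairs=1,
                             inter_block_gap=30.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_protocol):
    """Synthetic session with the default 10-25 Hz context effect (ratio 1.5)."""
    return simulate_lfp_session(small_protocol, {"central": 1, "basal": 2},
                                EffectSpec(power_ratio=1.5), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
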