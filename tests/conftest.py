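import numpy as np
import pytest

from emorec import (
    EffectSpec,
    GeneratorConfig,
    WindowSpec,
    build_feature_table,
    generate_recordings,
    train_final,
)
from emorec.montage import OPTIMAL_CHANNELS_8
from emorec.presets import strong_config, strong_effect, strong_windows


@pytest.fixture(scope="session")
def small_rs():
    """1 subject x 2 trials x 32 channels x 6 s: cheap IO/shape fixture."""
    cfg = GeneratorConfig(n_subjects=1, trials_per_subject=2, trial_duration_s=6.0)
    return generate_recordings(cfg, EffectSpec(), seed=7)


@pytest.fixture(scope="session")
def strong_rs():
    """Strong-coupling fixture: classes recoverable from gamma band power."""
    return generate_recordings(strong_config(), strong_effect(), seed=11)


@pytest.fixture(scope="session")
def strong_table(strong_rs):
    return build_feature_table(
        strong_rs, strong_windows(), montage=OPTIMAL_CHANNELS_8
    )


@pytest.fixture(scope="session")
def trio(strong_table):
    """Final Extra-Trees trio fitted on the strong-coupling table."""
    return train_final(strong_table, k=34)


@pytest.fixture(scope="session")
def replay_rs():
    """One 58-s 8-channel trial for streaming tests."""
    cfg = GeneratorConfig(
        n_subjects=1,
        trials_per_subject=1,
        trial_duration_s=58.0,
        channel_names=OPTIMAL_CHANNELS_8,
    )
    return generate_recordings(cfg, strong_effect(), seed=13)
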