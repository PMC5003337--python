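import numpy as np
import pandas as pd
import pytest

from tfspm.design import EventTable, StimulusSetConfig, build_trial_schedule
from tfspm.simulate import Epochs


@pytest.fixture(scope="session")
def paper_schedule():
    return build_trial_schedule(StimulusSetConfig(), seed=0)


@pytest.fixture
def small_schedule():
    cfg = StimulusSetConfig(n_models_female=1, n_models_male=1,
                            n_repetitions=2, n_target_trials=1)
    return build_trial_schedule(cfg, seed=3)


def make_epochs(data, fs=1000.0, t0=-1000.0, events=None,
                channels=("LTP", "RTP"), hemis=("left", "right")):
    data = np.asarray(data, float)
    if events is None:
        events = EventTable(pd.DataFrame(dict(
            trial_id=np.arange(data.shape[0]),
            onset_ms=np.arange(data.shape[0], dtype=float) * 4000,
            duration_ms=1500.0,
            stimulus_type=["eyes" if i % 2 == 0 else "mosaic"
                           for i in range(data.shape[0])],
            first_direction="averted", second_direction="straight",
            model_id=0, is_target=False)))
    return Epochs(data, fs, t0, channels[:data.shape[1]],
                  hemis[:data.shape[1]], "sub-01", events)


@pytest.fixture
def epochs_factory():
    return make_epochs
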