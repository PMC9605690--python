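import warnings

import numpy as np
import pytest

from dnpop.encoding import assemble_session
from dnpop.simulate import GeneratorConfig, generate_experiment

# the regression analyses legitimately emit skipped-fold warnings on rare
# behaviors; keep test output readable
warnings.filterwarnings("ignore", category=RuntimeWarning, message=".*fold skipped.*")


@pytest.fixture(scope="session")
def small_cfg():
    """One fly, two short trials: enough structure for unit tests."""
    return GeneratorConfig(seed=11, n_flies=1, n_trials=2, trial_duration=240.0)


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    return generate_experiment(small_cfg)


@pytest.fixture(scope="session")
def small_fly(small_experiment):
    return small_experiment.flies[0]


@pytest.fixture(scope="session")
def small_session(small_experiment, small_cfg):
    return assemble_session(small_experiment.flies[0].trials, small_cfg.kernel())


@pytest.fixture(scope="session")
def small_ground_truth(small_fly):
    return small_fly.ground_truth_frame()


def neuron_index(session, ground_truth, encoding_class, k=0):
    nid = ground_truth[ground_truth.encoding_class == encoding_class].neuron_id.iloc[k]
    return int(np.flatnonzero(session.neuron_ids == nid)[0])
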