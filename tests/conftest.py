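import numpy as np
import pytest

from graftdyn.preprocess import (baseline_correct, bin_trials,
                                 segment_residuals, segment_trials)
from graftdyn.synth import TaskSessionSpec, gen_task_session


@pytest.fixture(scope="session")
def task_session():
    """One mid-sized task session with strong, known structure."""
    spec = TaskSessionSpec(n_cells=40, n_trials=25, frac_modulated=0.4,
                           shared_frac=0.5, transient_amp=5.0, seed=123)
    rec, gt = gen_task_session(spec)
    return spec, rec, gt


@pytest.fixture(scope="session")
def segmented(task_session):
    _, rec, _ = task_session
    tens = segment_trials(rec, "pellet_touch", (5.0, 5.0))
    resid = segment_residuals(rec, "pellet_touch", (5.0, 5.0))
    return baseline_correct(tens, resid)


@pytest.fixture(scope="session")
def binned(segmented):
    return bin_trials(segmented, 0.5, (2.5, 2.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
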