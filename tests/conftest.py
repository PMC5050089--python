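import numpy as np
import pytest

from dietcalib import (ErrorModelSpec, ScenarioConfig, TrialDataset,
                       mask_calibration, simulate_full_trial)
from dietcalib.simulate import replicate_rng


def make_dataset(group, q, m1, m2):
    """Small explicit dataset builder for hand-checked examples."""
    return TrialDataset(group=np.asarray(group), q=np.asarray(q, float),
                        m=np.column_stack([np.asarray(m1, float),
                                           np.asarray(m2, float)]))


@pytest.fixture
def toy_dataset():
    """8 individuals, 4 per arm, fully observed; numbers chosen by hand."""
    return make_dataset(
        group=[1, 1, 1, 1, 2, 2, 2, 2],
        q=[4.1, 3.9, 4.4, 3.6, 3.2, 3.8, 3.5, 3.1],
        m1=[4.5, 4.2, 4.9, 4.0, 3.9, 4.4, 4.1, 3.7],
        m2=[4.6, 4.1, 4.8, 4.2, 4.0, 4.3, 4.2, 3.6],
    )


@pytest.fixture
def noise_free_dataset():
    """M1 = M2 = T exactly and Q exactly linear in T, arm-specific slopes."""
    rng = np.random.default_rng(5)
    t1 = rng.normal(4.6, 0.35, 30)
    t2 = rng.normal(4.1, 0.35, 30)
    t = np.concatenate([t1, t2])
    q = np.concatenate([0.3 + 0.8 * t1, 1.5 + 0.5 * t2])
    return make_dataset(group=np.r_[np.ones(30), 2 * np.ones(30)],
                        q=q, m1=t, m2=t)


@pytest.fixture(scope="session")
def sim_dataset_25pct():
    """One masked trial at the reference settings, 25% calibration."""
    cfg = ScenarioConfig.differential(seed=101)
    rng = replicate_rng(101, 0)
    full = simulate_full_trial(cfg, rng)
    return full, mask_calibration(full, 0.25, rng)


@pytest.fixture
def spec_diff():
    return ErrorModelSpec("differential")


@pytest.fixture
def spec_nondiff():
    return ErrorModelSpec("nondifferential")
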