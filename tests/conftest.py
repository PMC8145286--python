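import numpy as np
import pytest

import voxstate as vs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_activity(values, tr=2.0, runs=(0,)):
    return vs.ActivityMatrix(values=values, tr_seconds=tr, run_boundaries=runs)


@pytest.fixture(scope="session")
def attention_dataset():
    """Small preprocessed attention-scheme dataset shared across tests."""
    spec = vs.SyntheticSpec(n_trs=900, n_voxels=200, seed=7)
    design, bold, truth = vs.generate(spec)
    y = vs.zscore_voxels(vs.detrend_voxels(bold))
    return design, y, truth


@pytest.fixture(scope="session")
def attention_trajectory(attention_dataset):
    design, y, _ = attention_dataset
    model = vs.fit_state_space(design, y, n_components=24)
    return vs.project(y, model.basis_qs, model.variable_names, labels=design.labels)
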