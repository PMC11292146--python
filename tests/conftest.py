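import numpy as np
import pytest

import screenpref as sp


@pytest.fixture(scope="session")
def space():
    return sp.default_space()


@pytest.fixture(scope="session")
def small_design():
    """4 blocks x 6 tasks: enough variety to identify all 16 dummies."""
    return sp.generate_design(n_blocks=4, tasks_per_block=6, seed=7)


@pytest.fixture(scope="session")
def ref_params():
    return sp.reference_mxl_params()


@pytest.fixture(scope="session")
def small_dataset(small_design, ref_params):
    """150 simulated respondents on the small design, filters applied."""
    cohort = sp.simulate_respondents(150, seed=7, n_blocks=4)
    ds = sp.simulate_choices(small_design, cohort, params=ref_params, seed=7)
    filtered, _ = sp.apply_sample_filters(ds)
    return filtered


@pytest.fixture(scope="session")
def tiny_panel():
    """Hand-built 2-respondent x 2-task panel with one random coefficient.

    Features: [x, optout flag, left flag]; n_random = 2 (x and the opt-out
    constant), the left flag carries the fixed constant.
    """
    X = np.zeros((2, 2, 3, 3))
    X[:, :, 2, 1] = 1.0  # opt-out indicator on alternative 2
    X[:, :, 0, 2] = 1.0  # left flag on alternative 0
    # attribute feature x for (resp, task, alt in {left, right})
    X[0, 0, 0, 0], X[0, 0, 1, 0] = 1.0, 0.0
    X[0, 1, 0, 0], X[0, 1, 1, 0] = 0.0, 1.0
    X[1, 0, 0, 0], X[1, 0, 1, 0] = 1.0, 1.0
    X[1, 1, 0, 0], X[1, 1, 1, 0] = 0.0, 0.0
    chosen = np.array([[0, 2], [1, 0]])
    mask = np.ones((2, 2), dtype=bool)
    return sp.PanelArrays(
        X=X,
        chosen=chosen,
        mask=mask,
        resp_ids=np.array([1, 2]),
        feature_names=["x", "optout", "left_const"],
    )
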