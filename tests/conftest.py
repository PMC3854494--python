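import numpy as np
import pytest

from facegeo.synthetic import SyntheticConfig, generate_cohort, make_template_face


@pytest.fixture(scope="session")
def template():
    return make_template_face(n_dense_points=600)


@pytest.fixture(scope="session")
def cohort_small():
    """80 individuals, 600 dense points, planted rs642961 effect, seed 7."""
    cfg = SyntheticConfig(
        n_individuals=80, panel_sizes=(40, 40), females_per_panel=None,
        sex_ratio=0.5, n_dense_points=600, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
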