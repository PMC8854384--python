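import numpy as np
import pytest

from dynet.pipeline import AnalysisConfig, run_synthetic_study


@pytest.fixture(scope="session")
def study():
    """Full synthetic two-group study at the desk-scale conditions.

    20 subjects per group, 60 regions, 200 timepoints; shared across the
    pipeline-level and acceptance tests so the (~1 min) analysis runs once.
    """
    return run_synthetic_study(
        n_per_group=20,
        n_regions=60,
        n_timepoints=200,
        seed=7,
        config=AnalysisConfig(n_perm=5000),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
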