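import numpy as np
import pytest

from hrvchaos import pipeline, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded 27-participant x 5-set synthetic cohort."""
    manifest, series = synthetic.generate_cohort(27, 5, seed=0)
    return manifest, series


@pytest.fixture(scope="session")
def cohort_results(default_cohort):
    """Full pipeline outputs (index table, comparisons, CIR) on the default cohort."""
    _, series = default_cohort
    return pipeline.run_pipeline(list(series.values()))


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant x 2-set cohort for fast structural tests."""
    manifest, series = synthetic.generate_cohort(4, 2, seed=11)
    return manifest, series


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
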