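import numpy as np
import pytest

from posturekit.norms import SEX_NORMS
from posturekit.skeleton import StickFigure, figure_to_capture
from posturekit.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def mean_male_params():
    """Noise-free parameter set at the male normative means."""
    return {name: mu for name, (mu, _) in SEX_NORMS["M"].items()}


@pytest.fixture(scope="session")
def mean_male_figure(mean_male_params):
    return StickFigure(mean_male_params)


@pytest.fixture(scope="session")
def mean_male_captures(mean_male_figure):
    return {
        view: figure_to_capture(mean_male_figure, view, "mean_male", 1)
        for view in ("frontal", "dorsal", "lateral")
    }


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject zero-jitter landmark cohort with a 5-subject retest."""
    spec = SyntheticSpec(n_subjects=12, seed=42, jitter_sd=0.0, retest_n=5)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
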