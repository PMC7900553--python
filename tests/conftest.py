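import numpy as np
import pytest

from histomut.experiments import median_signal_auc
from histomut.synthetic import SynthParams, default_color_model, generate_slide
from histomut.io import BiomarkerLabelVector

#: Seeds of the synthetic cohorts used by the end-to-end experiments.
EXPERIMENT_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def signal_runs():
    """Twofold-CV runs on cohorts with a large morphology effect (δ=1)."""
    return median_signal_auc(1.0, EXPERIMENT_SEEDS)


@pytest.fixture(scope="session")
def null_runs():
    """Twofold-CV runs on cohorts with no label effect (δ=0)."""
    return median_signal_auc(0.0, EXPERIMENT_SEEDS)


@pytest.fixture(scope="session")
def mid_runs():
    """Twofold-CV runs at an intermediate effect size (δ=0.4)."""
    return median_signal_auc(0.4, EXPERIMENT_SEEDS[:3])


@pytest.fixture
def color_model():
    return default_color_model()


@pytest.fixture
def wild_type_label():
    return BiomarkerLabelVector((0,) * 8)


@pytest.fixture
def synthetic_slide(wild_type_label):
    """A single 256x256 synthetic slide plus its generator truth."""
    params = SynthParams(seed=7)
    return generate_slide(params, wild_type_label, seed=1, slide_id="fix")
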