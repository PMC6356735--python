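import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msifusion as mf
from msifusion.classifiers import TrainingConfig
from msifusion.experiments import NoisePair, run_family_study, train_systems

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_setup() -> mf.BimodalSetup:
    """A 4-class miniature of the audiovisual task for fast unit tests."""
    return mf.BimodalSetup(
        auditory=mf.make_auditory_prototypes(4, 8000.0, 256, prototype_seed=1),
        visual=mf.make_visual_prototypes(4, 16, 16),
        feature_dim=12,
        mlp_config=TrainingConfig(hidden_sizes=(16,), max_epochs=400, seed=0),
    )


@pytest.fixture(scope="session")
def paper_setup() -> mf.BimodalSetup:
    """The full-scale study conditions: 10 digits, 64x64 images, 4000-sample audio."""
    return mf.default_setup()


@pytest.fixture(scope="session")
def clean_trained(paper_setup):
    """All eight systems trained on a short clean-to-mild-noise ladder."""
    ladder = [NoisePair(0.0, 0.0, 1.0), NoisePair(1.5, 17.0, 0.9)]
    return train_systems(paper_setup, ladder, n_train_per_class=10, seed=3)


@pytest.fixture(scope="session")
def study(paper_setup):
    """The scaled-down noise sweep for both classifier families.

    Five paired noise levels, 10 train + 10 test stimuli per class,
    5 replicate seeds — shared across the acceptance tests.
    """
    out = {}
    for family in ("MLP", "MAP"):
        result, sig, pairs = run_family_study(paper_setup, family.lower(), seed=0)
        out[family] = {"result": result, "significance": sig, "pairs": pairs}
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
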