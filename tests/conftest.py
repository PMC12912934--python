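from pathlib import Path

import numpy as np
import pytest

from espi.effect_size import GroupSample

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def tiny_study_path() -> Path:
    return DATA_DIR / "tiny_study.csv"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_groups(rng, k=3, n=10, means=None, sds=None):
    """Random normal GroupSamples for screen/ANOVA tests."""
    means = means if means is not None else np.zeros(k)
    sds = sds if sds is not None else np.ones(k)
    return [GroupSample(rng.normal(means[i], sds[i], n)) for i in range(k)]
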