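import numpy as np
import pytest

from trapcount.config import PipelineConfig
from trapcount.geometry import Box
from trapcount.structures import Detection, GroundTruthBox


def det(xmin, ymin, xmax, ymax, label="diamondback moth", confidence=0.9) -> Detection:
    return Detection(box=Box(xmin, ymin, xmax, ymax), label=label, confidence=confidence)


def gt(xmin, ymin, xmax, ymax, label="diamondback moth") -> GroundTruthBox:
    return GroundTruthBox(box=Box(xmin, ymin, xmax, ymax), label=label)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
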