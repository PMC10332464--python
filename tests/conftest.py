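import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from flyfi.synth import NoiseModel, SyntheticBrainConfig
from flyfi.synth.brain import ClusterSpec


@pytest.fixture(scope="session")
def default_hemisphere():
    """Default single-hemisphere brain (seed 42): stack, truth, rois."""
    from flyfi.synth import generate_brain

    cfg = SyntheticBrainConfig().single_hemisphere("R")
    return cfg, generate_brain(cfg, "control", seed=42)


@pytest.fixture
def tiny_config():
    """One PAL neuron in a small quiet stack — fast measurement fixture."""
    return SyntheticBrainConfig(
        image_shape=(31, 48, 48),
        clusters=(ClusterSpec("PAL", 1, (24.0, 24.0, 15.0), 3.0),),
        background_level=0.0,
        noise=NoiseModel(gaussian_sd=0.0),
        hemispheres=("R",),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1)
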