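"""Shared fixtures: synthetic scenario bundles generated once per session."""

import numpy as np
import pytest

from drmchip import PipelineConfig
from drmchip.simulate import ScenarioParams, generate_scenario


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study conditions (per-subunit detection 0.9)."""
    return generate_scenario(ScenarioParams(), seed=42)


@pytest.fixture(scope="session")
def perfect_bundle():
    """Detection probability 1.0: every planted site is called everywhere."""
    return generate_scenario(ScenarioParams(detection_prob=1.0), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
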