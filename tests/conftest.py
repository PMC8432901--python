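"""Shared fixtures: canonical parameter sets and cached simulation runs."""

import numpy as np
import pytest

from wccrit.model import ModelParams


@pytest.fixture(scope="session")
def critical_params() -> ModelParams:
    """The near-critical operating point studied throughout: w0 = w0c."""
    return ModelParams.from_balance(0.1, 13.8, h=1e-6, n=10**5)


@pytest.fixture(scope="session")
def supercritical_params() -> ModelParams:
    """Strongly excitation-dominated point (w0 = 1), far from criticality."""
    return ModelParams.from_balance(1.0, 13.8, h=1e-5, n=10**5)


@pytest.fixture(scope="session")
def offcritical_params() -> ModelParams:
    """Moderately supercritical point (w0 = 0.2) with a finite input."""
    return ModelParams.from_balance(0.2, 13.8, h=1e-3, n=10**4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
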