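"""Shared fixtures: default parameters, baseline equilibrium, linearized
pathway models, and the normalized study stimulus."""

import numpy as np
import pytest

from nvugrey import (
    NVUParameters,
    StimulusWaveform,
    find_equilibrium,
    jacobian_linearize,
)


@pytest.fixture(scope="session")
def params():
    return NVUParameters.default()


@pytest.fixture(scope="session")
def equilibrium(params):
    eq = find_equilibrium(params)
    assert eq.residual < 1e-8
    return eq


@pytest.fixture(scope="session")
def pathway_models(params, equilibrium):
    return {pw: jacobian_linearize(params, equilibrium.state, pw)
            for pw in (1, 2, 3, 4)}


@pytest.fixture(scope="session")
def study_stimulus():
    """Normalized 150-s analysis-window stimulus (30 s ramp + plateau)."""
    return StimulusWaveform(amplitude=1.0, ramp_up=30.0, plateau=120.0,
                            ramp_down=0.0, sampling_rate=10.0).normalize()


@pytest.fixture(scope="session")
def study_input(study_stimulus):
    u = study_stimulus.value(np.arange(1501) * 0.1)
    return u
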