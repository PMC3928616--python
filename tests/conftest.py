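"""Shared fixtures: meshes and solves reused across test modules.

Everything is generated programmatically and seeded; the heavier MEA
meshes are session-scoped so geometry, field and scenario tests share
them.
"""

import numpy as np
import pytest

from neurostimfem.geometry import (MEAParams, NeuronGeometrySpec,
                                   build_mea_chamber, embed_neuron_surface)


@pytest.fixture(scope="session")
def mea_params():
    return MEAParams()


@pytest.fixture(scope="session")
def mea_mesh(mea_params):
    """Default 60-electrode chamber mesh."""
    return build_mea_chamber(mea_params, seed=0)


@pytest.fixture(scope="session")
def fiber_spec(mea_params):
    stim = mea_params.central_electrode
    cx, cy = mea_params.electrode_center(stim)
    return NeuronGeometrySpec.fiber_above((cx, cy), 50e-6, 260e-6, 2e-6)


@pytest.fixture(scope="session")
def fiber_mesh(mea_params, fiber_spec):
    """Chamber with the 260-um fiber membrane embedded."""
    return embed_neuron_surface(mea_params, fiber_spec, seed=0, h_stim=5e-6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
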