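import numpy as np
import pytest
from hypothesis import settings

from fragmon.workflows import pmma_box_setup, sphere_setup, profile_edges

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def box_setup():
    return pmma_box_setup()


@pytest.fixture(scope="session")
def box_edges(box_setup):
    beam, phantom, model, _ = box_setup
    return profile_edges(beam, phantom, model)


@pytest.fixture(scope="session")
def sphere_case():
    return sphere_setup()


@pytest.fixture(scope="session")
def box_chain(box_setup):
    """One reconstructed sample in the homogeneous-PMMA reference setup."""
    from fragmon.pipeline import run_chain

    beam, phantom, model, tracker = box_setup
    return run_chain(beam, phantom, model, tracker, 20000, seed=101)


@pytest.fixture(scope="session")
def small_lut(sphere_case):
    """A coarse absorption LUT for the sphere system (kept small for speed)."""
    from fragmon.unfolding import build_lut
    from fragmon.workflows import SPHERE_LUT_THICKNESSES

    beam, phantom, model, tracker = sphere_case
    return build_lut(beam, phantom, tracker, model,
                     thicknesses=SPHERE_LUT_THICKNESSES,
                     n_tracks=8000, seed=202)
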