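"""Shared fixtures: one seeded fish phantom and its simulated cube.

The phantom (seed 7) and its Poisson realization (seed 11) are the
study conditions used across the phantom-based tests; session scope so
the forward simulation and the per-pixel decomposition run once.
"""

import numpy as np
import pytest

from paleoxrf.decomposition import LineModel, element_maps
from paleoxrf.phantom import (
    BEAM_ENERGY_KEV,
    expected_class_spectra,
    forward_spectra,
    make_phantom,
)

PHANTOM_SEED = 7
NOISE_SEED = 11


@pytest.fixture(scope="session")
def fish_phantom():
    return make_phantom((128, 96), "fish", seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def fish_cube(fish_phantom):
    return forward_spectra(fish_phantom, seed=NOISE_SEED)


@pytest.fixture(scope="session")
def fish_expected(fish_phantom):
    expected, model, cal = expected_class_spectra(fish_phantom)
    return expected


@pytest.fixture(scope="session")
def fish_line_model(fish_phantom):
    return LineModel.for_elements(fish_phantom.elements,
                                  beam_energy=BEAM_ENERGY_KEV)


@pytest.fixture(scope="session")
def fish_element_maps(fish_cube, fish_line_model):
    return element_maps(fish_cube, fish_line_model)


@pytest.fixture(scope="session")
def reference_pixels(fish_phantom):
    return fish_phantom.reference_pixels()


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
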