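"""Shared phantom fixtures.

The expensive fixtures (rendered acquisitions and their derived images) are
session-scoped and reused across test modules; every stack is generated at
run time from the synthetic module, so the suite needs no data files.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from vesselmorph.phase_gradient import mpg_from_offsets
from vesselmorph.preprocess import preprocess_acquisition
from vesselmorph.segmentation import segment_vessel
from vesselmorph.synthetic import (
    PhantomNoiseModel,
    inject_mural_edges,
    simulate_default_phantom,
)

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """Default-noise straight phantom, LD 120 um / W 16 um at 1 um/px."""
    return simulate_default_phantom(
        120.0, 16.0, seed=11, n_frames=30, usable_length_px=100.0
    )


@pytest.fixture(scope="session")
def small_derived(small_phantom):
    derived, reg = preprocess_acquisition(small_phantom.channels)
    return derived, reg


@pytest.fixture(scope="session")
def small_images(small_derived):
    derived, _ = small_derived
    mpg = mpg_from_offsets(derived)
    return derived["confocal"].std_image, mpg.pixels


@pytest.fixture(scope="session")
def small_seg(small_phantom, small_images):
    std, mpg = small_images
    return segment_vessel(std, mpg, small_phantom.seed_point)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Flow speckle only: no jitter, no shot noise, no background noise."""
    return simulate_default_phantom(
        120.0, 16.0, seed=7, noise=PhantomNoiseModel.noiseless(),
        n_frames=12, usable_length_px=100.0,
    )


@pytest.fixture(scope="session")
def noiseless_seg(noiseless_phantom):
    derived, _ = preprocess_acquisition(noiseless_phantom.channels)
    mpg = mpg_from_offsets(derived)
    return segment_vessel(
        derived["confocal"].std_image, mpg.pixels, noiseless_phantom.seed_point
    )


@pytest.fixture(scope="session")
def mural_phantom():
    """Phantom with three injected mural-cell edges inside the wall band."""
    acq = simulate_default_phantom(140.0, 18.0, seed=21, n_frames=30,
                                   usable_length_px=120.0)
    noise = replace(acq.noise, mural_edge_rate=3.0)
    return inject_mural_edges(acq, noise)


@pytest.fixture(scope="session")
def mural_images(mural_phantom):
    derived, _ = preprocess_acquisition(mural_phantom.channels)
    mpg = mpg_from_offsets(derived)
    return derived["confocal"].std_image, mpg.pixels


def mural_sample_mask(acq, seg) -> np.ndarray:
    """Boolean mask of segmentation samples lying on an injected edge."""
    s = acq.truth.nearest_arc(seg.trace.points)
    mask = np.zeros(s.size, dtype=bool)
    for edge in acq.mural_edges:
        mask |= edge.contains(s)
    return mask
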