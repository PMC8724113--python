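"""Shared fixtures: small seeded phantom populations.

Geometry is scaled down from the default 19 × 512 × 496 raster so the
suite stays fast; the generators keep proportions (pit depth, layer
thicknesses) consistent with the full-size configuration.
"""

import numpy as np
import pytest

import octsynth as oc


@pytest.fixture(scope="session")
def small_config():
    return oc.PhantomConfig.scaled(
        n_volumes=8, n_bscans=5, width=64, height=128, rng_seed=11
    )


@pytest.fixture(scope="session")
def phantom_surfaces(small_config):
    return oc.generate_surfaces(small_config)


@pytest.fixture(scope="session")
def landmarked(phantom_surfaces):
    vecs = []
    grid = None
    for s in phantom_surfaces:
        v, grid = oc.extract_landmarks(s, points_per_curve=15)
        vecs.append(v)
    return vecs, grid


@pytest.fixture(scope="session")
def trained_model(landmarked):
    vecs, grid = landmarked
    aligned, _ = oc.align_shapes(vecs)
    return oc.build_pdm(aligned, variance_fraction=0.94), grid


@pytest.fixture(scope="session")
def dme_config():
    return oc.PhantomConfig.scaled(
        n_volumes=1, n_bscans=1, width=64, height=160, rng_seed=21
    )


@pytest.fixture(scope="session")
def dme_library(dme_config):
    return oc.generate_dme_library(dme_config, n_references=6)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def flat_surfaces(depths, n_bscans=2, width=8, height=200, spacing=None):
    """SurfaceSet with each surface at a constant depth."""
    z = np.stack(
        [np.full((n_bscans, width), float(d)) for d in depths]
    )
    return oc.SurfaceSet(surfaces=z, axial_depth=height, spacing=spacing)
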