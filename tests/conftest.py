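"""Shared fixtures: small synthetic scenes generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from lfseg.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def scene2d():
    """Default noisy 2D scene: 60 contacting cells on a 256x256 grid."""
    return generate_scene(SceneParams(shape=(256, 256), n_cells=60, seed=7))


@pytest.fixture(scope="session")
def scene2d_clean():
    """Same geometry as a default scene but without blur or additive noise."""
    return generate_scene(
        SceneParams(shape=(256, 256), n_cells=60, seed=7, noise_sd=0.0, blur_sigma=0.0)
    )


@pytest.fixture(scope="session")
def scene2d_small():
    """Small scene for exhaustive-oracle comparisons (<=128^2)."""
    return generate_scene(
        SceneParams(shape=(96, 96), n_cells=12, mean_cell_diameter=16, seed=3)
    )


@pytest.fixture(scope="session")
def scene3d():
    """3D scene with depth attenuation, 48^3 to keep tests quick."""
    return generate_scene(
        SceneParams(
            shape=(48, 48, 48),
            n_cells=30,
            mean_cell_diameter=14,
            nucleus_fraction=0.5,
            depth_attenuation=0.99,
            seed=9,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pipeline2d():
    """Full 2D desk-scale protocol, run once per session (~30 s)."""
    from lfseg.benchmarks import run_label_free_2d

    return run_label_free_2d(seed=0)


@pytest.fixture(scope="session")
def pipeline3d():
    """Full 3D desk-scale protocol, run once per session (~5 min)."""
    from lfseg.benchmarks import run_label_free_3d

    return run_label_free_3d(seed=0)


def truth_probabilities(scene) -> np.ndarray:
    """One-hot class probabilities from a scene's geometric ground truth."""
    geom = np.zeros(scene.truth.shape, dtype=int)
    geom[scene.truth > 0] = 2
    geom[scene.nuclei_truth > 0] = 1
    return np.stack([(geom == k).astype(float) for k in range(3)])
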