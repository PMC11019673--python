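"""Shared synthetic scenes for the test suite.

Session-scoped fixtures hold the expensive renders (the default ~500
bead noisy scene and its measured records) so unit and acceptance tests
share one computation.
"""

import numpy as np
import pytest

from opmcal import psf, scene


@pytest.fixture(scope="session")
def default_scene():
    """Default noisy PSF scene: ~500 beads across an 88 µm field."""
    truth = scene.generate_bead_field((88.0, 88.0, 1.0), 500, 2.5, seed=101)
    geometry = scene.StackGeometry(nx=820, ny=820, n_planes=54)
    stack = scene.render_stack(truth, geometry, seed=202)
    return truth, geometry, stack


@pytest.fixture(scope="session")
def default_scene_records(default_scene):
    truth, _, stack = default_scene
    return psf.measure_psfs(stack)


@pytest.fixture(scope="session")
def small_noisefree_scene():
    """Small noise-free scene for estimator-bias checks."""
    truth = scene.generate_bead_field((12.0, 12.0, 0.4), 5, 3.0, seed=3)
    geometry = scene.StackGeometry(nx=140, ny=140, n_planes=54)
    stack = scene.render_stack(truth, geometry, noise=None)
    return truth, stack


def match_to_truth(record, truth):
    """Index of the nearest true bead (lateral distance)."""
    d = np.hypot(truth.positions[:, 0] - record.x, truth.positions[:, 1] - record.y)
    return int(np.argmin(d)), float(d.min())
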