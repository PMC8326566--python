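"""Shared fixtures: small geometries and cached phantom objects.

Expensive phantom/registration artifacts are session-scoped so several tests
can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import aslnorm as an
from aslnorm.image_core import ImageGeometry, VolumetricImage, centered_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry() -> ImageGeometry:
    return centered_geometry((10, 10, 10), (2.0, 2.0, 2.0))


@pytest.fixture
def random_volume(small_geometry, rng) -> VolumetricImage:
    return VolumetricImage(
        small_geometry, rng.uniform(0, 100, small_geometry.shape), "cbf_ml_per_100g_min"
    )


@pytest.fixture(scope="session")
def default_template():
    return an.make_template()


@pytest.fixture(scope="session")
def default_subject():
    """Default-condition synthetic subject: 4 mm random warp, size and rigid
    offsets, noise sigma 5 ml/100 g/min."""
    return an.make_subject(an.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def dct_result(default_subject):
    """Full two-iteration nonlinear normalization of the default subject."""
    return an.normalize_asl(
        default_subject.native_cbf, default_subject.template, "dct"
    )
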