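"""Shared fixtures: phantom pools and trained detectives.

Session scope keeps the expensive pieces (image generation, ensemble
training) shared across test modules; every fixture is fully seeded so the
suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from adadetect import (
    ADASpec,
    DetectiveConfig,
    PhantomSpec,
    build_detective_trainset,
    generate_labeled_dataset,
    train_detective,
)

BLUR_SPEC = ADASpec("sharpness", blur_sigma=1.0)
CONTRAST_SPEC = ADASpec("contrast", gamma=1.3)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def pool600(phantom_spec):
    """Disease-free training pool (600 images, 64x64)."""
    return generate_labeled_dataset(600, phantom_spec, seed=101)


@pytest.fixture(scope="session")
def fresh400(phantom_spec):
    """Held-out shortcut-free set for Exam 2 analogs."""
    return generate_labeled_dataset(400, phantom_spec, seed=102)


@pytest.fixture(scope="session")
def fresh1000(phantom_spec):
    """Larger shortcut-free set for Exam 1 analogs."""
    return generate_labeled_dataset(1000, phantom_spec, seed=103)


@pytest.fixture(scope="session")
def blur_detective(pool600):
    trainset = build_detective_trainset(pool600.images, BLUR_SPEC, seed=201)
    return train_detective(trainset, DetectiveConfig(seed=202))


@pytest.fixture(scope="session")
def contrast_detective(pool600):
    trainset = build_detective_trainset(pool600.images, CONTRAST_SPEC, seed=203)
    return train_detective(trainset, DetectiveConfig(seed=204))


@pytest.fixture()
def ramp_image():
    """Smooth horizontal intensity ramp, 32x32."""
    row = np.linspace(10, 245, 32)
    return np.tile(row, (32, 1)).astype(np.uint8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
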