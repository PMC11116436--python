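"""Shared fixtures: small, fast phantoms rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from coroquant.phantom import (
    MotionSpec,
    PhantomSpec,
    StenosisSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A 256 px, 40-frame phantom with one 60% mid-RCA stenosis and motion."""
    spec = PhantomSpec(
        image_size=256,
        n_frames=40,
        stenoses=[StenosisSpec("mid-RCA", 0.5, 60.0)],
        motion=MotionSpec(cardiac_amp=(6.0, 5.0), respiratory_amp=(2.0, 3.0)),
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def static_phantom():
    """A motionless, noise-free phantom with full contrast throughout."""
    spec = PhantomSpec(
        image_size=256,
        n_frames=12,
        stenoses=[StenosisSpec("mid-RCA", 0.5, 50.0)],
        motion=MotionSpec(cardiac_amp=(0.0, 0.0), respiratory_amp=(0.0, 0.0)),
        wash_in_frames=0,
        wash_out_start_frac=1.0,
        noise_sigma=0.0,
        n_distractors=0,
        seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
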