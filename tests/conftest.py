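"""Shared fixtures: small phantom instances and helper factories."""

from __future__ import annotations

import numpy as np
import pytest

from otoseg.io_core import LandmarkSet, Volume
from otoseg.phantom import generate_phantom, small_cohort, small_phantom_spec


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 32-cube phantom (volume, label, landmarks)."""
    return generate_phantom(small_phantom_spec(seed=42))


@pytest.fixture(scope="session")
def phantom64():
    """One deterministic 64-cube phantom."""
    from otoseg.phantom import PhantomSpec

    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_instances():
    """Preprocessed 32-cube cohort as (image, label, landmarks) triples."""
    from otoseg.preprocess import preprocess_internal

    out = []
    for vol, lab, lms in small_cohort(4, seed=5):
        pv, _ = preprocess_internal(vol)
        out.append((pv.data, lab.data, lms))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(10, 11, 12), spacing=(99.0, 99.0, 99.0)) -> Volume:
    return Volume(data=rng.normal(size=shape).astype(np.float32), spacing=spacing)


def random_landmarks(rng, shape) -> LandmarkSet:
    hi = np.asarray(shape) - 1
    pts = rng.uniform(0, hi, size=(3, 3))
    return LandmarkSet(helicotrema=pts[0], oval_window=pts[1], round_window=pts[2])
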