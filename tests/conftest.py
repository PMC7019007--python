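"""Shared fixtures: phantom pairs are expensive to render, so they are built
once per session and treated as read-only by every test."""

from __future__ import annotations

import numpy as np
import pytest

from cnscoreg.core import Centerline
from cnscoreg.phantom import (
    default_brain_spec,
    default_cord_spec,
    render_brain_phantom,
    render_cord_phantom,
)


@pytest.fixture(scope="session")
def cord_pair():
    """Noiseless curved-cord phantom pair with ground truth."""
    return render_cord_phantom(default_cord_spec(seed=11))


@pytest.fixture(scope="session")
def noisy_cord_pair():
    """Cord phantom at SNR 10 (noise sigma = tissue level / 10)."""
    return render_cord_phantom(default_cord_spec(seed=11, noise_sigma_high=18.0))


@pytest.fixture(scope="session")
def brain_pair():
    """Brain phantom pair with the known similarity misalignment."""
    return render_brain_phantom(default_brain_spec(seed=11))


def rms_distance_to_curve(points: np.ndarray, curve: Centerline) -> tuple[float, float]:
    """(RMS, max) Euclidean distance (µm) from each point to the curve."""
    d = np.array(
        [
            np.linalg.norm(curve.point_at(curve.nearest_arclength(p[None, :]))[0] - p)
            for p in np.atleast_2d(points)
        ]
    )
    return float(np.sqrt((d**2).mean())), float(d.max())
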