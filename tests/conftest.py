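"""Shared fixtures: small phantoms and a single-tube analysis runner."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lumenmorph import (
    PhantomSpec,
    add_noise,
    extract_axis_profile,
    local_thickness,
    make_phantom,
    measure_periodicity,
    preprocess,
    radius_map,
    segment_lumina,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_mask(rng: np.random.Generator, shape, density=None) -> np.ndarray:
    """Random boolean mask with at least one background pixel."""
    density = rng.uniform(0.2, 0.8) if density is None else density
    m = rng.random(shape) < density
    if m.all():
        m[(0,) * m.ndim] = False
    return m


@pytest.fixture(scope="session")
def straight_tube():
    """Noise-free straight tube: r = 1 µm, L = 20 µm, 0.1 µm/px, no stripes."""
    spec = PhantomSpec(
        shape_kind="tube", spacing=(0.1, 0.1), tube_radius=1.0,
        tube_length=20.0, bulkhead_spacing=0.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def cyst_8um():
    """Noise-free spherical cyst of radius 8 µm at 0.1 µm/px."""
    spec = PhantomSpec(shape_kind="cyst", spacing=(0.1, 0.1), cyst_radius=8.0)
    return make_phantom(spec)


def run_tube_periodicity(seed, bulkhead_spacing=2.0, jitter=0.0, snr=5.0,
                         min_prominence=0.2):
    """Full single-tube chain: phantom -> noise -> segment -> periodicity.

    Returns None when segmentation does not yield exactly one object
    (callers count such replicates as failures where appropriate).
    """
    spec = PhantomSpec(
        spacing=(0.1, 0.1), tube_radius=1.0, tube_length=20.0,
        bulkhead_spacing=bulkhead_spacing, bulkhead_jitter=jitter,
        noise_gaussian_sd=(100.0 - 10.0) / snr, seed=seed,
    )
    img, _ = make_phantom(spec)
    noisy = add_noise(img, spec)
    pre = preprocess(noisy, smooth_sigma=0.2, ball_radius=10.0)
    labels = segment_lumina(pre)
    if labels.n_objects != 1:
        return None
    tmap = local_thickness(labels.labels > 0, labels.spacing)
    profile = extract_axis_profile(labels, pre, radius_map(tmap), 1)
    return measure_periodicity(profile, min_prominence=min_prominence)
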