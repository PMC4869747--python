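"""Shared fixtures: kernel bank and standard synthetic scenes."""

import math

import numpy as np
import pytest

from fibermech.segmentation import build_kernel_bank
from fibermech.synthetic import (
    Fiber,
    SyntheticImageSpec,
    bright_dots,
    fiber_field,
    render_image,
)


@pytest.fixture(scope="session")
def bank():
    return build_kernel_bank()


@pytest.fixture(scope="session")
def single_fiber_scene():
    """One 30-degree fiber on a dome background with mild noise."""
    spec = SyntheticImageSpec(
        shape=(160, 160), cell_center=(79.5, 79.5), cell_semi_axes=(70, 70),
        noise_sigma=2.0, background_amplitude=50, seed=1,
    )
    spec.fibers = (Fiber(center=(79.5, 79.5), theta_deg=30, length_px=80),)
    return render_image(spec)


def standard_cell_spec(seed, n_fibers=30, n_dots=20, noise=2.0):
    """The polarized-cell scene used for pipeline recovery checks.

    One near-parallel fiber family spanning a large elliptical cell, with
    bright dots placed away from fibers so every pixel has an unambiguous
    label.
    """
    rng = np.random.default_rng(seed)
    spec = SyntheticImageSpec(
        shape=(512, 512), pixel_size_um=0.3, cell_semi_axes=(230, 170),
        noise_sigma=noise, seed=seed, nucleus_radius_px=45,
    )
    spec.fibers = tuple(fiber_field(n_fibers, None, 0.0, spec, rng,
                                    n_families=1, length_px=(150, 210)))
    if n_dots:
        spec.dots = tuple(bright_dots(n_dots, spec, rng,
                                      min_fiber_distance_px=9.0))
    return spec


@pytest.fixture(scope="session")
def standard_cell():
    return render_image(standard_cell_spec(seed=5))


@pytest.fixture(scope="session")
def standard_quant(standard_cell):
    from fibermech.pipeline import QuantifyConfig, quantify_image

    return quantify_image(standard_cell.image, QuantifyConfig(pixel_size_um=0.3))


@pytest.fixture(scope="session")
def annulus_scene():
    """Tangential fibers concentrated at 70 percent of the cell radius."""
    rng = np.random.default_rng(1)
    spec = SyntheticImageSpec(
        shape=(384, 384), pixel_size_um=0.3, cell_center=(191.5, 191.5),
        cell_semi_axes=(150, 150), noise_sigma=2.0, seed=1,
        nucleus_radius_px=35,
    )
    fibers = []
    for _ in range(24):
        phi = rng.uniform(0, 2 * math.pi)
        rad = 0.70 * 150
        center = (191.5 + rad * math.cos(phi), 191.5 + rad * math.sin(phi))
        tangent = math.degrees(math.atan2(math.cos(phi), -math.sin(phi))) % 180
        fibers.append(Fiber(center=center, theta_deg=tangent, length_px=40,
                            intensity=rng.uniform(60, 120)))
    spec.fibers = tuple(fibers)
    return render_image(spec)
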