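"""Shared fixtures: synthetic frames, outlines and periodic translations."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from zygoflow._geom import unit_direction
from zygoflow.outline import Outline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def periodic_shift(img: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Exact (sub-pixel, periodic) rigid translation via the Fourier domain."""
    return np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(img), (dr, dc))))


@pytest.fixture
def textured_frame(rng):
    """Factory for smooth random texture with good PIV contrast."""
    def make(shape=(256, 256), sigma=1.5, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return gaussian_filter(r.random(shape), sigma)
    return make


def disk_image(radius, centre=None, shape=(300, 300), inside=0.8, outside=0.1):
    """Bright disk on a dark background (a step edge at the boundary)."""
    H, W = shape
    if centre is None:
        centre = (H / 2.0, W / 2.0)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    rho = np.hypot(rr - centre[0], cc - centre[1])
    return np.where(rho < radius, inside, outside).astype(float)


def ellipse_image(a, b, orientation_deg=0.0, centre=None, shape=(512, 512),
                  inside=0.8, outside=0.1):
    """Filled ellipse with semi-axes ``a`` (along orientation) and ``b`` in px."""
    H, W = shape
    if centre is None:
        centre = (H / 2.0, W / 2.0)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    theta = np.deg2rad(
        np.degrees(np.arctan2(cc - centre[1], -(rr - centre[0]))) - orientation_deg
    )
    rho = np.hypot(rr - centre[0], cc - centre[1])
    r_b = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return np.where(rho < r_b, inside, outside).astype(float)


def polygon_outline(radius_fn, centre=(150.0, 150.0), n=360, frame_index=0):
    """Outline whose radius at angle theta (deg) is ``radius_fn(theta)`` px."""
    theta = np.arange(n) * (360.0 / n)
    r = np.asarray(radius_fn(theta), dtype=float)
    d = unit_direction(theta)
    return Outline(np.asarray(centre) + d * r[:, None], frame_index=frame_index)


def circle_outline(radius_px, centre=(150.0, 150.0), n=360):
    return polygon_outline(lambda t: np.full_like(np.asarray(t, float), radius_px),
                           centre=centre, n=n)


def ellipse_outline(a_px, b_px, orientation_deg=0.0, centre=(150.0, 150.0), n=360):
    def rfn(theta):
        d = np.deg2rad(np.asarray(theta) - orientation_deg)
        return a_px * b_px / np.sqrt((b_px * np.cos(d)) ** 2 + (a_px * np.sin(d)) ** 2)
    return polygon_outline(rfn, centre=centre, n=n)
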