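"""Shared geometric fixtures: rasterized discs, annuli, tubes, lattices.

All fixtures are generated programmatically; shapes are centred on an
integer pixel so distance-transform thickness estimates are unbiased.
"""

import numpy as np
import pytest


def disc_mask(radius, size=None, center=None):
    size = size or 2 * int(radius) + 11
    c = center if center is not None else size // 2
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def annulus_mask(r_outer, r_inner, size=None):
    size = size or 2 * int(r_outer) + 11
    return disc_mask(r_outer, size) & ~disc_mask(r_inner, size)


def ellipse_mask(a, b, size=None, angle_deg=0.0):
    size = size or 2 * int(max(a, b)) + 11
    c = size // 2
    yy, xx = np.mgrid[:size, :size].astype(float)
    yy, xx = yy - c, xx - c
    if angle_deg:
        th = np.radians(angle_deg)
        xx, yy = xx * np.cos(th) + yy * np.sin(th), -xx * np.sin(th) + yy * np.cos(th)
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


def ball_mask(radius, size=None):
    size = size or 2 * int(radius) + 9
    c = size // 2
    zz, yy, xx = np.mgrid[:size, :size, :size]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def tube_stack(n_slices, r_outer, r_inner, size=None):
    """Uniform circular tube along axis 0."""
    ann = annulus_mask(r_outer, r_inner, size)
    return np.broadcast_to(ann, (n_slices,) + ann.shape).copy()


def plate_lattice_2d(size, thickness, period):
    """Vertical parallel plates spanning the full height, clear of the
    left/right borders so each plate has two measurable faces.

    Returns ``(lattice, roi)`` where the roi covers a whole number of
    periods, so the analytic area fraction is exactly thickness/period.
    """
    _, xx = np.mgrid[:size, :size]
    start = period // 2
    n_periods = (size - start) // period
    roi = (xx >= start) & (xx < start + n_periods * period)
    lattice = (((xx - start) % period) < thickness) & roi
    return lattice, roi


@pytest.fixture(scope="session")
def annulus_50_40():
    return annulus_mask(50, 40)


@pytest.fixture(scope="session")
def ball_20():
    return ball_mask(20)
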