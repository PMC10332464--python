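"""Independent oracles shared by unit and acceptance tests.

Everything here is deliberately written from first principles (scalar
loops, closed forms, simulation) and must stay independent of the
package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def point_in_polygon_evenodd(px: float, py: float, poly) -> bool:
    """Scalar even-odd ray-cast: is (px, py) inside the polygon?"""
    inside = False
    n = len(poly)
    for i in range(n):
        xa, ya = poly[i]
        xb, yb = poly[(i + 1) % n]
        if (ya > py) != (yb > py):
            x_int = xa + (py - ya) * (xb - xa) / (yb - ya)
            if px < x_int:
                inside = not inside
    return inside


def roi_measurement_bruteforce(plane: np.ndarray, poly):
    """Exhaustive pixel-center enumeration: (area_px, intensity_sum)."""
    h, w = plane.shape
    area, total = 0, 0.0
    for y in range(h):
        for x in range(w):
            if point_in_polygon_evenodd(float(x), float(y), poly):
                area += 1
                total += float(plane[y, x])
    return area, total


def random_star_polygon(rng: np.random.Generator, center, r_min, r_max,
                        n_vertices=None):
    """Random star-shaped (hence simple) polygon around ``center``.

    Consecutive angular gaps are bounded so every gap is < pi, which
    guarantees each edge stays inside its angular wedge and no two
    edges can cross.
    """
    if n_vertices is None:
        n_vertices = int(rng.integers(4, 10))
    gaps = rng.uniform(0.6, 1.4, n_vertices)
    angles = rng.uniform(0, 2 * math.pi) + np.cumsum(
        gaps / gaps.sum() * 2.0 * math.pi)
    radii = rng.uniform(r_min, r_max, n_vertices)
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(angles),
                            cy + radii * np.sin(angles)])


def gaussian_window_integral(amplitude, sigma, roi_radius, z_offsets):
    """Analytic blob mass inside a cylinder: radius ``roi_radius`` in-plane,
    one disc per z offset (in voxel units)."""
    plane = 2.0 * math.pi * sigma**2 * (
        1.0 - math.exp(-(roi_radius**2) / (2.0 * sigma**2)))
    return amplitude * plane * sum(
        math.exp(-(dz**2) / (2.0 * sigma**2)) for dz in z_offsets)


def studentized_range_quantile_mc(span, df, q_level, n_draws, seed):
    """Monte-Carlo quantile of the studentized range of ``span`` iid
    standard-normal means over an independent rms error with ``df``
    degrees of freedom (the Newman-Keuls null)."""
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_draws, span))
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    q = (means.max(axis=1) - means.min(axis=1)) / s
    return float(np.quantile(q, q_level))
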