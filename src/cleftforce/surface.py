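"""Sphere-point sampling shared by SASA and surface-potential export."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["golden_spiral_points", "accessible_points"]


def golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points via the golden-spiral lattice.

    Deterministic, so repeated SASA evaluations are bit-identical.
    """
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def accessible_points(coords: np.ndarray, radii: np.ndarray, probe: float,
                      n_points: int):
    """Per-atom solvent-accessible test points (Shrake–Rupley core).

    For each atom, ``n_points`` points are placed on its expanded sphere of
    radius ``r_i + probe``; a point is accessible if it lies outside every
    other atom's expanded sphere.  Returns ``(counts, points)`` where
    ``counts[i]`` is the number of accessible points of atom ``i`` and
    ``points[i]`` the (m_i, 3) array of their coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = coords.shape[0]
    unit = golden_spiral_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    counts = np.zeros(n_atoms, dtype=int)
    points: list[np.ndarray] = []
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            free &= d > expanded[j]
        counts[i] = int(free.sum())
        points.append(pts[free])
    return counts, points
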