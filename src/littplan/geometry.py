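"""Voxel-grid and world-space geometry primitives.

Conventions used throughout the package:

* World coordinates are RAS+ millimetres (x right, y anterior, z superior).
* A voxel is represented by its centre; NIfTI affines map 0-based voxel
  indices to world coordinates.
* "Medial" means toward the ``x = 0`` mid-sagittal plane.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "voxel_to_world",
    "world_to_voxel",
    "spacing_from_affine",
    "segment_point_distance",
    "polyline_point_distance",
    "box_slices",
    "subgrid_world",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit length; raise on a zero vector."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("cannot normalize a zero-length vector")
    return v / n


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (``(..., 3)``) to world millimetres."""
    affine = np.asarray(affine, dtype=float)
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world millimetres to (fractional) voxel indices."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    """Voxel spacing in mm per axis (column norms of the linear part)."""
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


def segment_point_distance(points: np.ndarray, a, b) -> tuple[np.ndarray, np.ndarray]:
    """Distance from each point to the segment ``a``–``b``.

    Returns ``(dist, t)`` where ``t`` in [0, 1] is the clamped projection
    parameter of each point onto the segment.
    """
    points = np.asarray(points, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    denom = float(d @ d)
    if denom == 0.0:
        t = np.zeros(points.shape[:-1])
    else:
        t = np.clip(((points - a) @ d) / denom, 0.0, 1.0)
    closest = a + t[..., None] * d
    return np.linalg.norm(points - closest, axis=-1), t


def polyline_point_distance(points: np.ndarray, nodes) -> np.ndarray:
    """Minimum distance from each point to a polyline given by ``nodes``."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[0] < 2:
        raise ValueError("a polyline needs at least two nodes")
    best = np.full(np.asarray(points).shape[:-1], np.inf)
    for a, b in zip(nodes[:-1], nodes[1:]):
        d, _ = segment_point_distance(points, a, b)
        np.minimum(best, d, out=best)
    return best


def box_slices(shape, affine, lo, hi, margin: float = 1.0) -> tuple[slice, slice, slice]:
    """Voxel-index slices covering the world-space box ``[lo, hi]`` + margin.

    All eight corners of the box are mapped through the inverse affine so the
    result is correct for any invertible (not only axis-aligned) affine.
    """
    lo = np.asarray(lo, dtype=float) - margin
    hi = np.asarray(hi, dtype=float) + margin
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    ijk = world_to_voxel(affine, corners)
    start = np.maximum(np.floor(ijk.min(axis=0)).astype(int), 0)
    stop = np.minimum(np.ceil(ijk.max(axis=0)).astype(int) + 1, np.asarray(shape))
    start = np.minimum(start, stop)  # empty slice when box is fully outside
    return tuple(slice(int(a), int(b)) for a, b in zip(start, stop))


def subgrid_world(affine, slices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World x/y/z coordinate arrays for the voxel subgrid ``slices``.

    Built by broadcasting open index grids through the affine, so memory use
    is linear until the three coordinate components are materialized.
    """
    affine = np.asarray(affine, dtype=float)
    axes = [np.arange(s.start, s.stop, dtype=float) for s in slices]
    i = axes[0][:, None, None]
    j = axes[1][None, :, None]
    k = axes[2][None, None, :]
    m, t = affine[:3, :3], affine[:3, 3]
    coords = []
    for r in range(3):
        coords.append(m[r, 0] * i + m[r, 1] * j + m[r, 2] * k + t[r])
    x, y, z = np.broadcast_arrays(*coords)
    return x, y, z
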