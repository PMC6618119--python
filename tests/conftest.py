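"""Shared fixtures and independent geometric oracles.

The oracles here are deliberately naive (direct voxel-membership tests,
brute-force neighbour loops) so they stay independent of the package code
paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


def rotation_matrix_zyx(angles) -> np.ndarray:
    """Independent rotation construction for (z, y, x)-ordered vectors.

    Built from explicit 2D rotations, mirroring none of the package code.
    """
    ax, ay, az = angles

    def rot(i, j, t):
        m = np.eye(3)
        m[i, i] = math.cos(t)
        m[j, j] = math.cos(t)
        m[i, j] = -math.sin(t)
        m[j, i] = math.sin(t)
        return m

    # "about x" mixes (z, y) = components 0,1; "about y" mixes (z, x) = 0,2;
    # "about z" mixes (y, x) = 1,2
    return rot(1, 2, az) @ rot(0, 2, ay) @ rot(0, 1, ax)


def digital_ellipsoid(semi_axes, rotation=None, centre=None) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside a rotated ellipsoid.

    ``semi_axes`` in voxel units; this is the voxel-membership oracle used
    to validate both the phantom generator and the trait operators.
    """
    a = float(max(semi_axes))
    n = int(math.ceil(a)) + 2
    grid = np.arange(-n, n + 1, dtype=float)
    zz, yy, xx = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    if centre is not None:
        pts = pts - np.asarray(centre, dtype=float)
    if rotation is not None:
        pts = pts @ rotation
    q = np.sum((pts / np.asarray(semi_axes, dtype=float)) ** 2, axis=-1)
    return q <= 1.0


def brute_force_face_count(mask: np.ndarray) -> int:
    """Exposed 6-neighbour faces by an explicit per-voxel loop over a set."""
    voxels = {tuple(v) for v in np.argwhere(mask)}
    faces = 0
    for z, y, x in voxels:
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            if (z + dz, y + dy, x + dx) not in voxels:
                faces += 1
    return faces


@pytest.fixture(scope="session")
def small_phantom():
    """A 6-grain noise-free phantom at coarse (137.6 μm) voxels with ground
    truth, shared by segmentation and measurement tests."""
    from grainct import simgrain

    spec = simgrain.spike_phantom(
        6, voxel_size=137.6, noise_sd=0.0, blur_sigma=0.0, touching_fraction=0.0, seed=11
    )
    volume, labels = simgrain.generate_spike_volume(spec)
    return spec, volume, labels
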