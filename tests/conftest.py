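"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths: the
occupancy oracle counts voxel membership with explicit Python loops, the
superposition oracle solves the optimal rotation with Kearsley's quaternion
eigenvalue method (the package uses an SVD), and the curation oracle
re-states the two discard rules literally.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Occupancy oracle: triple loop over voxels, frames, atoms
# ---------------------------------------------------------------------------

def occupancy_oracle(points, origin, spacing, dims):
    """Per-voxel occupied-frame fraction by exhaustive membership testing.

    ``points``: (n_frames, n_atoms, 3).  A voxel is occupied in a frame iff
    some atom lies in its half-open cube.
    """
    points = np.asarray(points, float)
    n_frames = len(points)
    values = np.zeros(dims)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                lo = np.asarray(origin) + np.array([i, j, k]) * spacing
                hi = lo + spacing
                # membership of every atom of every frame in this one cube
                inside = ((points >= lo) & (points < hi)).all(axis=2)
                values[i, j, k] = inside.any(axis=1).sum() / n_frames
    return values


# ---------------------------------------------------------------------------
# Superposition oracle: Kearsley quaternion method
# ---------------------------------------------------------------------------

def optimal_rmsd_oracle(mobile, target):
    """Minimal RMSD between two point sets over rigid motions (quaternions)."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    xm, ym = x - y, x + y
    K = np.zeros((4, 4))
    K[0, 0] = np.sum(xm[:, 0] ** 2 + xm[:, 1] ** 2 + xm[:, 2] ** 2)
    K[1, 1] = np.sum(xm[:, 0] ** 2 + ym[:, 1] ** 2 + ym[:, 2] ** 2)
    K[2, 2] = np.sum(ym[:, 0] ** 2 + xm[:, 1] ** 2 + ym[:, 2] ** 2)
    K[3, 3] = np.sum(ym[:, 0] ** 2 + ym[:, 1] ** 2 + xm[:, 2] ** 2)
    K[0, 1] = K[1, 0] = np.sum(ym[:, 1] * xm[:, 2] - xm[:, 1] * ym[:, 2])
    K[0, 2] = K[2, 0] = np.sum(xm[:, 0] * ym[:, 2] - ym[:, 0] * xm[:, 2])
    K[0, 3] = K[3, 0] = np.sum(ym[:, 0] * xm[:, 1] - xm[:, 0] * ym[:, 1])
    K[1, 2] = K[2, 1] = np.sum(xm[:, 0] * xm[:, 1] - ym[:, 0] * ym[:, 1])
    K[1, 3] = K[3, 1] = np.sum(xm[:, 0] * xm[:, 2] - ym[:, 0] * ym[:, 2])
    K[2, 3] = K[3, 2] = np.sum(xm[:, 1] * xm[:, 2] - ym[:, 1] * ym[:, 2])
    lam = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(lam, 0.0) / len(mobile))


# ---------------------------------------------------------------------------
# Curation oracle: the two discard rules, stated literally
# ---------------------------------------------------------------------------

def curation_oracle(missing):
    """(deleted_structure_indices, deleted_column_indices) for a boolean
    missing matrix (structures x columns), single pass on the initial set."""
    missing = np.asarray(missing, bool)
    col_counts = missing.sum(axis=0)
    deleted_cols = {int(c) for c in range(missing.shape[1]) if col_counts[c] >= 2}
    deleted_structs = set()
    for s in range(missing.shape[0]):
        for c in range(missing.shape[1]):
            if missing[s, c] and col_counts[c] == 1:
                deleted_structs.add(s)
    return deleted_structs, deleted_cols


# ---------------------------------------------------------------------------
# Probe-contact oracle: all-pairs distances with explicit loops
# ---------------------------------------------------------------------------

def probe_contact_oracle(water_xyz, ref_xyz, cutoff):
    """(contact_fraction, mean_count) over frames by O(F*W*R) looping."""
    n_frames = len(water_xyz)
    counts = []
    for f in range(n_frames):
        n = 0
        for w in water_xyz[f]:
            for r in ref_xyz[f]:
                if np.sqrt(np.sum((np.asarray(w) - np.asarray(r)) ** 2)) <= cutoff:
                    n += 1
                    break
        counts.append(n)
    counts = np.asarray(counts)
    return float(np.mean(counts >= 1)), float(np.mean(counts))
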