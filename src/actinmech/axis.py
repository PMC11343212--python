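"""Midpoint construction of the filament central axis.

The axis is built purely from subunit centroids: centroids of consecutive
particle pairs on the genetic helix are joined into segments, and the
midpoints of neighboring segments form the axis polyline.  Because
consecutive subunits sit on opposite long-pitch strands, each pair centroid
lies close to the true axis, and the second averaging step cancels the
residual spiral offset almost completely.
"""

from __future__ import annotations

import numpy as np

__all__ = ["axis_midpoints", "midpoint_projection_twist", "spiral_amplitude", "pca"]


def axis_midpoints(positions: np.ndarray) -> np.ndarray:
    """Axis polyline points from subunit centroids; shape (n-2, 3)."""
    pos = np.asarray(positions, float)
    if len(pos) < 4:
        raise ValueError("need at least 4 subunits to construct the axis")
    c = 0.5 * (pos[:-1] + pos[1:])
    return 0.5 * (c[:-1] + c[1:])


def midpoint_projection_twist(positions: np.ndarray) -> np.ndarray:
    """Per-interface twist (degrees) by the midpoint-projection method.

    Each consecutive-subunit pair is projected onto the nearest axis
    segment (joining neighboring axis midpoints); the twist is the signed
    angle between the two projection vectors about that segment, negative
    for the left-handed genetic helix.

    Returns the interfaces that have a covering axis segment: pairs
    ``(i, i+1)`` for ``i = 1 .. n-3``, i.e. ``n - 3`` values for ``n``
    subunits.  The two terminal interfaces are omitted because no axis
    segment spans them and their projection geometry is systematically
    biased (an edge effect; terminal subunits are likewise excluded in the
    twist-variance analysis).
    """
    pos = np.asarray(positions, float)
    m = axis_midpoints(pos)
    if len(m) < 2:
        raise ValueError("need at least 5 subunits for a twist measurement")
    seg_a = m[:-1]
    seg_v = m[1:] - m[:-1]
    seg_len2 = np.einsum("ij,ij->i", seg_v, seg_v)
    if np.any(seg_len2 == 0):
        bad = int(np.argmin(seg_len2))
        raise ValueError(f"collapsed axis segment at interface {bad}")

    twists = np.empty(len(pos) - 3)
    for i in range(1, len(pos) - 2):
        mid = 0.5 * (pos[i] + pos[i + 1])
        # nearest axis segment to the pair midpoint
        t = np.clip(
            np.einsum("ij,ij->i", mid - seg_a, seg_v) / seg_len2, 0.0, 1.0
        )
        feet = seg_a + t[:, None] * seg_v
        j = int(np.argmin(np.einsum("ij,ij->i", mid - feet, mid - feet)))
        u = seg_v[j] / np.sqrt(seg_len2[j])
        v1 = pos[i] - seg_a[j]
        v1 = v1 - np.dot(v1, u) * u
        v2 = pos[i + 1] - seg_a[j]
        v2 = v2 - np.dot(v2, u) * u
        twists[i - 1] = np.degrees(
            np.arctan2(np.dot(np.cross(v1, v2), u), np.dot(v1, v2))
        )
    return twists


def pca(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal axes of a point cloud.

    Returns (mean, components, projections): components rows are PC1..PC3,
    projections are the centered points in the PC basis.
    """
    pts = np.asarray(points, float)
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return mean, vt, centered @ vt.T


def spiral_amplitude(positions: np.ndarray) -> float:
    """Transverse PC2 amplitude (nm) of the filament central axis.

    The significance cutoff used throughout is 15 nm: smaller amplitudes are
    regarded as ordinary thermal undulation rather than a superhelix.
    """
    m = axis_midpoints(positions)
    _, _, proj = pca(m)
    return float(np.max(np.abs(proj[:, 1])))
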