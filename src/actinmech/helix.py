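"""Instantaneous helical rise and twist along a deformed filament axis.

The filament axis is a smoothing spline through the strand-pair midpoints
of the protomer-centroid chain, arc-length parameterized, with the
centroid-to-axis radius fitted by a separate univariate spline so that
radial breathing of a deformed lattice does not leak into the twist.

Rise is the path length along the axis between the foot points of
neighboring protomers (genetic-helix neighbors).  Twist is the rotation of
the protomer azimuth about the local tangent between consecutive foot
points, evaluated in a frame transported along the axis: the Frenet frame
(tangent, normal, binormal) where curvature is well defined, with the
frame's own torsional spin removed, which is equivalent to a
parallel-transported frame — on straight stretches, where the Frenet
normal is singular, the parallel-transported frame is the fallback and the
choice is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .axis import axis_midpoints

__all__ = [
    "AxisSpline",
    "HelicalProfile",
    "fit_axis_spline",
    "instantaneous_rise",
    "instantaneous_twist",
    "helical_profile",
    "stitch_three",
    "centroids_from_structure",
]

# nm^2 of allowed squared residual per midpoint; the midpoint construction
# leaves only ~0.03 nm of spiral residue, and heavier smoothing flattens
# genuinely curved (superhelical) axes — validated on the modulated-lattice
# and superhelical-axis recovery suites
DEFAULT_AXIS_SMOOTHING = 0.003


@dataclass
class AxisSpline:
    """Arc-length parameterized axis curve with a radius function."""

    tck: tuple = field(repr=False)
    u_of_s: np.ndarray = field(repr=False)  # dense arc length -> spline parameter
    s_dense: np.ndarray = field(repr=False)
    length_nm: float = 0.0
    radius_spline: object = field(repr=False, default=None)
    frame_kind: str = "parallel_transport"

    def point(self, s) -> np.ndarray:
        u = np.interp(s, self.s_dense, self.u_of_s)
        return np.array(interpolate.splev(u, self.tck)).T

    def tangent(self, s) -> np.ndarray:
        u = np.interp(s, self.s_dense, self.u_of_s)
        d = np.array(interpolate.splev(u, self.tck, der=1)).T
        d = np.atleast_2d(d)
        t = d / np.linalg.norm(d, axis=1, keepdims=True)
        return t[0] if np.isscalar(s) else t

    def radius(self, s):
        if self.radius_spline is None:
            return np.zeros_like(np.asarray(s, float))
        return self.radius_spline(s)

    def foot(self, p: np.ndarray) -> float:
        """Arc length of the orthogonal projection of ``p`` onto the axis."""
        pts = self.point(self.s_dense)
        d2 = np.sum((pts - p) ** 2, axis=1)
        k = int(np.argmin(d2))
        lo = self.s_dense[max(k - 1, 0)]
        hi = self.s_dense[min(k + 1, len(self.s_dense) - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda s: float(np.sum((self.point(s) - p) ** 2)),
            bounds=(lo, hi),
            method="bounded",
        )
        return float(res.x)


def fit_axis_spline(
    centroids: np.ndarray,
    smoothing: float = DEFAULT_AXIS_SMOOTHING,
) -> AxisSpline:
    """Fit the central axis through strand-pair midpoints of the chain.

    ``centroids`` are protomer centroids in nm, ordered along the genetic
    helix.  The radius (centroid distance to axis) is fitted by a separate
    univariate spline over arc length.  An all-collinear chain returns the
    line itself with radius 0.
    """
    centroids = np.asarray(centroids, float)
    if len(centroids) < 7:
        raise ValueError("need at least 7 centroids")
    mids = axis_midpoints(centroids)

    # collinear input: return the line
    centered = mids - mids.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        direction = centered[-1] - centered[0]
        direction /= np.linalg.norm(direction)
        t = centered @ direction
        line = mids.mean(axis=0) + np.outer(t, direction)
        tck, _ = interpolate.splprep(line.T, u=(t - t.min()) / np.ptp(t), s=0, k=1)
        s_dense = np.linspace(0.0, np.ptp(t), 500)
        axis = AxisSpline(
            tck=tck,
            u_of_s=s_dense / np.ptp(t),
            s_dense=s_dense,
            length_nm=float(np.ptp(t)),
        )
    else:
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(mids, axis=0), axis=1))]
        )
        u = chord / chord[-1]
        tck, _ = interpolate.splprep(mids.T, u=u, s=smoothing * len(mids), k=3)
        dense_u = np.linspace(0.0, 1.0, max(200, 30 * len(mids)))
        dense = np.array(interpolate.splev(dense_u, tck)).T
        s_dense = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        axis = AxisSpline(
            tck=tck,
            u_of_s=dense_u,
            s_dense=s_dense,
            length_nm=float(s_dense[-1]),
        )

    feet = np.array([axis.foot(p) for p in centroids])
    radii = np.linalg.norm(centroids - axis.point(feet), axis=1)
    # drop boundary-clamped feet (terminal centroids project beyond the
    # domain) and enforce strictly increasing abscissae for the radius fit
    margin = 1e-4 * max(axis.length_nm, 1.0)
    inside = (feet > margin) & (feet < axis.length_nm - margin)
    fx, fy = feet[inside], radii[inside]
    order = np.argsort(fx)
    fx, fy = fx[order], fy[order]
    keep = np.concatenate([[True], np.diff(fx) > 1e-9])
    fx, fy = fx[keep], fy[keep]
    # separate univariate spline for the (possibly varying) radius
    if len(fx) > 5:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            axis.radius_spline = interpolate.UnivariateSpline(
                fx, fy, s=len(fy) * 0.01, k=3
            )
    else:
        mean_r = float(radii.mean())
        axis.radius_spline = lambda s: np.full_like(np.asarray(s, float), mean_r)
    return axis


def _transported_frames(axis: AxisSpline, s_grid: np.ndarray):
    """Orthonormal frames along the axis with zero torsional spin.

    Starts from the Frenet normal where curvature is defined (fallback: an
    arbitrary perpendicular), then parallel transports along the curve.
    Returns (tangents, normals, binormals, frame_kind).
    """
    pts = axis.point(s_grid)
    tangents = np.gradient(pts, s_grid, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    d2 = np.gradient(tangents, s_grid, axis=0)
    curv = np.linalg.norm(d2, axis=1)
    kind = "frenet_transported" if curv.max() > 1e-4 else "parallel_transport"
    # initial normal
    if kind == "frenet_transported":
        k0 = int(np.argmax(curv))
        n = d2[k0] - np.dot(d2[k0], tangents[k0]) * tangents[k0]
    else:
        k0 = 0
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, tangents[0])) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = trial - np.dot(trial, tangents[0]) * tangents[0]
    n = n / np.linalg.norm(n)
    normals = np.empty_like(tangents)
    normals[k0] = n
    for i in range(k0 + 1, len(s_grid)):
        normals[i] = _transport(normals[i - 1], tangents[i - 1], tangents[i])
    for i in range(k0 - 1, -1, -1):
        normals[i] = _transport(normals[i + 1], tangents[i + 1], tangents[i])
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals, kind


def _transport(n_prev: np.ndarray, t_prev: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    v = np.cross(t_prev, t_new)
    sv = np.linalg.norm(v)
    if sv < 1e-14:
        n = n_prev
    else:
        c = np.clip(np.dot(t_prev, t_new), -1.0, 1.0)
        ang = np.arctan2(sv, c)
        k = v / sv
        n = (
            n_prev * np.cos(ang)
            + np.cross(k, n_prev) * np.sin(ang)
            + k * np.dot(k, n_prev) * (1 - np.cos(ang))
        )
    n = n - np.dot(n, t_new) * t_new
    return n / np.linalg.norm(n)


def instantaneous_rise(
    centroids: np.ndarray,
    axis: AxisSpline | None = None,
    return_interfaces: bool = False,
):
    """Per-interface rise (A): axis path length between neighboring feet.

    Terminal centroids project beyond the midpoint-axis domain (their feet
    clamp to the boundary, where the path length is undefined); interfaces
    involving a clamped foot are excluded.  For a full chain of n subunits
    this leaves interfaces 1 .. n-3, matching the twist measurement.  With
    ``return_interfaces=True`` the leading-protomer indices are returned
    alongside.
    """
    centroids = np.asarray(centroids, float)
    if axis is None:
        axis = fit_axis_spline(centroids)
    feet = np.array([axis.foot(p) for p in centroids])
    margin = 1e-4 * axis.length_nm
    interior = (feet > margin) & (feet < axis.length_nm - margin)
    valid = interior[:-1] & interior[1:]
    rise = np.abs(np.diff(feet))[valid] * 10.0
    if return_interfaces:
        return rise, np.nonzero(valid)[0]
    return rise


def instantaneous_twist(
    centroids: np.ndarray,
    axis: AxisSpline | None = None,
    return_metadata: bool = False,
):
    """Per-interface twist (degrees) about the local axis tangent.

    The azimuth of each protomer in the transported normal-binormal plane
    at its foot point is differenced between genetic-helix neighbors and
    wrapped into (-180, 180], preserving the left-handed sign.
    """
    centroids = np.asarray(centroids, float)
    if axis is None:
        axis = fit_axis_spline(centroids)
    s_grid = np.linspace(0.0, axis.length_nm, max(500, 20 * len(centroids)))
    tangents, normals, binormals, kind = _transported_frames(axis, s_grid)
    feet = np.array([axis.foot(p) for p in centroids])
    azimuth = np.empty(len(centroids))
    for i, (p, s) in enumerate(zip(centroids, feet)):
        k = int(np.argmin(np.abs(s_grid - s)))
        v = p - axis.point(s)
        v = v - np.dot(v, tangents[k]) * tangents[k]
        azimuth[i] = np.arctan2(np.dot(v, binormals[k]), np.dot(v, normals[k]))
    d = np.degrees(np.diff(azimuth))
    d = (d + 180.0) % 360.0 - 180.0
    if return_metadata:
        return d, {"frame": kind}
    return d


@dataclass
class HelicalProfile:
    """Per-interface rise/twist with strand labels by index parity."""

    rise_A: np.ndarray
    twist_deg: np.ndarray
    strand: np.ndarray  # 0/1, parity of the leading protomer index
    interface: np.ndarray = None  # leading protomer index per interface
    frame: str = "parallel_transport"

    def to_frame(self):
        import pandas as pd

        iface = (
            self.interface
            if self.interface is not None
            else np.arange(len(self.rise_A))
        )
        return pd.DataFrame(
            {
                "interface": iface,
                "rise_A": self.rise_A,
                "twist_deg": self.twist_deg,
                "strand": self.strand,
            }
        )


def helical_profile(
    centroids: np.ndarray,
    smoothing: float = DEFAULT_AXIS_SMOOTHING,
    stitch: bool = False,
) -> HelicalProfile:
    """Measure rise and twist along the fitted variable-radius axis.

    With ``stitch=True`` three copies of the chain are stitched end to end
    (by the rigid transform that maps the first half onto the second half)
    and only the central copy's interfaces are reported, minimizing edge
    artifacts.
    """
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    if stitch:
        stitched, offset = stitch_three(centroids)
        axis = fit_axis_spline(stitched, smoothing)
        rise, iface = instantaneous_rise(stitched, axis, return_interfaces=True)
        twist_all, meta = instantaneous_twist(stitched, axis, return_metadata=True)
        keep = (iface >= offset) & (iface < offset + n - 1)  # central copy only
        rise = rise[keep]
        twist = twist_all[iface[keep]]
        iface = iface[keep] - offset
    else:
        axis = fit_axis_spline(centroids, smoothing)
        rise, iface = instantaneous_rise(centroids, axis, return_interfaces=True)
        twist_all, meta = instantaneous_twist(centroids, axis, return_metadata=True)
        twist = twist_all[iface]
    strand = iface % 2
    return HelicalProfile(
        rise_A=rise,
        twist_deg=twist,
        strand=strand,
        interface=iface,
        frame=meta["frame"],
    )


def stitch_three(centroids: np.ndarray) -> tuple[np.ndarray, int]:
    """Stitch three copies of a protomer chain along its helical advance.

    The rigid transform mapping the first half of the chain onto the second
    half (a helical advance by n//2 subunits) is applied forward and
    backward to extend the chain by one copy on each side.  Returns the
    stitched chain and the index offset of the original chain within it.
    """
    from .subdomains import kabsch

    centroids = np.asarray(centroids, float)
    n = len(centroids)
    half = n // 2
    rot, trans = kabsch(centroids[: n - half], centroids[half:])
    # apply the half-advance twice: a full-copy advance of 2*half subunits
    fwd = centroids @ rot.T + trans
    fwd2 = fwd @ rot.T + trans
    inv_rot = rot.T
    inv_trans = -rot.T @ trans
    back = centroids @ inv_rot.T + inv_trans
    back2 = back @ inv_rot.T + inv_trans
    h2 = 2 * half
    out = np.vstack([back2[:h2], centroids, fwd2[n - h2 :]])
    return out, h2


def centroids_from_structure(path) -> np.ndarray:
    """Protomer centroids (nm) from a multi-chain PDB/mmCIF model.

    Each chain is one protomer; the centroid is the mean of its C-alpha
    positions.  Chains are ordered by mean position along the first
    principal axis of the whole model, approximating genetic-helix order.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    model = st[0]
    cents = []
    for ch in model:
        cas = [
            np.array([a.pos.x, a.pos.y, a.pos.z])
            for res in ch
            for a in res
            if a.name == "CA"
        ]
        if cas:
            cents.append(np.mean(cas, axis=0))
    if len(cents) < 7:
        raise ValueError("need at least 7 protomer chains")
    cents = np.array(cents) / 10.0  # A -> nm
    centered = cents - cents.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    return cents[order]
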