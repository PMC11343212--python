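"""Ground-truth synthetic data for every analysis stage.

These generators emulate the observable layers of the real data — 3D
filament traces from tomograms, helically modulated protomer lattices, 2D
segmentation probability maps, curvature samples, thermal twist noise, and
protomer coordinate sets with programmed subdomain shifts — with the ground
truth attached, so each analyzer can be tested as a generator -> analyzer
round trip.  All generators are pure functions of their parameters and a
mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import FilamentConfiguration, LatticeParams

__all__ = [
    "gen_superhelix_trace",
    "gen_planar_arc_trace",
    "gen_straight_trace",
    "gen_modulated_lattice",
    "gen_segmentation_image",
    "sample_curvatures",
    "gen_twist_noise_trajectory",
    "gen_shifted_protomer",
    "SyntheticTrace",
    "ModulatedLattice",
    "SyntheticSegmentation",
]


@dataclass
class SyntheticTrace:
    """Marker points (nm) plus the generating ground truth."""

    markers: np.ndarray
    truth: dict


def gen_superhelix_trace(
    wavelength_nm: float = 160.0,
    amp2_nm: float = 10.0,
    amp3_nm: float = 10.0,
    length_nm: float = 400.0,
    marker_step_nm: float = 4.0,
    noise_nm: float = 0.0,
    seed: int = 0,
    tilt_deg: float = 0.0,
) -> SyntheticTrace:
    """Markers on an ideal (optionally elliptical) superhelix about the z axis.

    x(t) = A2 sin(2 pi t / lambda), y(t) = A3 cos(2 pi t / lambda): the two
    transverse signals are in exact quadrature, so the fractional phase
    offset of the ideal path is 1/4.  ``tilt_deg`` rotates the path about
    its propagation (z) axis, lifting the major (x) oscillation plane out of
    the x-z plane — the fixture for ice-plane angle measurements, where the
    plane contains the filament axis; Gaussian marker noise emulates
    manual-picking jitter.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, length_nm + 1e-9, marker_step_nm)
    x = amp2_nm * np.sin(2 * np.pi * t / wavelength_nm)
    y = amp3_nm * np.cos(2 * np.pi * t / wavelength_nm)
    pts = np.column_stack([x, y, t])
    if tilt_deg:
        a = np.deg2rad(tilt_deg)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        pts = pts @ rot.T
    if noise_nm > 0:
        pts = pts + rng.normal(0.0, noise_nm, pts.shape)
    return SyntheticTrace(
        markers=pts,
        truth={
            "kind": "superhelix",
            "wavelength_nm": wavelength_nm,
            "amplitude_pc2_nm": max(amp2_nm, amp3_nm),
            "amplitude_pc3_nm": min(amp2_nm, amp3_nm),
            "phase_offset": 0.25 if amp3_nm > 0 else None,
            "tilt_deg": tilt_deg,
            "noise_nm": noise_nm,
        },
    )


def gen_planar_arc_trace(
    curvature_um: float = 1.0,
    length_nm: float = 400.0,
    marker_step_nm: float = 4.0,
    noise_nm: float = 0.0,
    seed: int = 0,
) -> SyntheticTrace:
    """Markers on a planar circular arc of the given signed curvature."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, length_nm + 1e-9, marker_step_nm)
    if abs(curvature_um) < 1e-12:
        return gen_straight_trace(length_nm, marker_step_nm, noise_nm, seed)
    r_nm = 1000.0 / abs(curvature_um)
    phi = t / r_nm
    sign = np.sign(curvature_um)
    pts = np.column_stack(
        [sign * r_nm * (1 - np.cos(phi)), np.zeros_like(t), r_nm * np.sin(phi)]
    )
    if noise_nm > 0:
        pts = pts + rng.normal(0.0, noise_nm, pts.shape)
    return SyntheticTrace(
        markers=pts,
        truth={"kind": "planar_arc", "curvature_um": curvature_um, "noise_nm": noise_nm},
    )


def gen_straight_trace(
    length_nm: float = 400.0,
    marker_step_nm: float = 4.0,
    noise_nm: float = 0.0,
    seed: int = 0,
) -> SyntheticTrace:
    """Markers on a straight line along z."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, length_nm + 1e-9, marker_step_nm)
    pts = np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
    if noise_nm > 0:
        pts = pts + rng.normal(0.0, noise_nm, pts.shape)
    return SyntheticTrace(
        markers=pts, truth={"kind": "straight", "noise_nm": noise_nm}
    )


# ---------------------------------------------------------------------------
# modulated protomer lattices


@dataclass
class ModulatedLattice:
    """Protomer chain with programmed per-interface rise/twist."""

    config: FilamentConfiguration
    rise_A: np.ndarray  # per interface, ground truth
    twist_deg: np.ndarray  # per interface, ground truth
    params: LatticeParams


def _parallel_transport_frames(axis_pts: np.ndarray):
    """Tangent + parallel-transported normal/binormal along a polyline."""
    tangents = np.gradient(axis_pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    # initial normal: any vector orthogonal to t0
    t0 = tangents[0]
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, t0)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    n = trial - np.dot(trial, t0) * t0
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(tangents)):
        v = np.cross(tangents[i - 1], tangents[i])
        c = np.clip(np.dot(tangents[i - 1], tangents[i]), -1.0, 1.0)
        if np.linalg.norm(v) < 1e-12:
            normals[i] = normals[i - 1]
        else:
            ang = np.arccos(c)
            axis = v / np.linalg.norm(v)
            nn = normals[i - 1]
            normals[i] = (
                nn * np.cos(ang)
                + np.cross(axis, nn) * np.sin(ang)
                + axis * np.dot(axis, nn) * (1 - np.cos(ang))
            )
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def gen_modulated_lattice(
    n_subunits: int = 100,
    params: LatticeParams | None = None,
    rise_modulation=None,
    twist_modulation=None,
    axis_path=None,
    seed: int = 0,
) -> ModulatedLattice:
    """Lattice with per-interface rise/twist perturbed by a program.

    ``rise_modulation(i)`` / ``twist_modulation(i)`` return the additive
    perturbation (A / degrees) at interface ``i``; ``axis_path(s)`` maps
    axial position (nm) to a 3D axis point (nm) for bent/superhelical
    filaments (default straight).  The attached truth holds the exact
    per-interface rise and twist programs.
    """
    if params is None:
        params = LatticeParams(n_subunits=n_subunits)
    else:
        params = LatticeParams(
            rise_A=params.rise_A,
            twist_deg=params.twist_deg,
            radius_A=params.radius_A,
            n_subunits=n_subunits,
        )
    iface = np.arange(n_subunits - 1)
    rise = np.full(n_subunits - 1, params.rise_A)
    twist = np.full(n_subunits - 1, params.twist_deg)
    if rise_modulation is not None:
        rise = rise + np.array([float(rise_modulation(i)) for i in iface])
    if twist_modulation is not None:
        twist = twist + np.array([float(twist_modulation(i)) for i in iface])
    if np.any(rise <= 0):
        raise ValueError("rise modulation produced non-positive rise")

    z = np.concatenate([[0.0], np.cumsum(rise)]) / 10.0  # nm
    psi = np.deg2rad(np.concatenate([[0.0], np.cumsum(twist)]))
    r_nm = params.radius_A / 10.0

    if axis_path is None:
        pos = np.column_stack(
            [r_nm * np.cos(psi), r_nm * np.sin(psi), z]
        )
    else:
        # arc-length parameterize the axis path and transport frames
        s_dense = np.linspace(0.0, z[-1], max(2000, 10 * n_subunits))
        axis_dense = np.array([axis_path(s) for s in s_dense], float)
        seglen = np.linalg.norm(np.diff(axis_dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        # re-map so subunit i sits at arc length z[i] along the path
        s_of_arc = np.interp(np.clip(z, 0, arc[-1]), arc, s_dense)
        axis_pts = np.array([axis_path(s) for s in s_of_arc], float)
        tangents, normals, binormals = _parallel_transport_frames(axis_pts)
        pos = (
            axis_pts
            + r_nm * (np.cos(psi)[:, None] * normals + np.sin(psi)[:, None] * binormals)
        )

    return ModulatedLattice(
        config=FilamentConfiguration(pos),
        rise_A=rise,
        twist_deg=twist,
        params=params,
    )


# ---------------------------------------------------------------------------
# 2D segmentation maps


@dataclass
class SyntheticSegmentation:
    """Probability map plus ground-truth filament paths and flags."""

    image: np.ndarray  # (H, W) float in [0, 1]
    pixel_size_A: float
    paths_px: list  # list of (m, 2) arrays, (col, row) order
    superhelical: list  # bool per path


def _curvature_path(segments, step_px: float = 1.0, start=(0.0, 0.0), heading_deg: float = 90.0):
    """2D path from a piecewise-constant signed curvature program.

    ``segments``: list of (curvature_per_px, length_px); positive curvature
    turns left along the traversal.
    """
    pts = [np.asarray(start, float)]
    heading = np.deg2rad(heading_deg)
    for kappa, length in segments:
        n = max(1, int(round(length / step_px)))
        for _ in range(n):
            heading += kappa * step_px
            pts.append(pts[-1] + step_px * np.array([np.cos(heading), np.sin(heading)]))
    return np.array(pts)


def gen_segmentation_image(
    paths_spec,
    shape=(768, 768),
    pixel_size_A: float = 4.32,
    width_px: float = 18.0,  # FWHM; ~80 A filament diameter at 4.32 A/px
    seed: int = 0,
    noise: float = 0.0,
) -> SyntheticSegmentation:
    """Rasterize filaments with Gaussian cross-sections into a probability map.

    ``paths_spec`` is a list of dicts with keys ``start`` (px), ``heading_deg``,
    ``segments`` (list of (curvature_um, length_A) converted internally to
    pixel units), and optional ``superhelical`` truth flag; alternatively a
    precomputed ``path_px`` array.  The Gaussian cross-section makes the 0.3
    binarization threshold meaningful.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.zeros(shape, float)
    paths = []
    flags = []
    yy, xx = np.mgrid[0:h, 0:w]
    for spec in paths_spec:
        if "path_px" in spec:
            path = np.asarray(spec["path_px"], float)
        else:
            segments_px = [
                (kappa_um * 1e-4 * pixel_size_A, length_A / pixel_size_A)
                for kappa_um, length_A in spec["segments"]
            ]
            path = _curvature_path(
                segments_px,
                start=spec.get("start", (w / 2, 20.0)),
                heading_deg=spec.get("heading_deg", 90.0),
            )
        inside = (
            (path[:, 0] >= 0) & (path[:, 0] < w) & (path[:, 1] >= 0) & (path[:, 1] < h)
        )
        if not inside.all():
            path = path[inside]
        paths.append(path)
        flags.append(bool(spec.get("superhelical", False)))
        # stamp Gaussian profile along the path (local crop per point)
        half = int(np.ceil(3 * width_px))
        for cx, cy in path:
            x0, x1 = int(cx) - half, int(cx) + half + 1
            y0, y1 = int(cy) - half, int(cy) + half + 1
            x0c, x1c = max(x0, 0), min(x1, w)
            y0c, y1c = max(y0, 0), min(y1, h)
            if x0c >= x1c or y0c >= y1c:
                continue
            sub_y = yy[y0c:y1c, x0c:x1c]
            sub_x = xx[y0c:y1c, x0c:x1c]
            d2 = (sub_x - cx) ** 2 + (sub_y - cy) ** 2
            np.maximum(
                img[y0c:y1c, x0c:x1c],
                np.exp(-d2 / (2 * (width_px / 2.355) ** 2)),
                out=img[y0c:y1c, x0c:x1c],
            )
    if noise > 0:
        img = np.clip(img + rng.normal(0.0, noise, img.shape), 0.0, 1.0)
    return SyntheticSegmentation(
        image=img, pixel_size_A=pixel_size_A, paths_px=paths, superhelical=flags
    )


# ---------------------------------------------------------------------------
# curvature samples, twist noise, shifted protomers


def sample_curvatures(
    alpha: float,
    persistence_length_um: float,
    segment_length_um: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """IID draws from the thermal curvature distribution (1/um).

    The Boltzmann weight exp(-alpha Lp L kappa^2 / 2) over kappa >= 0 is a
    half-Gaussian with scale 1 / sqrt(alpha Lp L).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(alpha * persistence_length_um * segment_length_um)
    return np.abs(rng.normal(0.0, scale, n))


def gen_twist_noise_trajectory(
    n_subunits: int = 100,
    sigma_deg: float = 2.0,
    n_frames: int = 1000,
    correlation_interfaces: float = 0.0,
    params: LatticeParams | None = None,
    seed: int = 0,
):
    """Trajectory whose per-interface twists carry Gaussian noise.

    Rise is canonical; only the twist program fluctuates, with marginal
    standard deviation ``sigma_deg``.  ``correlation_interfaces`` smooths
    the noise along the filament (Gaussian kernel, rescaled back to
    ``sigma_deg``): zero gives white (IID) noise, whose Nyquist-frequency
    component any axis-based twist estimator partially attenuates; a few
    interfaces of correlation emulate the smoother fluctuation field of a
    thermal filament.  Returns a :class:`~actinmech.dynamics.Trajectory` so
    the twist-variance profiling can be exercised without running dynamics.
    """
    from scipy import ndimage

    from .dynamics import Trajectory

    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        noise = rng.normal(0.0, sigma_deg, n_subunits - 1)
        if correlation_interfaces > 0:
            noise = ndimage.gaussian_filter1d(
                noise, correlation_interfaces, mode="wrap"
            )
            noise *= sigma_deg / max(noise.std(), 1e-12)
            noise -= noise.mean()
        lat = gen_modulated_lattice(
            n_subunits=n_subunits,
            params=params,
            twist_modulation=lambda i, noise=noise: noise[i],
        )
        frames.append(lat.config.positions)
    return Trajectory(
        frames=np.array(frames),
        times=np.arange(n_frames, dtype=float) + 1.0,
        phase=np.array(["free"] * n_frames),
    )


def gen_shifted_protomer(
    subdomain_shifts: dict | None = None,
    n_residues: int = 375,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Synthetic protomer C-alpha models: a reference and a shifted copy.

    The reference is a smooth, compact synthetic C-alpha path (not a real
    actin fold).  ``subdomain_shifts`` maps (first_res, last_res) inclusive
    ranges to 3-vector displacements (A) applied to the copy.  Returns two
    ``{residue_number: xyz}`` dicts.
    """
    rng = np.random.default_rng(seed)
    # random smooth walk folded into a compact blob
    steps = rng.normal(0.0, 1.0, (n_residues, 3))
    path = np.cumsum(steps, axis=0)
    path = path - path.mean(axis=0)
    path = path / np.abs(path).max() * 20.0  # ~40 A blob
    path += rng.normal(0.0, 0.5, path.shape)
    residues = np.arange(1, n_residues + 1)
    reference = {int(r): path[k].copy() for k, r in enumerate(residues)}
    shifted = {int(r): path[k].copy() for k, r in enumerate(residues)}
    if subdomain_shifts:
        for (lo, hi), vec in subdomain_shifts.items():
            vec = np.asarray(vec, float)
            for r in range(lo, hi + 1):
                if r in shifted:
                    shifted[r] = shifted[r] + vec
    return shifted, reference
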