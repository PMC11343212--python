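"""Quantification of oscillatory (superhelical) character of 3D filament traces.

A filament trace — manually placed markers along a filament's central axis,
or the midpoint axis of a simulated filament — is smoothed with a
univariate spline (default smoothing factor 150, with coordinates in
Angstrom) and resampled evenly at 9.6 A steps.  Oscillatory segments of
350-500 nm are decomposed by PCA: PC1 is the propagation axis, PC2/PC3 the
transverse oscillation planes.  The wavelength is the first peak of the
autocorrelation of the PC2 signal after Gaussian smoothing (sigma = 2 nm);
segments whose transverse amplitude is below 15 nm are flagged
insignificant.  An ideal circular superhelix projects as sin/cos in
quadrature, giving a fractional PC2-PC3 phase offset of exactly 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, stats

from .axis import pca

__all__ = [
    "TraceSpline",
    "OscillatorySegment",
    "SpiralStats",
    "fit_trace",
    "curvature_torsion",
    "find_oscillatory_segments",
    "pca_align",
    "spiral_stats",
    "plane_angle",
    "ks_uniformity_test",
]

DEFAULT_SMOOTHING = 150.0  # UnivariateSpline s-factor, coordinates in Angstrom
DEFAULT_STEP_A = 9.6  # resampling step, Angstrom
AMPLITUDE_CUTOFF_NM = 15.0
ACF_BLUR_SIGMA_NM = 2.0


@dataclass
class TraceSpline:
    """Smoothed, evenly resampled 3D filament trace (nm)."""

    points: np.ndarray  # (m, 3) nm, equally spaced along arc length
    step_nm: float
    smoothing: float
    markers: np.ndarray  # source markers, nm
    tck: tuple = field(repr=False, default=None)

    @property
    def arc_length(self) -> np.ndarray:
        return np.arange(len(self.points)) * self.step_nm

    @property
    def length_nm(self) -> float:
        return (len(self.points) - 1) * self.step_nm


def fit_trace(
    markers: np.ndarray,
    smoothing: float = DEFAULT_SMOOTHING,
    step_A: float = DEFAULT_STEP_A,
    units: str = "nm",
) -> TraceSpline:
    """Fit a smoothing spline through marker points and resample evenly.

    ``smoothing`` follows the scipy ``s`` convention with coordinates in nm
    (the residual sum of squares allowed to the fit; 150 nm^2 absorbs
    roughly 0.5-1 nm of marker jitter over a few hundred markers); markers
    may be supplied in nm (default) or Angstrom via ``units``.
    """
    markers = np.asarray(markers, float)
    if units == "A":
        markers = markers / 10.0
    elif units != "nm":
        raise ValueError(f"unknown units {units!r}")
    if markers.ndim != 2 or markers.shape[1] != 3:
        raise ValueError("markers must be an (n, 3) array")
    # collapse duplicate consecutive markers
    keep = np.ones(len(markers), bool)
    keep[1:] = np.linalg.norm(np.diff(markers, axis=0), axis=1) > 1e-12
    markers = markers[keep]
    if len(markers) < 10:
        raise ValueError(f"need at least 10 distinct markers, got {len(markers)}")

    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(markers, axis=0), axis=1))]
    )
    u = chord / chord[-1]
    k = 3 if len(markers) > 3 else len(markers) - 1
    tck, _ = interpolate.splprep(markers.T, u=u, s=smoothing, k=k)

    # arc-length reparameterization on a dense grid, then even resampling
    dense_u = np.linspace(0.0, 1.0, max(20 * len(markers), 1000))
    dense = np.array(interpolate.splev(dense_u, tck)).T
    s_dense = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    total = s_dense[-1]
    step_nm = step_A / 10.0
    targets = np.arange(0.0, total + 1e-9, step_nm)
    u_eval = np.interp(targets, s_dense, dense_u)
    pts = np.array(interpolate.splev(u_eval, tck)).T
    return TraceSpline(
        points=pts,
        step_nm=step_A / 10.0,
        smoothing=smoothing,
        markers=markers,
        tck=tck,
    )


def curvature_torsion(trace: TraceSpline) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous curvature and torsion along the trace, in 1/um.

    kappa = |r' x r''| / |r'|^3 and tau = (r' x r'') . r''' / |r' x r''|^2,
    evaluated from finite differences of the evenly resampled points (the
    trace is already smooth by construction).
    """
    pts = trace.points
    if len(pts) < 5:
        raise ValueError("need at least 5 resampled points")
    h = trace.step_nm
    d1 = np.gradient(pts, h, axis=0)
    d2 = np.gradient(d1, h, axis=0)
    d3 = np.gradient(d2, h, axis=0)
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=1)
    if np.any(speed == 0):
        raise ValueError("vanishing speed along trace")
    cross_norm = np.linalg.norm(cross, axis=1)
    kappa = cross_norm / speed**3 * 1000.0  # 1/nm -> 1/um
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(
            cross_norm > 1e-12,
            np.einsum("ij,ij->i", cross, d3) / cross_norm**2 * 1000.0,
            0.0,
        )
    return kappa, tau


@dataclass
class OscillatorySegment:
    """Sub-trace with oscillatory character and its PCA decomposition."""

    points: np.ndarray  # (m, 3) nm
    step_nm: float
    components: np.ndarray | None = None  # rows PC1..PC3
    projections: np.ndarray | None = None  # (m, 3) in PC basis
    center_index: int | None = None  # index of the PC2 extremum after alignment
    flipped: bool = False

    @property
    def length_nm(self) -> float:
        return (len(self.points) - 1) * self.step_nm


def find_oscillatory_segments(
    trace: TraceSpline,
    min_len_nm: float = 350.0,
    max_len_nm: float = 500.0,
    kappa_threshold_um: float = 1.5,
    min_sign_changes: int = 2,
) -> list[OscillatorySegment]:
    """Identify 350-500 nm sub-traces with high, oscillating curvature.

    Candidate windows must contain at least ``min_sign_changes`` sign changes
    of the (binormal-signed) curvature with magnitude exceeding the
    threshold — the programmatic stand-in for visual selection of segments
    with high, oscillating curvature and torsion.
    """
    kappa, _ = curvature_torsion(trace)
    # sign curvature by the transverse direction in the dominant bending plane
    _, _, proj = pca(trace.points)
    signed = kappa * np.sign(
        np.gradient(np.gradient(proj[:, 1]))
    ) * -1.0  # curvature toward -PC2 positive; only sign changes matter
    n_win = int(round(min_len_nm / trace.step_nm))
    if len(trace.points) < n_win + 1:
        return []
    max_win = min(int(round(max_len_nm / trace.step_nm)), len(trace.points) - 1)
    segments: list[OscillatorySegment] = []
    start = 0
    while start + n_win <= len(trace.points) - 1:
        window = signed[start : start + max_win]
        strong = np.abs(window) >= kappa_threshold_um
        signs = np.sign(window[strong])
        changes = int(np.sum(np.abs(np.diff(signs)) > 0))
        if changes >= min_sign_changes:
            stop = min(start + max_win + 1, len(trace.points))
            segments.append(
                OscillatorySegment(points=trace.points[start:stop], step_nm=trace.step_nm)
            )
            start = stop
        else:
            start += n_win // 4
    return segments


def _smooth_signal(signal: np.ndarray, step_nm: float, sigma_nm: float) -> np.ndarray:
    return ndimage.gaussian_filter1d(signal, sigma=sigma_nm / step_nm, mode="nearest")


def pca_align(
    segments: list[OscillatorySegment],
    window_nm: float = 350.0,
) -> list[OscillatorySegment]:
    """Align PCA decompositions on the central PC2 extremum.

    Each segment is decomposed by PCA; the PC2 signal sign is fixed so that
    the maximum-amplitude extremum has positive second derivative (i.e. is a
    trough), the segment is re-centered on that extremum, and a common
    analysis window is imposed.  Segments whose decomposition is inverted
    relative to the convention are flipped by reversing the traversal
    direction of the trace.
    """
    if not segments:
        raise ValueError("no segments to align")
    aligned = []
    half = None
    for seg in segments:
        mean, comps, proj = pca(seg.points)
        pc2 = _smooth_signal(proj[:, 1], seg.step_nm, ACF_BLUR_SIGMA_NM)
        if np.ptp(pc2) < 1e-9:
            raise ValueError("flat PC2 signal: cannot align segment")
        idx = int(np.argmax(np.abs(pc2)))
        flipped = False
        if pc2[idx] > 0:
            # make the central extremum a trough (positive second derivative)
            comps = comps * np.array([1.0, -1.0, -1.0])[:, None]
            proj = proj * np.array([1.0, -1.0, -1.0])
        # traversal convention: PC1 increases along the trace
        if proj[-1, 0] < proj[0, 0]:
            proj = proj[::-1] * np.array([-1.0, 1.0, -1.0])
            seg_points = seg.points[::-1]
            flipped = True
        else:
            seg_points = seg.points
        idx = int(np.argmax(np.abs(_smooth_signal(proj[:, 1], seg.step_nm, ACF_BLUR_SIGMA_NM))))
        half = int(round(window_nm / 2.0 / seg.step_nm))
        # keep the full window length even when the extremum sits near an
        # end: slide the window inside the trace
        width = min(2 * half + 1, len(proj))
        lo = int(np.clip(idx - half, 0, len(proj) - width))
        hi = lo + width
        aligned.append(
            OscillatorySegment(
                points=seg_points[lo:hi],
                step_nm=seg.step_nm,
                components=comps,
                projections=proj[lo:hi] - proj[idx],
                center_index=idx - lo,
                flipped=flipped,
            )
        )
    return aligned


@dataclass
class SpiralStats:
    """Geometric statistics of one oscillatory segment."""

    wavelength_nm: float | None
    amplitude_pc2_nm: float
    amplitude_pc3_nm: float
    phase_offset: float | None  # fraction of wavelength, in [0, 0.5]
    major_axis_nm: float
    minor_axis_nm: float
    significant: bool
    plane_angle_deg: float | None = None


def _cosine_refine(
    signal: np.ndarray, step_nm: float, period0_nm: float
) -> float:
    """Refine a period estimate by local least-squares cosine fitting.

    Scans periods within +/-12% of the initial estimate, fitting
    a cos + b sin + c at each, and returns the residual-minimizing period.
    Removes the finite-window bias of the raw autocorrelation peak (a few
    percent at two observed periods).
    """
    s = np.arange(len(signal)) * step_nm
    periods = np.linspace(0.88 * period0_nm, 1.12 * period0_nm, 97)
    resid = np.empty_like(periods)
    for i, p in enumerate(periods):
        w = 2 * np.pi / p
        basis = np.column_stack([np.cos(w * s), np.sin(w * s), np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(basis, signal, rcond=None)
        r = signal - basis @ coef
        resid[i] = float(r @ r)
    k = int(np.argmin(resid))
    if 0 < k < len(periods) - 1:
        y0, y1, y2 = resid[k - 1], resid[k], resid[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            return float(periods[k] + 0.5 * (y0 - y2) / denom * (periods[1] - periods[0]))
    return float(periods[k])


def _autocorrelation_wavelength(
    signal: np.ndarray, step_nm: float, sigma_nm: float = ACF_BLUR_SIGMA_NM
) -> float | None:
    """First autocorrelation peak after the first zero crossing, in nm."""
    sig = _smooth_signal(np.asarray(signal, float), step_nm, sigma_nm)
    sig = sig - sig.mean()
    n = len(sig)
    acf = np.correlate(sig, sig, mode="full")[n - 1 :]
    # overlap-normalized (unbiased) estimate: the triangular taper of the raw
    # sum otherwise drags the first peak toward shorter lags
    acf = acf / np.arange(n, 0, -1)
    acf = acf[: max(int(n * 0.75), 3)]
    if acf[0] <= 0:
        return None
    acf = acf / acf[0]
    n = len(acf)
    # first zero crossing
    below = np.nonzero(acf < 0)[0]
    if len(below) == 0:
        return None
    start = below[0]
    # first local maximum after it; ties broken toward the smaller lag
    for k in range(max(start + 1, 1), n - 1):
        if acf[k] >= acf[k - 1] and acf[k] > acf[k + 1]:
            # parabolic interpolation of the peak, then a local cosine-fit
            # refinement against the signal to remove finite-window bias
            y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return _cosine_refine(sig, step_nm, (k + delta) * step_nm)
    return None


def spiral_stats(
    segment: OscillatorySegment,
    amplitude_cutoff_nm: float = AMPLITUDE_CUTOFF_NM,
) -> SpiralStats:
    """Wavelength, transverse amplitudes, phase offset and cross-section axes.

    The wavelength comes from the first autocorrelation peak of the PC2
    signal (Gaussian blur sigma = 2 nm); amplitudes are the maximum absolute
    projections; the fractional phase offset is the cross-correlation lag
    between the PC2 and PC3 signals divided by the wavelength, folded into
    [0, 0.5].  Segments below the amplitude cutoff are flagged
    insignificant; near-planar segments have an undefined phase offset.
    """
    if segment.projections is None:
        raise ValueError("segment must be aligned (run pca_align) first")
    proj = segment.projections
    step = segment.step_nm
    # the oscillation propagates along PC1: resample the transverse signals
    # on a uniform PC1 grid (arc length along the curve over-counts by the
    # local slope of the transverse oscillation)
    order = np.argsort(proj[:, 0])
    pc1 = proj[order, 0]
    grid = np.arange(pc1[0], pc1[-1] + 1e-9, step)
    pc2 = np.interp(grid, pc1, proj[order, 1])
    pc3 = np.interp(grid, pc1, proj[order, 2])
    pc2 = pc2 - pc2.mean()
    pc3 = pc3 - pc3.mean()
    # half peak-to-peak: insensitive to the residual mean offset of a
    # non-integer number of observed periods
    amp2 = float(np.ptp(pc2) / 2.0)
    amp3 = float(np.ptp(pc3) / 2.0)
    wavelength = _autocorrelation_wavelength(pc2, step)

    phase = None
    if wavelength is not None and amp3 > 0.05 * amp2 and amp3 > 0.5:
        a = _smooth_signal(pc2, step, ACF_BLUR_SIGMA_NM)
        b = _smooth_signal(pc3, step, ACF_BLUR_SIGMA_NM)
        xc = np.correlate(a - a.mean(), b - b.mean(), mode="full")
        m = len(a)
        overlap = m - np.abs(np.arange(len(xc)) - (m - 1))
        xc = xc / overlap  # unbiased: avoid taper bias toward zero lag
        lags = (np.arange(len(xc)) - (m - 1)) * step
        inside = np.nonzero(np.abs(lags) <= wavelength)[0]
        k = inside[np.argmax(xc[inside])]
        lag = float(lags[k])
        if 0 < k < len(xc) - 1:  # parabolic sub-step refinement
            y0, y1, y2 = xc[k - 1], xc[k], xc[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag += 0.5 * (y0 - y2) / denom * step
        frac = abs(lag) / wavelength
        frac = frac % 1.0
        if frac > 0.5:
            frac = 1.0 - frac
        phase = float(frac)

    return SpiralStats(
        wavelength_nm=wavelength,
        amplitude_pc2_nm=amp2,
        amplitude_pc3_nm=amp3,
        phase_offset=phase,
        major_axis_nm=amp2,
        minor_axis_nm=amp3,
        significant=amp2 >= amplitude_cutoff_nm,
    )


def plane_angle(segment: OscillatorySegment, plane_points: np.ndarray) -> float:
    """Angle (degrees) between the segment's major axis and a fitted plane.

    The plane (e.g. the ice layer, fitted by PCA of marker points in
    surrounding amorphous density) is defined by its first two principal
    components.  The plane normal is projected out of the segment's PC1
    direction, and the angle between the segment's PC2 (major axis of the
    elliptical cross-section) and the residual normal determines the tilt:
    0 deg when the major axis lies in the plane, 90 deg along the normal.
    """
    plane_points = np.asarray(plane_points, float)
    if len(plane_points) < 3:
        raise ValueError("need at least 3 plane points")
    _, comps, proj = pca(plane_points)
    if np.linalg.matrix_rank(plane_points - plane_points.mean(axis=0), tol=1e-10) < 2:
        raise ValueError("plane points are collinear")
    normal = comps[2]
    if segment.components is None:
        raise ValueError("segment must be aligned (run pca_align) first")
    pc1 = segment.components[0]
    pc2 = segment.components[1]
    n_proj = normal - np.dot(normal, pc1) * pc1
    norm = np.linalg.norm(n_proj)
    if norm < 1e-12:
        return 0.0
    n_proj = n_proj / norm
    cos_to_normal = abs(float(np.dot(pc2, n_proj)))
    angle_from_normal = np.degrees(np.arccos(np.clip(cos_to_normal, -1.0, 1.0)))
    return float(90.0 - angle_from_normal)


def ks_uniformity_test(
    angles: np.ndarray,
    reference_cdf=None,
    mode: str = "fitted-normal",
) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of an angle sample.

    ``reference_cdf`` may be any callable CDF; otherwise a normal reference
    is used, either fitted to the sample (``mode="fitted-normal"``) or
    standard (``mode="standard-normal"``).
    """
    angles = np.asarray(angles, float)
    if len(angles) < 3:
        raise ValueError("need at least 3 angles")
    if reference_cdf is None:
        if mode == "fitted-normal":
            loc, scale = float(np.mean(angles)), float(np.std(angles, ddof=1))
            reference_cdf = stats.norm(loc=loc, scale=scale).cdf
        elif mode == "standard-normal":
            reference_cdf = stats.norm.cdf
        else:
            raise ValueError(f"unknown mode {mode!r}")
    res = stats.kstest(angles, reference_cdf)
    return float(res.statistic), float(res.pvalue)
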