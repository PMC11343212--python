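"""Numba-compiled force kernel for production integration.

Mirrors :func:`actinmech.dynamics.compute_forces` term by term; the test
suite asserts agreement with the numpy reference path.  Importing this
module fails cleanly when numba is unavailable, in which case the reference
path is used everywhere.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _interior_angle_grads(pa, pb, pc):
    """Interior angle at pb of (pa, pb, pc) and gradients w.r.t. all three."""
    ux, uy, uz = pa[0] - pb[0], pa[1] - pb[1], pa[2] - pb[2]
    vx, vy, vz = pc[0] - pb[0], pc[1] - pb[1], pc[2] - pb[2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
    vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
    c = uhx * vhx + uhy * vhy + uhz * vhz
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    s2 = 1.0 - c * c
    if s2 < 1e-12:
        s2 = 1e-12
    s = np.sqrt(s2)
    theta = np.arccos(c)
    ga = np.empty(3)
    gc = np.empty(3)
    ga[0] = (c * uhx - vhx) / (nu * s)
    ga[1] = (c * uhy - vhy) / (nu * s)
    ga[2] = (c * uhz - vhz) / (nu * s)
    gc[0] = (c * vhx - uhx) / (nv * s)
    gc[1] = (c * vhy - uhy) / (nv * s)
    gc[2] = (c * vhz - uhz) / (nv * s)
    gb = -(ga + gc)
    return theta, ga, gb, gc


@njit(cache=True, fastmath=False)
def forces(
    pos,
    bonds,
    bond_k,
    bond_l0,
    angles,
    theta0,
    k_theta,
    dihedrals,
    phi0,
    k_phi,
    n_mult,
    eps,
    taper,
):
    taper_rest = 1.0 / (1.0 + 0.25)  # s^2/(s^2+eps) at rest with eps=(s0/2)^2
    n = pos.shape[0]
    out = np.zeros((n, 3))

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        coef = bond_k[b] * (l - bond_l0[b]) / l
        out[i, 0] += coef * dx
        out[i, 1] += coef * dy
        out[i, 2] += coef * dz
        out[j, 0] -= coef * dx
        out[j, 1] -= coef * dy
        out[j, 2] -= coef * dz

    for t in range(angles.shape[0]):
        j = angles[t, 0]
        i = angles[t, 1]
        k = angles[t, 2]
        ux = pos[j, 0] - pos[i, 0]
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = pos[k, 0] - pos[i, 0]
        vy = pos[k, 1] - pos[i, 1]
        vz = pos[k, 2] - pos[i, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        c = uhx * vhx + uhy * vhy + uhz * vhz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1e-16:
            s2 = 1e-16
        s = np.sqrt(s2)
        theta = np.arccos(c)
        coef = k_theta * (theta - theta0[t])
        djx = (c * uhx - vhx) / (nu * s)
        djy = (c * uhy - vhy) / (nu * s)
        djz = (c * uhz - vhz) / (nu * s)
        dkx = (c * vhx - uhx) / (nv * s)
        dky = (c * vhy - uhy) / (nv * s)
        dkz = (c * vhz - uhz) / (nv * s)
        out[j, 0] -= coef * djx
        out[j, 1] -= coef * djy
        out[j, 2] -= coef * djz
        out[k, 0] -= coef * dkx
        out[k, 1] -= coef * dky
        out[k, 2] -= coef * dkz
        out[i, 0] += coef * (djx + dkx)
        out[i, 1] += coef * (djy + dky)
        out[i, 2] += coef * (djz + dkz)

    for q in range(dihedrals.shape[0]):
        a = dihedrals[q, 0]
        b = dihedrals[q, 1]
        c_ = dihedrals[q, 2]
        d = dihedrals[q, 3]
        b1x = pos[b, 0] - pos[a, 0]
        b1y = pos[b, 1] - pos[a, 1]
        b1z = pos[b, 2] - pos[a, 2]
        b2x = pos[c_, 0] - pos[b, 0]
        b2y = pos[c_, 1] - pos[b, 1]
        b2z = pos[c_, 2] - pos[b, 2]
        b3x = pos[d, 0] - pos[c_, 0]
        b3y = pos[d, 1] - pos[c_, 1]
        b3z = pos[d, 2] - pos[c_, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2len = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = (n1y * b2z - n1z * b2y) / b2len
        my = (n1z * b2x - n1x * b2z) / b2len
        mz = (n1x * b2y - n1y * b2x) / b2len
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = mx * n2x + my * n2y + mz * n2z
        phi = np.arctan2(y, x)
        well = 1.0 - np.cos(n_mult * phi - phi0[q])
        dwell = n_mult * np.sin(n_mult * phi - phi0[q])
        if taper:
            ta, ga_a, ga_b, ga_c = _interior_angle_grads(pos[a], pos[b], pos[c_])
            tb, gb_b, gb_c, gb_d = _interior_angle_grads(pos[b], pos[c_], pos[d])
            sa = np.sin(ta)
            if sa < 1e-9:
                sa = 1e-9
            sb = np.sin(tb)
            if sb < 1e-9:
                sb = 1e-9
            ea = eps[q, 0]
            eb = eps[q, 1]
            fa = sa * sa / (sa * sa + ea)
            fb = sb * sb / (sb * sb + eb)
            w = fa * fb / (taper_rest * taper_rest)
            dv = k_phi * w * dwell
            wa = k_phi * well * w * 2.0 * ea * np.cos(ta) / (sa * (sa * sa + ea))
            wb = k_phi * well * w * 2.0 * eb * np.cos(tb) / (sb * (sb * sb + eb))
        else:
            w = 1.0
            dv = k_phi * dwell
            wa = 0.0
            wb = 0.0
        if n1sq < 1e-16:
            n1sq = 1e-16
        if n2sq < 1e-16:
            n2sq = 1e-16
        g1x = (b2len / n1sq) * n1x
        g1y = (b2len / n1sq) * n1y
        g1z = (b2len / n1sq) * n1z
        g4x = -(b2len / n2sq) * n2x
        g4y = -(b2len / n2sq) * n2y
        g4z = -(b2len / n2sq) * n2z
        t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2len * b2len)
        t2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2len * b2len)
        g2x = -(1.0 + t1) * g1x + t2 * g4x
        g2y = -(1.0 + t1) * g1y + t2 * g4y
        g2z = -(1.0 + t1) * g1z + t2 * g4z
        g3x = t1 * g1x - (1.0 + t2) * g4x
        g3y = t1 * g1y - (1.0 + t2) * g4y
        g3z = t1 * g1z - (1.0 + t2) * g4z
        out[a, 0] -= dv * g1x
        out[a, 1] -= dv * g1y
        out[a, 2] -= dv * g1z
        out[b, 0] -= dv * g2x
        out[b, 1] -= dv * g2y
        out[b, 2] -= dv * g2z
        out[c_, 0] -= dv * g3x
        out[c_, 1] -= dv * g3y
        out[c_, 2] -= dv * g3z
        out[d, 0] -= dv * g4x
        out[d, 1] -= dv * g4y
        out[d, 2] -= dv * g4z
        if taper:
            for ax in range(3):
                out[a, ax] -= wa * ga_a[ax]
                out[b, ax] -= wa * ga_b[ax] + wb * gb_b[ax]
                out[c_, ax] -= wa * ga_c[ax] + wb * gb_c[ax]
                out[d, ax] -= wb * gb_d[ax]

    return out
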