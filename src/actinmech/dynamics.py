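"""Spring-network energetics and Langevin dynamics of the filament.

The potential is the sum of harmonic bonds, harmonic angles, and cosine
dihedrals::

    V = sum 1/2 k_l (l - l0)^2
      + sum 1/2 k_theta (theta - theta0)^2
      + sum k_phi [1 - cos(n phi - phi0)]

with all rest values measured on the equilibrium lattice, which is therefore
the exact zero of the potential.

Forces are the analytic negative gradient; a numba-compiled kernel is used
for production integration when available, with a pure-numpy reference path
that the test suite cross-checks against finite differences.

Units: nm, pN, pN nm (energy), ns, K.  kT at 298 K is about 4.11 pN nm.
Particle masses are nominal (equal) since only configurational statistics
are of interest; the time axis is therefore internal simulation time, not a
physical mapping of filament hydrodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import (
    FilamentConfiguration,
    LatticeParams,
    MechanicalParams,
    SpringTopology,
)

KB = 0.0138065  # pN nm / K

__all__ = [
    "ForceProtocol",
    "IntegratorParams",
    "Trajectory",
    "total_energy",
    "compute_forces",
    "run_dynamics",
    "relax",
    "transient_response",
    "save_xyz_trajectory",
    "load_xyz_trajectory",
]


# ---------------------------------------------------------------------------
# protocol / integrator metadata


@dataclass(frozen=True)
class ForceProtocol:
    """External load protocol mimicking myosin forces on a filament end.

    The first ``n_fixed`` subunits are immobilized; an axial force of
    ``per_particle_force`` pN is applied to each of the last ``n_loaded``
    subunits (both strands), defaulting to 5 pN on 5 subunits — 25 pN total,
    approximating a single myosin.  ``tension`` pulls the loaded end away
    from the fixed end along the initial filament axis; ``compression``
    pushes it toward the fixed end.  ``apply_release`` switches the force
    off after ``apply_steps``.
    """

    mode: str = "constant"  # "constant" | "apply_release"
    sense: str = "tension"  # "tension" | "compression"
    per_particle_force: float = 5.0  # pN
    n_loaded: int = 5
    n_fixed: int = 5
    apply_steps: int = 0
    release_steps: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "apply_release"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.sense not in ("tension", "compression"):
            raise ValueError(f"unknown force sense {self.sense!r}")
        if self.per_particle_force < 0:
            raise ValueError("per-particle force must be >= 0")


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin (BAOAB) integrator settings.

    ``friction`` is the per-particle friction coefficient in pN ns / nm.
    With ``thermostat_on=False`` the integrator reduces to velocity Verlet
    (vacuum dynamics).  ``dt=None`` selects 1/20 of the fastest harmonic
    period implied by the stiffest bond and the particle mass.
    """

    dt: float | None = None  # ns
    temperature: float = 298.0  # K
    friction: float = 0.5  # pN ns / nm
    thermostat_on: bool = True
    seed: int = 0
    n_steps: int = 10000
    mass: float = 1.0  # nominal
    save_every: int = 100

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.thermostat_on and self.friction <= 0:
            raise ValueError("friction must be positive when the thermostat is on")


@dataclass
class Trajectory:
    """Time-ordered stack of configurations with protocol metadata."""

    frames: np.ndarray  # (n_frames, n, 3) nm
    times: np.ndarray  # (n_frames,) ns
    phase: np.ndarray  # (n_frames,) "apply" | "release" | "free"
    protocol: ForceProtocol | None = None
    integrator: IntegratorParams | None = None
    final_velocities: np.ndarray | None = None
    kinetic_energy: np.ndarray | None = None  # per saved frame, pN nm

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def configuration(self, k: int) -> FilamentConfiguration:
        return FilamentConfiguration(self.frames[k])


# ---------------------------------------------------------------------------
# energy / forces (numpy reference path)


TAPER_HALF_FRACTION = 0.5  # eps = (TAPER_HALF_FRACTION * rest sine)^2


def _unpack(topo: SpringTopology, mech: MechanicalParams):
    kb = mech.bond_k(topo.bond_type)
    rest = topo.dihedral_rest_sines
    if rest is None:
        rest = np.full((len(topo.dihedrals), 2), 0.5)
    eps = (TAPER_HALF_FRACTION * rest) ** 2
    return (
        topo.bonds,
        kb,
        topo.bond_l0,
        topo.angles,
        topo.angle_theta0,
        topo.dihedrals,
        topo.dihedral_phi0,
        eps,
        float(topo.dihedral_n),
    )


#: value of s^2/(s^2+eps) at the rest geometry, per arm
_TAPER_REST = 1.0 / (1.0 + TAPER_HALF_FRACTION**2)


def _dihedral_taper(pos: np.ndarray, quads: np.ndarray, eps: np.ndarray):
    """Bounded bending taper W of each dihedral, normalized to 1 at rest.

    W = prod_arm [s^2/(s^2+eps)] / rest, s = sin(arm interior angle);
    returns (W, theta_a, theta_b, s_a, s_b).
    """
    from .lattice import measure_angles

    ta = measure_angles(pos, quads[:, :3])
    tb = measure_angles(pos, quads[:, 1:])
    sa = np.maximum(np.sin(ta), 1e-9)
    sb = np.maximum(np.sin(tb), 1e-9)
    fa = sa**2 / (sa**2 + eps[:, 0])
    fb = sb**2 / (sb**2 + eps[:, 1])
    w = fa * fb / _TAPER_REST**2
    return w, ta, tb, sa, sb


def total_energy(
    config: FilamentConfiguration | np.ndarray,
    topo: SpringTopology,
    mech: MechanicalParams,
) -> float:
    """Total elastic energy (pN nm) of the configuration."""
    pos = config.positions if isinstance(config, FilamentConfiguration) else np.asarray(config, float)
    bonds, kb, l0, angles, theta0, dihedrals, phi0, w0, n_mult = _unpack(topo, mech)

    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    l = np.linalg.norm(d, axis=1)
    if np.any(l == 0):
        raise ValueError("coincident bonded particles")
    e_bond = 0.5 * np.sum(kb * (l - l0) ** 2)

    u = pos[angles[:, 0]] - pos[angles[:, 1]]
    v = pos[angles[:, 2]] - pos[angles[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident particles in angle triplet")
    c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(c)
    e_angle = 0.5 * mech.k_theta * np.sum((theta - theta0) ** 2)

    phi = _dihedral_angles(pos, dihedrals)
    well = 1.0 - np.cos(n_mult * phi - phi0)
    if mech.dihedral_mode == "tapered":
        w, _, _, _, _ = _dihedral_taper(pos, dihedrals, w0)
        e_dih = mech.k_phi * np.sum(w * well)
    else:
        e_dih = mech.k_phi * np.sum(well)

    return float(e_bond + e_angle + e_dih)


def _dihedral_angles(pos: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = pos[quads[:, 1]] - pos[quads[:, 0]]
    b2 = pos[quads[:, 2]] - pos[quads[:, 1]]
    b3 = pos[quads[:, 3]] - pos[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m = np.cross(n1, b2n)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def _angle_grads(pos: np.ndarray, trip: np.ndarray):
    """Interior angle of (j, i, k) triplets and its position gradients."""
    j, i, k = trip[:, 0], trip[:, 1], trip[:, 2]
    u = pos[j] - pos[i]
    v = pos[k] - pos[i]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
    theta = np.arccos(c)
    gj = (c[:, None] * uh - vh) / (nu * s)[:, None]
    gk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    return theta, gj, -(gj + gk), gk


def _scatter(forces: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    n = len(forces)
    for ax in range(3):
        forces[:, ax] += np.bincount(idx, weights=contrib[:, ax], minlength=n)


def compute_forces(
    config: FilamentConfiguration | np.ndarray,
    topo: SpringTopology,
    mech: MechanicalParams,
) -> np.ndarray:
    """Analytic forces, -dV/dr, as an (n, 3) array in pN."""
    pos = config.positions if isinstance(config, FilamentConfiguration) else np.asarray(config, float)
    n = len(pos)
    bonds, kb, l0, angles, theta0, dihedrals, phi0, w0, n_mult = _unpack(topo, mech)
    forces = np.zeros((n, 3))

    # bonds
    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    l = np.linalg.norm(d, axis=1)
    if np.any(l == 0):
        raise ValueError("coincident bonded particles")
    f = (kb * (l - l0) / l)[:, None] * d  # force on particle i (toward j if stretched)
    _scatter(forces, bonds[:, 0], f)
    _scatter(forces, bonds[:, 1], -f)

    # angles: triplet (j, i, k), vertex i
    j, i, k = angles[:, 0], angles[:, 1], angles[:, 2]
    u = pos[j] - pos[i]
    v = pos[k] - pos[i]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
    theta = np.arccos(c)
    coef = mech.k_theta * (theta - theta0)  # dV/dtheta
    dth_dj = (c[:, None] * uh - vh) / (nu * s)[:, None]
    dth_dk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    _scatter(forces, j, -coef[:, None] * dth_dj)
    _scatter(forces, k, -coef[:, None] * dth_dk)
    _scatter(forces, i, coef[:, None] * (dth_dj + dth_dk))

    # dihedrals: quadruplet (a, b, c, d)
    a, b, cc, dd = dihedrals[:, 0], dihedrals[:, 1], dihedrals[:, 2], dihedrals[:, 3]
    b1 = pos[b] - pos[a]
    b2 = pos[cc] - pos[b]
    b3 = pos[dd] - pos[cc]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    b2len = np.linalg.norm(b2, axis=1)
    m = np.cross(n1, b2 / b2len[:, None])
    phi = np.arctan2(np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2))
    well = 1.0 - np.cos(n_mult * phi - phi0)
    dwell_dphi = n_mult * np.sin(n_mult * phi - phi0)
    g1 = (b2len / np.maximum(n1sq, 1e-16))[:, None] * n1  # dphi/da
    g4 = -(b2len / np.maximum(n2sq, 1e-16))[:, None] * n2  # dphi/dd
    t1 = (np.einsum("ij,ij->i", b1, b2) / b2len**2)[:, None]
    t2 = (np.einsum("ij,ij->i", b3, b2) / b2len**2)[:, None]
    g2 = -(1.0 + t1) * g1 + t2 * g4
    g3 = t1 * g1 - (1.0 + t2) * g4

    if mech.dihedral_mode == "tapered":
        w, ta, tb, sa, sb = _dihedral_taper(pos, dihedrals, w0)
        coef = mech.k_phi * w * dwell_dphi
        # dW/dtheta = W * 2 eps cos(theta) / (s (s^2 + eps)) per arm; W ~ s^2
        # near collinearity keeps every term bounded there
        _, ga_a, ga_b, ga_c = _angle_grads(pos, dihedrals[:, :3])
        _, gb_b, gb_c, gb_d = _angle_grads(pos, dihedrals[:, 1:])
        dlnw_a = 2.0 * w0[:, 0] * np.cos(ta) / (sa * (sa**2 + w0[:, 0]))
        dlnw_b = 2.0 * w0[:, 1] * np.cos(tb) / (sb * (sb**2 + w0[:, 1]))
        wa = (mech.k_phi * well * w * dlnw_a)[:, None]
        wb = (mech.k_phi * well * w * dlnw_b)[:, None]
        _scatter(forces, a, -(coef[:, None] * g1 + wa * ga_a))
        _scatter(forces, b, -(coef[:, None] * g2 + wa * ga_b + wb * gb_b))
        _scatter(forces, cc, -(coef[:, None] * g3 + wa * ga_c + wb * gb_c))
        _scatter(forces, dd, -(coef[:, None] * g4 + wb * gb_d))
    else:
        dv_dphi = mech.k_phi * dwell_dphi
        _scatter(forces, a, -dv_dphi[:, None] * g1)
        _scatter(forces, b, -dv_dphi[:, None] * g2)
        _scatter(forces, cc, -dv_dphi[:, None] * g3)
        _scatter(forces, dd, -dv_dphi[:, None] * g4)

    return forces


# optional compiled fast path ------------------------------------------------

try:  # pragma: no cover - availability depends on environment
    from . import _kernels

    _HAVE_KERNELS = True
except Exception:  # pragma: no cover
    _HAVE_KERNELS = False


def _force_evaluator(topo: SpringTopology, mech: MechanicalParams, use_kernels: bool):
    if use_kernels and _HAVE_KERNELS:
        kb = np.ascontiguousarray(mech.bond_k(topo.bond_type), dtype=np.float64)
        rest = topo.dihedral_rest_sines
        if rest is None:
            rest = np.full((len(topo.dihedrals), 2), 0.5)
        eps = (TAPER_HALF_FRACTION * rest) ** 2
        args = (
            np.ascontiguousarray(topo.bonds, dtype=np.int64),
            kb,
            np.ascontiguousarray(topo.bond_l0, dtype=np.float64),
            np.ascontiguousarray(topo.angles, dtype=np.int64),
            np.ascontiguousarray(topo.angle_theta0, dtype=np.float64),
            float(mech.k_theta),
            np.ascontiguousarray(topo.dihedrals, dtype=np.int64),
            np.ascontiguousarray(topo.dihedral_phi0, dtype=np.float64),
            float(mech.k_phi),
            float(topo.dihedral_n),
            np.ascontiguousarray(eps, dtype=np.float64),
            mech.dihedral_mode == "tapered",
        )

        def evaluate(pos: np.ndarray) -> np.ndarray:
            return _kernels.forces(pos, *args)

        return evaluate

    def evaluate(pos: np.ndarray) -> np.ndarray:
        return compute_forces(pos, topo, mech)

    return evaluate


# ---------------------------------------------------------------------------
# integration


def default_dt(
    topo: SpringTopology,
    mech: MechanicalParams,
    mass: float,
    config0: FilamentConfiguration | None = None,
) -> float:
    """1/20 of the fastest harmonic period of the network.

    The stiffest effective mode is probed numerically from the diagonal of
    the force Jacobian at (or near) equilibrium: nearly straight angle
    triplets and nearly antiparallel dihedral arms amplify the bare spring
    constants by large geometric factors, so a bond-only estimate is far
    too optimistic.
    """
    if config0 is None:
        n = topo.n_subunits
        params = LatticeParams(n_subunits=n)
        from .lattice import build_canonical_lattice

        config0 = build_canonical_lattice(params)
    pos = config0.positions
    # largest Hessian eigenvalue by matrix-free power iteration
    h = 1e-6
    rng = np.random.default_rng(0)
    v = rng.normal(size=pos.shape)
    v /= np.linalg.norm(v)
    k_max = float(np.max(mech.bond_k(topo.bond_type)))
    for _ in range(40):
        hv = -(
            compute_forces(pos + h * v, topo, mech)
            - compute_forces(pos - h * v, topo, mech)
        ) / (2 * h)
        lam = float(np.sum(v * hv))
        norm = np.linalg.norm(hv)
        if norm < 1e-12:
            break
        v = hv / norm
        k_max = max(k_max, lam)
    omega = np.sqrt(k_max / mass)
    return 2.0 * np.pi / omega / 20.0


def _external_force_template(
    pos0: np.ndarray, protocol: ForceProtocol
) -> np.ndarray:
    """Per-particle external force (pN) during the apply phase.

    Directed along the initial filament axis (fixed-end centroid toward
    loaded-end centroid); tension is outward along that axis, compression
    inward.  The direction is held fixed for the whole run.
    """
    n = len(pos0)
    if protocol.n_loaded + protocol.n_fixed >= n:
        raise ValueError("n_loaded + n_fixed must be smaller than the filament")
    if protocol.per_particle_force == 0:
        return np.zeros((n, 3))
    anchor = pos0[: max(protocol.n_fixed, 1)].mean(axis=0)
    axis = pos0[-protocol.n_loaded :].mean(axis=0) - anchor
    axis = axis / np.linalg.norm(axis)
    sign = 1.0 if protocol.sense == "tension" else -1.0
    ext = np.zeros((n, 3))
    ext[-protocol.n_loaded :] = sign * protocol.per_particle_force * axis
    return ext


def run_dynamics(
    config0: FilamentConfiguration,
    topo: SpringTopology,
    mech: MechanicalParams,
    protocol: ForceProtocol,
    integ: IntegratorParams,
    use_kernels: bool = True,
    divergence_bound: float = 1e5,
) -> Trajectory:
    """Integrate Langevin (BAOAB) or vacuum velocity-Verlet dynamics.

    The first ``n_fixed`` particles are immobile; the trajectory is
    bit-for-bit reproducible for a given seed and code path.  Raises if any
    coordinate exceeds ``divergence_bound`` nm (integration blow-up).
    """
    pos = config0.positions.copy()
    n = len(pos)
    m = integ.mass
    dt = integ.dt if integ.dt is not None else default_dt(topo, mech, m, config0)
    rng = np.random.default_rng(integ.seed)
    vel = np.zeros((n, 3))
    if integ.thermostat_on and integ.temperature > 0:
        vel = rng.normal(0.0, np.sqrt(KB * integ.temperature / m), size=(n, 3))

    if protocol.mode == "constant":
        n_steps = integ.n_steps
        apply_until = n_steps
    else:
        if protocol.apply_steps <= 0 or protocol.release_steps <= 0:
            raise ValueError("apply_release mode requires positive apply and release steps")
        n_steps = protocol.apply_steps + protocol.release_steps
        apply_until = protocol.apply_steps

    fixed = slice(0, protocol.n_fixed)
    ext = _external_force_template(pos, protocol)
    evaluate = _force_evaluator(topo, mech, use_kernels)

    if integ.thermostat_on:
        c1 = np.exp(-integ.friction * dt / m)
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(KB * integ.temperature / m)
    forces = evaluate(pos) + ext

    frames = [pos.copy()]
    times = [0.0]
    phases = ["apply" if protocol.per_particle_force > 0 else "free"]
    kin = [0.5 * m * float(np.sum(vel[protocol.n_fixed :] ** 2))]

    for step in range(1, n_steps + 1):
        loaded = step <= apply_until
        vel += 0.5 * dt / m * forces
        vel[fixed] = 0.0
        pos += 0.5 * dt * vel
        if integ.thermostat_on:
            noise = rng.normal(size=(n, 3))
            vel = c1 * vel + c2 * noise
            vel[fixed] = 0.0
        pos += 0.5 * dt * vel
        forces = evaluate(pos)
        if loaded:
            forces = forces + ext
        vel += 0.5 * dt / m * forces
        vel[fixed] = 0.0

        if step % integ.save_every == 0 or step == n_steps:
            if not np.isfinite(pos).all() or np.max(np.abs(pos)) > divergence_bound:
                raise FloatingPointError(f"integration diverged at step {step}")
            frames.append(pos.copy())
            times.append(step * dt)
            if protocol.mode == "apply_release":
                phases.append("apply" if loaded else "release")
            else:
                phases.append("apply" if protocol.per_particle_force > 0 else "free")
            kin.append(0.5 * m * float(np.sum(vel[protocol.n_fixed :] ** 2)))

    return Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        phase=np.array(phases),
        protocol=protocol,
        integrator=integ,
        final_velocities=vel,
        kinetic_energy=np.array(kin),
    )


def relax(
    config0: FilamentConfiguration,
    topo: SpringTopology,
    mech: MechanicalParams,
    external: np.ndarray | None = None,
    fixed: int = 0,
    tol: float = 1e-8,
    use_kernels: bool = True,
) -> tuple[FilamentConfiguration, float]:
    """Deterministic vacuum relaxation to mechanical equilibrium.

    Minimizes the total potential (elastic minus work of the constant
    external force field) over the mobile particles with L-BFGS using the
    analytic gradient — the overdamped zero-temperature limit of the
    dynamics.  Returns the relaxed configuration and the residual maximum
    force component (pN).
    """
    from scipy.optimize import minimize

    pos0 = config0.positions
    n = len(pos0)
    evaluate = _force_evaluator(topo, mech, use_kernels)
    ext = np.zeros((n, 3)) if external is None else external
    head = pos0[:fixed]

    def fun(x: np.ndarray):
        pos = np.vstack([head, x.reshape(-1, 3)])
        e = total_energy(pos, topo, mech) - float(np.sum(ext * pos))
        g = -(evaluate(pos) + ext)[fixed:]
        return e, g.ravel()

    res = minimize(
        fun,
        pos0[fixed:].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 100000, "ftol": 1e-15, "gtol": tol},
    )
    pos = np.vstack([head, res.x.reshape(-1, 3)])
    residual = float(np.max(np.abs(evaluate(pos) + ext)[fixed:]))
    if residual > 1e-3:
        raise RuntimeError(
            f"relaxation did not converge: residual force {residual:.3g} pN"
        )
    return FilamentConfiguration(pos), residual


def spiral_wavelength(frame: np.ndarray) -> float | None:
    """Dominant spiral wavelength (nm) of one configuration's central axis.

    The midpoint axis is spline-smoothed and resampled, decomposed by PCA,
    and the wavelength read from the first autocorrelation peak of the PC2
    signal versus PC1 — the same analysis applied to experimental filament
    traces.  When the spiral spans less than about one period of the
    filament (so the autocorrelation has no interior peak) a least-squares
    cosine fit over periods up to 1.3x the axial span is used instead;
    estimates pinned at that cap are discarded as unmeasurable.
    """
    from .axis import axis_midpoints, pca
    from .traces import _autocorrelation_wavelength, fit_trace

    markers = axis_midpoints(np.asarray(frame, float))
    trace = fit_trace(markers)
    _, _, proj = pca(trace.points)
    order = np.argsort(proj[:, 0])
    pc1 = proj[order, 0]
    span = pc1[-1] - pc1[0]
    grid = np.arange(pc1[0], pc1[-1], trace.step_nm)
    pc2 = np.interp(grid, pc1, proj[order, 1])
    pc2 = pc2 - pc2.mean()
    wl = _autocorrelation_wavelength(pc2, trace.step_nm)
    if wl is None:
        s = np.arange(len(pc2)) * trace.step_nm
        periods = np.linspace(40.0, 1.3 * span, 100)
        resid = np.empty_like(periods)
        for i, p in enumerate(periods):
            w = 2 * np.pi / p
            basis = np.column_stack([np.cos(w * s), np.sin(w * s), np.ones_like(s)])
            coef, *_ = np.linalg.lstsq(basis, pc2, rcond=None)
            r = pc2 - basis @ coef
            resid[i] = r @ r
        p = periods[int(np.argmin(resid))]
        wl = None if p > 1.2 * span else float(p)
    return wl


def phase_spiral_wavelength(
    traj: "Trajectory",
    phase: str,
    amplitude_cutoff_nm: float = 15.0,
    n_frames: int = 8,
) -> float | None:
    """Median spiral wavelength over the first significant frames of a phase.

    Restricting to the frames right after the amplitude first crosses the
    significance cutoff captures the wavelength of the emerging superhelix
    before post-buckling coarsening grows it toward the filament length.
    """
    from .axis import spiral_amplitude

    idx = np.nonzero(traj.phase == phase)[0]
    amps = np.array([spiral_amplitude(traj.frames[k]) for k in idx])
    significant = idx[amps >= amplitude_cutoff_nm]
    wls = [spiral_wavelength(traj.frames[k]) for k in significant[:n_frames]]
    wls = [w for w in wls if w is not None]
    return float(np.median(wls)) if wls else None


def protocol_summary(
    traj: Trajectory,
    amplitude_cutoff_nm: float = 15.0,
    equilibration_fraction: float = 0.3,
) -> dict:
    """Per-phase amplitude and wavelength summary of a protocol run.

    Amplitudes are the transverse PC2 amplitude of the central axis per
    frame; the reported per-phase amplitude is the median over the frames
    after discarding the first ``equilibration_fraction`` of each phase.
    The wavelength is measured on the maximum-amplitude frame of each phase
    when that frame is significant (above the cutoff).
    """
    from .axis import spiral_amplitude

    from .axis import axis_midpoints, pca

    out = {}
    for phase in np.unique(traj.phase):
        idx = np.nonzero(traj.phase == phase)[0]
        amps = np.array([spiral_amplitude(traj.frames[k]) for k in idx])
        skip = int(len(idx) * equilibration_fraction)
        steady = amps[skip:] if len(amps) > skip + 1 else amps
        wl = phase_spiral_wavelength(traj, str(phase), amplitude_cutoff_nm)
        # transverse cross-section of the most developed spiral frame
        best = traj.frames[idx[int(np.argmax(amps))]]
        _, _, proj = pca(axis_midpoints(best))
        out[str(phase)] = {
            "median_amplitude_nm": float(np.median(steady)),
            "max_amplitude_nm": float(amps.max()),
            "spiral": bool(steady.max() >= amplitude_cutoff_nm) if len(steady) else False,
            "wavelength_nm": wl,
            "amplitude_pc2_nm": float(np.max(np.abs(proj[:, 1]))),
            "amplitude_pc3_nm": float(np.max(np.abs(proj[:, 2]))),
        }
    return out


def transient_response(
    traj: Trajectory, amplitude_cutoff_nm: float = 15.0
) -> dict:
    """Report whether a spiral formed and in which protocol phase.

    A spiral is scored by the transverse (PC2) amplitude of the filament
    central axis exceeding the significance cutoff (default 15 nm).
    """
    from .axis import spiral_amplitude

    if traj.protocol is not None and traj.protocol.mode == "apply_release":
        if not np.any(traj.phase == "release"):
            raise ValueError("apply/release trajectory lacks release frames")
    amplitudes = np.array([spiral_amplitude(f) for f in traj.frames])
    formed = amplitudes > amplitude_cutoff_nm
    result = {
        "spiral_formed": bool(formed.any()),
        "phase": None,
        "max_amplitude_nm": float(amplitudes.max()),
        "amplitudes_nm": amplitudes,
    }
    if formed.any():
        result["phase"] = str(traj.phase[int(np.argmax(formed))])
    return result


# ---------------------------------------------------------------------------
# trajectory I/O (multi-frame XYZ)


def save_xyz_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for frame, t, ph in zip(traj.frames, traj.times, traj.phase):
            fh.write(f"{len(frame)}\ntime_ns={t:.6f} phase={ph}\n")
            for x, y, z in frame * 10.0:  # Angstrom out
                fh.write(f"ACT {x:.4f} {y:.4f} {z:.4f}\n")


def load_xyz_trajectory(path) -> Trajectory:
    frames, times, phases = [], [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k])
        meta = dict(item.split("=") for item in lines[k + 1].split())
        times.append(float(meta.get("time_ns", len(times))))
        phases.append(meta.get("phase", "free"))
        block = lines[k + 2 : k + 2 + n]
        frames.append(
            np.array([[float(v) for v in ln.split()[1:4]] for ln in block]) / 10.0
        )
        k += 2 + n
    return Trajectory(
        frames=np.array(frames), times=np.array(times), phase=np.array(phases)
    )
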