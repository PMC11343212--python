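"""Canonical F-actin lattice geometry and spring-network topology.

The filament is represented as one spherical particle per actin subunit,
placed on the genetic (short-pitch, left-handed) helix: subunit ``i`` sits at
cylindrical coordinates ``(r, i * twist, i * rise)``.  Consecutive subunits
(``i``, ``i+1``) lie on opposite long-pitch strands, so (``i``, ``i+2``)
bonds run along one strand ("axial") while (``i``, ``i+1``) bonds cross
between strands ("lateral").

All rest values of the derived spring network are *measured* on the
generating configuration, which therefore is the exact zero-energy state.

Internal units: nm for lengths, radians for angles.  Angstrom and degree
values are accepted and reported at the user boundary, matching structural
conventions (rise 27.8 A, twist -166.67 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

A_PER_NM = 10.0

__all__ = [
    "LatticeParams",
    "FilamentConfiguration",
    "SpringTopology",
    "MechanicalParams",
    "build_canonical_lattice",
    "derive_topology",
    "load_params",
    "save_xyz",
    "save_csv",
]


@dataclass(frozen=True)
class LatticeParams:
    """Helical lattice parameters of the canonical filament.

    Parameters
    ----------
    rise_A:
        Axial translation per subunit along the genetic helix, in Angstrom.
    twist_deg:
        Signed azimuthal rotation per subunit, in degrees.  Negative for the
        left-handed genetic helix of F-actin.
    radius_A:
        Distance of the subunit centroid from the helix axis, in Angstrom.
        Not stated by the canonical helical symmetry itself; the default of
        25 A approximates the centroid radius of an actin protomer in the
        filament.
    n_subunits:
        Number of subunits.
    """

    rise_A: float = 27.8
    twist_deg: float = -166.67
    radius_A: float = 25.0
    n_subunits: int = 100

    def __post_init__(self) -> None:
        if not np.isfinite([self.rise_A, self.twist_deg, self.radius_A]).all():
            raise ValueError("lattice parameters must be finite")
        if self.rise_A <= 0:
            raise ValueError(f"rise must be positive, got {self.rise_A}")
        if self.radius_A <= 0:
            raise ValueError(f"radius must be positive, got {self.radius_A}")
        if abs(self.twist_deg) > 180:
            raise ValueError(f"|twist| must be <= 180 deg, got {self.twist_deg}")
        if self.n_subunits < 1:
            raise ValueError(f"need at least one subunit, got {self.n_subunits}")


@dataclass
class FilamentConfiguration:
    """Ordered subunit-centroid positions of one filament, in nm.

    ``positions[i]`` is subunit ``i`` in 0-based genetic-helix order.
    """

    positions: np.ndarray  # (n, 3) float, nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions must be finite")
        if len(self.positions) > 1:
            steps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
            if np.any(steps == 0):
                raise ValueError("consecutive positions must not coincide")

    @property
    def n_subunits(self) -> int:
        return len(self.positions)

    def positions_A(self) -> np.ndarray:
        return self.positions * A_PER_NM


@dataclass
class SpringTopology:
    """Bond / angle / dihedral table with rest values (nm, radians).

    ``bonds``: (nb, 2) int indices; ``bond_type`` entries are "lateral"
    (i, i+1) or "axial" (i, i+2); ``angles``: (na, 3) as (j, i, k) with the
    vertex i in the middle; ``dihedrals``: (nd, 4) quadruplets along the
    genetic helix and the long-pitch strands, multiplicity 1.
    """

    bonds: np.ndarray
    bond_type: np.ndarray  # array of "lateral"/"axial" strings
    bond_l0: np.ndarray  # nm
    angles: np.ndarray
    angle_theta0: np.ndarray  # radians, in (0, pi)
    dihedrals: np.ndarray
    dihedral_phi0: np.ndarray  # radians
    #: (nd, 2) rest sines of each dihedral's two arm angles, used by the
    #: bending-tapered torsion potential
    dihedral_rest_sines: np.ndarray = None
    dihedral_n: int = 1
    n_subunits: int = 0

    def n_angles_at_vertex(self, i: int) -> int:
        return int(np.sum(self.angles[:, 1] == i))

    def n_dihedrals_leading(self, i: int) -> int:
        return int(np.sum(self.dihedrals[:, 0] == i))


@dataclass(frozen=True)
class MechanicalParams:
    """Spring constants of the filament network.

    Units: ``k_l`` pN/nm, ``k_theta`` pN nm/rad^2, ``k_phi`` pN nm.  A single
    ``k_l`` is shared by lateral and axial bonds by default; the per-type
    overrides allow decoupling them.

    ``dihedral_mode`` selects the torsion potential: ``"cosine"`` is the
    plain k_phi [1 - cos(n phi - phi0)] form; ``"tapered"`` (the default)
    multiplies it by a bounded bending taper
    prod_arm s^2 / (s^2 + eps), s = sin(arm angle), eps = (s_rest / 2)^2,
    normalized to 1 at the rest geometry.  The taper switches the torsion
    off smoothly as a dihedral's three leading or trailing beads pass
    through collinearity — where the dihedral angle itself is discontinuous
    — and is bounded above by 1.5625, so bending a strand can never amplify
    its torsional rigidity.  This regularization is essential for stable
    integration of the nearly straight long-pitch strands; at equilibrium
    both forms have identical energy, forces and curvature, so static
    calibration is unaffected.
    """

    k_l: float
    k_theta: float
    k_phi: float
    k_l_lateral: float | None = None
    k_l_axial: float | None = None
    dihedral_mode: str = "tapered"

    def __post_init__(self) -> None:
        for name in ("k_l", "k_theta", "k_phi"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.dihedral_mode not in ("cosine", "tapered"):
            raise ValueError(f"unknown dihedral mode {self.dihedral_mode!r}")

    def bond_k(self, bond_type: np.ndarray) -> np.ndarray:
        """Per-bond stiffness array given the bond-type labels."""
        k_lat = self.k_l if self.k_l_lateral is None else self.k_l_lateral
        k_ax = self.k_l if self.k_l_axial is None else self.k_l_axial
        return np.where(bond_type == "lateral", k_lat, k_ax)

    def scaled(self, factor: float) -> "MechanicalParams":
        return MechanicalParams(
            k_l=self.k_l * factor,
            k_theta=self.k_theta * factor,
            k_phi=self.k_phi * factor,
            k_l_lateral=None if self.k_l_lateral is None else self.k_l_lateral * factor,
            k_l_axial=None if self.k_l_axial is None else self.k_l_axial * factor,
            dihedral_mode=self.dihedral_mode,
        )


def build_canonical_lattice(params: LatticeParams) -> FilamentConfiguration:
    """Place subunit centroids on the canonical helix.

    Subunit ``i`` sits at cylindrical coordinates
    ``(r = radius, angle = i * twist, z = i * rise)``, so every consecutive
    pair is related by exactly the stated rise and twist.
    """
    i = np.arange(params.n_subunits)
    ang = np.deg2rad(params.twist_deg) * i
    r_nm = params.radius_A / A_PER_NM
    z_nm = params.rise_A / A_PER_NM * i
    pos = np.column_stack([r_nm * np.cos(ang), r_nm * np.sin(ang), z_nm])
    return FilamentConfiguration(pos)


def _bond_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    lateral = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    axial = np.column_stack([np.arange(n - 2), np.arange(2, n)])
    return lateral, axial


def measure_bond_lengths(pos: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    return np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1)


def measure_angles(pos: np.ndarray, triplets: np.ndarray) -> np.ndarray:
    """Interior angle at the middle index of each (j, i, k) triplet."""
    u = pos[triplets[:, 0]] - pos[triplets[:, 1]]
    v = pos[triplets[:, 2]] - pos[triplets[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


def measure_dihedrals(pos: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angle of each (i, j, k, l) quadruplet, in (-pi, pi]."""
    b1 = pos[quads[:, 1]] - pos[quads[:, 0]]
    b2 = pos[quads[:, 2]] - pos[quads[:, 1]]
    b3 = pos[quads[:, 3]] - pos[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def derive_topology(config: FilamentConfiguration) -> SpringTopology:
    """Derive the spring network whose rest values are measured on ``config``.

    Bonds are (i, i+1) lateral and (i, i+2) axial.  Every particle is the
    vertex of all angle triplets formed by distinct pairs of its bonded
    neighbors {i-2, i-1, i+1, i+2}: interior particles carry the full
    C(4, 2) = 6 triplets.  Dihedrals follow the two helical paths, one
    quadruplet per leading particle: the genetic helix (i, i+1, i+2, i+3)
    and the long-pitch strand (i, i+2, i+4, i+6).
    """
    n = config.n_subunits
    if n < 7:
        raise ValueError(f"topology requires at least 7 subunits, got {n}")
    pos = config.positions

    lateral, axial = _bond_pairs(n)
    bonds = np.vstack([lateral, axial])
    bond_type = np.array(["lateral"] * len(lateral) + ["axial"] * len(axial))
    bond_l0 = measure_bond_lengths(pos, bonds)
    if np.any(bond_l0 <= 0):
        raise ValueError("degenerate bond of zero length")

    triplets = []
    for i in range(n):
        nbrs = [j for j in (i - 2, i - 1, i + 1, i + 2) if 0 <= j < n]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                triplets.append((nbrs[a], i, nbrs[b]))
    angles = np.array(triplets, dtype=int)
    theta0 = measure_angles(pos, angles)

    quads = []
    for i in range(n - 3):
        quads.append((i, i + 1, i + 2, i + 3))
    for i in range(n - 6):
        quads.append((i, i + 2, i + 4, i + 6))
    dihedrals = np.array(sorted(quads), dtype=int)
    phi0 = measure_dihedrals(pos, dihedrals)
    s1 = np.sin(measure_angles(pos, dihedrals[:, :3]))
    s2 = np.sin(measure_angles(pos, dihedrals[:, 1:]))
    rest_sines = np.column_stack([s1, s2])

    return SpringTopology(
        bonds=bonds,
        bond_type=bond_type,
        bond_l0=bond_l0,
        angles=angles,
        angle_theta0=theta0,
        dihedrals=dihedrals,
        dihedral_phi0=phi0,
        dihedral_rest_sines=rest_sines,
        dihedral_n=1,
        n_subunits=n,
    )


def load_params(path) -> LatticeParams:
    """Read lattice parameters from a plain-text ``key = value`` file."""
    fields = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    kwargs = {}
    for key in ("rise_A", "twist_deg", "radius_A"):
        if key in fields:
            kwargs[key] = float(fields[key])
    if "n_subunits" in fields:
        kwargs["n_subunits"] = int(fields["n_subunits"])
    return LatticeParams(**kwargs)


def save_xyz(config: FilamentConfiguration, path, comment: str = "") -> None:
    """Write one frame as XYZ with coordinates in Angstrom."""
    pos = config.positions_A()
    with open(path, "w") as fh:
        fh.write(f"{len(pos)}\n{comment}\n")
        for x, y, z in pos:
            fh.write(f"ACT {x:.4f} {y:.4f} {z:.4f}\n")


def save_csv(config: FilamentConfiguration, path) -> None:
    """Write (index, x, y, z) in Angstrom as CSV."""
    pos = config.positions_A()
    with open(path, "w") as fh:
        fh.write("index,x_A,y_A,z_A\n")
        for i, (x, y, z) in enumerate(pos):
            fh.write(f"{i},{x:.6f},{y:.6f},{z:.6f}\n")
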