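"""Averaged per-subdomain C-alpha displacements between protomer models.

A deformed protomer model (e.g. flexibly fitted into a density map) is
rigidly superposed onto a reference protomer; the displacement vector of
every shared C-alpha is computed, and displacements are averaged within
each actin subdomain.  The subdomain scheme is the standard set of
residue-range boundaries (subdomains 1-4 split into seven ranges); ranges
overlap at their shared boundary residues by construction and are kept as
stated, so a boundary residue may contribute to two subdomain means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProtomerModel",
    "SubdomainScheme",
    "DEFAULT_SCHEME",
    "kabsch",
    "superpose",
    "subdomain_vectors",
    "read_protomer",
]

#: Subdomain residue ranges (inclusive).
DEFAULT_RANGES = (
    (7, 35),
    (35, 72),
    (72, 147),
    (340, 377),
    (147, 183),
    (272, 340),
    (183, 272),
)


@dataclass
class ProtomerModel:
    """C-alpha coordinates (A) of one protomer, keyed by residue number."""

    coords: dict  # residue number -> (3,) array
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = {int(r): np.asarray(x, float) for r, x in self.coords.items()}
        for r, x in self.coords.items():
            if not np.isfinite(x).all():
                raise ValueError(f"non-finite coordinates at residue {r}")

    @property
    def residues(self) -> list:
        return sorted(self.coords)

    def array(self, residues) -> np.ndarray:
        return np.array([self.coords[r] for r in residues])


@dataclass(frozen=True)
class SubdomainScheme:
    ranges: tuple = DEFAULT_RANGES

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if not (1 <= lo <= hi):
                raise ValueError(f"bad range ({lo}, {hi})")

    def names(self) -> list:
        return [f"{lo}-{hi}" for lo, hi in self.ranges]


DEFAULT_SCHEME = SubdomainScheme()


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t: R @ x + t -> target.

    Reflections are rejected: the returned rotation always has det +1, so a
    mirrored model superposes with a nonzero residual rather than silently
    inverting chirality.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - rot @ mc
    return rot, trans


def superpose(
    model: ProtomerModel,
    reference: ProtomerModel,
    residues=None,
) -> tuple[ProtomerModel, float]:
    """Rigidly superpose ``model`` onto ``reference`` over shared C-alphas.

    Returns the transformed model and the RMSD (A) over the alignment set.
    ``residues`` restricts the alignment subset (default: all shared).
    """
    shared = sorted(set(model.coords) & set(reference.coords))
    if residues is not None:
        shared = sorted(set(shared) & set(residues))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared residues, got {len(shared)}")
    x = model.array(shared)
    y = reference.array(shared)
    rot, trans = kabsch(x, y)
    moved = {r: rot @ c + trans for r, c in model.coords.items()}
    rmsd = float(np.sqrt(np.mean(np.sum((x @ rot.T + trans - y) ** 2, axis=1))))
    return ProtomerModel(moved, model.chain_id, model.source), rmsd


def subdomain_vectors(
    aligned: ProtomerModel,
    reference: ProtomerModel,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
):
    """Mean displacement vector (A) per subdomain residue range.

    Returns a pandas DataFrame with one row per range: (subdomain, dx, dy,
    dz, magnitude, n_residues).  Ranges with no shared residues yield a NaN
    vector with n_residues = 0.
    """
    import pandas as pd

    shared = sorted(set(aligned.coords) & set(reference.coords))
    rows = []
    for (lo, hi), name in zip(scheme.ranges, scheme.names()):
        members = [r for r in shared if lo <= r <= hi]
        if members:
            disp = aligned.array(members) - reference.array(members)
            vec = disp.mean(axis=0)
            rows.append((name, *vec, float(np.linalg.norm(vec)), len(members)))
        else:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["subdomain", "dx", "dy", "dz", "magnitude", "n_residues"]
    )


def read_protomer(path, chain: str | None = None) -> ProtomerModel:
    """Read C-alpha coordinates from a PDB/mmCIF file (first model).

    ``chain`` selects one chain; default takes the first chain encountered.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        coords = {}
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                coords[res.seqid.num] = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
        if coords:
            return ProtomerModel(coords, ch.name, str(path))
    raise ValueError(f"no C-alpha atoms found in {path} (chain={chain})")
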