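"""Rigid-body superposition (Kabsch), RMSD, and per-residue displacement.

The optimal rotation is obtained from the SVD of the covariance of the
centered coordinate sets, with the usual determinant correction so the
result is a proper rotation. Displacements between paralog structures
are measured in a common frame obtained by superposing on all mapped
Cα atoms, which is the only frame the two structures define without a
manual choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence import ResidueMap
from .structure import Structure


@dataclass
class Superposition:
    rotation: np.ndarray  # (3,3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float
    atom_selection: str = "CA_only"
    n_atoms: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation matrix is not proper orthogonal")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid transform to an (n,3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0, "identity", 0)


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray, selection: str = "custom"
) -> Superposition:
    """Least-squares rigid transform mapping point set P onto Q.

    Returns the Superposition with the RMSD of the transformed P
    against Q. Requires at least 3 non-collinear points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"size mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return Superposition(R, t, rmsd, selection, len(P))


def _paired_coords(
    s_a: Structure, s_b: Structure, rmap: ResidueMap, selection: str
) -> tuple[np.ndarray, np.ndarray]:
    """Matched coordinate arrays for a residue-key map.

    ``CA_only`` uses Cα atoms; ``all_heavy`` uses all non-hydrogen atoms
    whose names occur in both members of a pair.
    """
    if not rmap.pairs:
        raise ValueError("empty residue map")
    A: list[np.ndarray] = []
    B: list[np.ndarray] = []
    for ka, kb in rmap.pairs:
        ra, rb = s_a.find(ka), s_b.find(kb)
        if ra is None or rb is None:
            continue
        if selection == "CA_only":
            aa, ab = ra.get_atom("CA"), rb.get_atom("CA")
            if aa is not None and ab is not None:
                A.append(aa.coords)
                B.append(ab.coords)
        elif selection == "all_heavy":
            names = {a.name for a in ra.atoms if a.element != "H"} & {
                a.name for a in rb.atoms if a.element != "H"
            }
            for name in sorted(names):
                A.append(ra.get_atom(name).coords)
                B.append(rb.get_atom(name).coords)
        else:
            raise ValueError(f"unknown selection {selection!r}")
    if not A:
        raise ValueError("selection produced no paired atoms")
    return np.array(A), np.array(B)


def paired_superpose(
    s_a: Structure, s_b: Structure, rmap: ResidueMap, selection: str = "CA_only"
) -> Superposition:
    """Optimal superposition of A onto B over mapped residues."""
    P, Q = _paired_coords(s_a, s_b, rmap, selection)
    return kabsch_superpose(P, Q, selection)


def paired_rmsd(
    s_a: Structure, s_b: Structure, rmap: ResidueMap, selection: str = "CA_only"
) -> float:
    """RMSD (Å) after optimal superposition on the selected atoms."""
    return paired_superpose(s_a, s_b, rmap, selection).rmsd


def fixed_frame_rmsd(
    s_a: Structure,
    s_b: Structure,
    rmap: ResidueMap,
    selection: str = "CA_only",
    frame: Superposition | None = None,
) -> float:
    """RMSD in a given frame (no re-fitting); identity frame by default."""
    P, Q = _paired_coords(s_a, s_b, rmap, selection)
    frame = frame or Superposition.identity()
    diff = frame.transform(P) - Q
    return float(np.sqrt((diff**2).sum() / len(P)))


def residue_displacement(
    s_a: Structure,
    s_b: Structure,
    rmap: ResidueMap,
    residue_key: tuple,
    atom_name: str = "CA",
    frame: Superposition | None = None,
) -> float:
    """Distance (Å) between one atom of a mapped residue pair.

    The atom of A is moved into B's frame with ``frame`` (typically the
    whole-protomer Cα superposition; identity if omitted) and compared
    with its partner in B.
    """
    a2b = rmap.a_to_b()
    if residue_key not in a2b:
        raise KeyError(f"residue {residue_key} is not in the map")
    ra = s_a.find(residue_key)
    rb = s_b.find(a2b[residue_key])
    aa = ra.get_atom(atom_name) if ra else None
    ab = rb.get_atom(atom_name) if rb else None
    if aa is None or ab is None:
        raise ValueError(f"atom {atom_name} missing in residue pair {residue_key}")
    frame = frame or Superposition.identity()
    moved = frame.transform(aa.coords[None, :])[0]
    return float(np.linalg.norm(moved - ab.coords))


def displacement_table(
    s_a: Structure,
    s_b: Structure,
    rmap: ResidueMap,
    atom_name: str = "CA",
    frame: Superposition | None = None,
) -> list[tuple[tuple, float]]:
    """Per-residue displacement for every mapped residue with the atom."""
    frame = frame or paired_superpose(s_a, s_b, rmap, "CA_only")
    out = []
    for ka, _ in rmap.pairs:
        try:
            out.append((ka, residue_displacement(s_a, s_b, rmap, ka, atom_name, frame)))
        except ValueError:
            continue
    return out
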