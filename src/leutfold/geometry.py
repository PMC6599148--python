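"""Shared geometric primitives: dihedral angles and side-chain χ atom tables.

χ definitions follow the standard heavy-atom convention (χ1 = N–CA–CB–CG for
aromatic residues, etc.).  Angles are signed, right-handed, reported in
degrees in (−180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "CHI_ATOMS", "chi_atom_names", "rotation_about_axis"]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (−180, 180]) for four points.

    Standard convention: looking down the p1→p2 bond, the angle from the
    p0–p1 bond projection to the p2–p3 bond projection, positive clockwise.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("degenerate dihedral: central bond has zero length")
    b1u = b1 / nb1
    # components perpendicular to the central bond
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("zero-length rotation axis")
    x, y, z = axis / n
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


#: Four defining atoms of each χ dihedral, per residue type.  χ1 entries use
#: the standard γ heavy atom; branched residues follow the IUPAC primary
#: branch (CG1 for ILE/VAL, OG for SER, ...).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def chi_atom_names(resname: str, chi_index: int) -> tuple[str, str, str, str]:
    """The four atom names defining χ_{chi_index} of a residue type."""
    chis = CHI_ATOMS.get(resname.upper())
    if not chis:
        raise ValueError(f"residue type {resname!r} has no χ dihedrals")
    if not 1 <= chi_index <= len(chis):
        raise ValueError(f"{resname} has no χ{chi_index}")
    return chis[chi_index - 1]
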