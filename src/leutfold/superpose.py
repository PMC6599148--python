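"""Least-squares rigid-body superposition and segment-fit evaluation.

The central primitive is the Kabsch fit: the rotation + translation that
minimises the RMSD between two equal-length point sets, computed by singular
value decomposition of the covariance matrix with the standard determinant
correction to exclude reflections.  On top of it sit the hash-domain
alignment (the scaffold helices TM3/TM4/TM8/TM9 of the LeuT fold are the
conventional superposition frame for conformational comparisons) and the
segment-fit table used to pick chimeric template boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .structures_io import (
    BACKBONE_NAMES,
    AtomSelection,
    RoleMap,
    Structure,
    select,
)

__all__ = [
    "RigidTransform",
    "SegmentMap",
    "kabsch_fit",
    "rmsd_nofit",
    "hash_superpose",
    "segment_fit_table",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body motion x ↦ R·x + t (Å)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, atol: float = 1e-6) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


@dataclass
class Segment:
    """One paired target/donor residue range of a chimeric segment map."""

    label: str
    target_range: tuple[int, int]
    donor_range: tuple[int, int]
    target_chain: str = "A"
    donor_chain: str = "A"

    def __post_init__(self) -> None:
        for rng in (self.target_range, self.donor_range):
            if rng[1] < rng[0]:
                raise ValueError(f"segment {self.label}: bad range {rng}")


@dataclass
class SegmentMap:
    """Paired target/donor residue ranges defining repositioned segments."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        for which in ("target_range", "donor_range"):
            spans = sorted(getattr(s, which) for s in self.segments)
            for a, b in zip(spans, spans[1:]):
                if b[0] <= a[1]:
                    raise ValueError(
                        f"overlapping {which.split('_')[0]} ranges {a} and {b}"
                    )

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentMap":
        doc = yaml.safe_load(Path(path).read_text())
        segs = [
            Segment(
                label=e["label"],
                target_range=tuple(e["target"]),
                donor_range=tuple(e["donor"]),
                target_chain=e.get("target_chain", "A"),
                donor_chain=e.get("donor_chain", "A"),
            )
            for e in doc["segments"]
        ]
        return cls(segs)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "segments": [
                {
                    "label": s.label,
                    "target": list(s.target_range),
                    "donor": list(s.donor_range),
                    "target_chain": s.target_chain,
                    "donor_chain": s.donor_chain,
                }
                for s in self.segments
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------


def kabsch_fit(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform minimising the RMSD of the transformed
    mobile coordinates against the target, and that minimum RMSD (Å).
    Requires ≥3 non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered mobile cloud
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def rmsd_nofit(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square of paired distances without superposition."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate lists must be matching (N, 3) arrays")
    if A.shape[0] < 1:
        raise ValueError("need at least one coordinate pair")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def _paired_backbone(
    mobile: Structure,
    reference: Structure,
    resids_mobile: Sequence[int],
    resids_reference: Sequence[int],
    chain_mobile: str,
    chain_reference: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinate pairs, matching residues by position within the
    role/segment ranges (i-th residue to i-th residue), atoms by name."""
    if len(resids_mobile) != len(resids_reference):
        raise ValueError("residue lists have different lengths")
    mob_pts: list[np.ndarray] = []
    ref_pts: list[np.ndarray] = []
    for rm, rr in zip(resids_mobile, resids_reference):
        am = {a.name: a for a in mobile.residue_atoms(chain_mobile, rm)}
        ar = {a.name: a for a in reference.residue_atoms(chain_reference, rr)}
        for name in BACKBONE_NAMES:
            if name in am and name in ar:
                mob_pts.append(am[name].coords)
                ref_pts.append(ar[name].coords)
    if not mob_pts:
        raise ValueError("no pairable backbone atoms")
    return np.stack(mob_pts), np.stack(ref_pts)


def hash_superpose(
    mobile: Structure,
    reference: Structure,
    roles: RoleMap,
    roles_reference: RoleMap | None = None,
) -> RigidTransform:
    """Rigid transform superposing ``mobile`` onto ``reference`` using the
    backbone atoms of the hash scaffold (TM3 + TM4 + TM8 + TM9).

    The transform is returned, not applied — callers decide what to move.
    With two role maps, hash residues are paired positionally between the two
    numbering schemes (e.g. a transporter vs a bacterial homologue).
    """
    roles_ref = roles_reference or roles
    missing = []
    for st, rm, tag in ((mobile, roles, "mobile"), (reference, roles_ref, "reference")):
        try:
            rm.resolve(st, "hash")
        except ValueError:
            missing.append(tag)
    if missing:
        raise ValueError(f"hash residues missing in: {', '.join(missing)}")
    ids_mob = roles.resolve(mobile, "hash")
    ids_ref = roles_ref.resolve(reference, "hash")
    if len(ids_mob) != len(ids_ref):
        # pair positionally on the common length (truncation at range ends)
        n = min(len(ids_mob), len(ids_ref))
        ids_mob, ids_ref = ids_mob[:n], ids_ref[:n]
    P, Q = _paired_backbone(
        mobile, reference, ids_mob, ids_ref, roles.chain, roles_ref.chain
    )
    transform, _ = kabsch_fit(P, Q)
    return transform


def segment_fit_table(
    target: Structure,
    donor: Structure,
    candidates: Sequence[SegmentMap],
    roles_target: RoleMap,
    roles_donor: RoleMap | None = None,
) -> pd.DataFrame:
    """Evaluate candidate segment maps for chimeric template construction.

    The donor is first hash-superposed onto the target; then for each
    candidate each target segment is Kabsch-fitted (backbone atoms) to its
    donor segment.  The combined RMSD is the atom-count-weighted RMS over
    segments.  The table is sorted by (descending total residues, ascending
    combined RMSD) — the "largest combination of fragments with the smallest
    RMSD" rule.  Unpairable candidates are marked unevaluable, not fatal.
    """
    roles_donor = roles_donor or roles_target
    tf = hash_superpose(donor, target, roles_donor, roles_target)
    donor_aligned = tf.apply_structure(donor)
    rows = []
    for ci, cand in enumerate(candidates):
        per_segment: dict[str, float] = {}
        ssq_sum = 0.0
        n_atoms = 0
        n_res = 0
        evaluable = True
        for seg in cand:
            t_ids = list(range(seg.target_range[0], seg.target_range[1] + 1))
            d_ids = list(range(seg.donor_range[0], seg.donor_range[1] + 1))
            if len(t_ids) != len(d_ids):
                evaluable = False
                break
            try:
                P, Q = _paired_backbone(
                    target, donor_aligned, t_ids, d_ids,
                    seg.target_chain, seg.donor_chain,
                )
                _, rmsd = kabsch_fit(P, Q)
            except ValueError:
                evaluable = False
                break
            per_segment[seg.label] = rmsd
            ssq_sum += rmsd**2 * len(P)
            n_atoms += len(P)
            n_res += len(t_ids)
        rows.append(
            {
                "candidate": ci,
                "n_segments": len(cand),
                "total_residues": n_res if evaluable else 0,
                "combined_rmsd": (
                    float(np.sqrt(ssq_sum / n_atoms)) if evaluable else np.nan
                ),
                "evaluable": evaluable,
                "per_segment_rmsd": per_segment if evaluable else {},
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["evaluable", "total_residues", "combined_rmsd"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df
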