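"""Docking-pose clustering and interaction fingerprints.

Poses are clustered pairwise on the coordinate RMSD *without fitting* —
ligand heavy atoms concatenated with the binding-site backbone atoms — using
average-linkage (UPGMA) agglomeration.  The number of clusters is chosen at
the minimum of the Kelley penalty: the min–max-normalised mean intra-cluster
spread (scaled onto [1, N−2]) plus the cluster count, in the published
Kelley–Gardner–Sutcliffe formulation.

Cluster characterisation uses distance-criterion interaction fingerprints
(ionic, H-bond and proximity bits, each reported with its distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structures_io import Structure
from .superpose import rmsd_nofit

__all__ = [
    "Pose",
    "PoseSet",
    "ClusterTree",
    "pose_distance_matrix",
    "average_linkage",
    "kelley_select",
    "InteractionDef",
    "fingerprints",
    "serotonin_fingerprint_defs",
]


@dataclass
class Pose:
    """One docking pose: ligand atoms by name plus the refined binding-site
    backbone coordinates, with opaque score labels."""

    ligand_names: list[str]
    ligand_coords: np.ndarray  # (L, 3)
    ligand_elements: list[str] | None = None
    site_coords: np.ndarray | None = None  # (M, 3), backbone of site residues
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        if self.ligand_coords.shape != (len(self.ligand_names), 3):
            raise ValueError("ligand coords/names mismatch")
        if self.site_coords is not None:
            self.site_coords = np.asarray(self.site_coords, dtype=float)

    def heavy_mask(self) -> np.ndarray:
        if self.ligand_elements is None:
            return np.ones(len(self.ligand_names), dtype=bool)
        return np.array([e.upper() not in ("H", "D")
                         for e in self.ligand_elements])

    def metric_coords(self) -> np.ndarray:
        parts = [self.ligand_coords[self.heavy_mask()]]
        if self.site_coords is not None:
            parts.append(self.site_coords)
        return np.concatenate(parts, axis=0)

    def ligand_atom(self, name: str) -> np.ndarray:
        try:
            return self.ligand_coords[self.ligand_names.index(name)]
        except ValueError:
            raise KeyError(f"ligand atom {name!r} not in pose")


@dataclass
class PoseSet:
    poses: list[Pose]

    def __post_init__(self) -> None:
        if self.poses:
            names = self.poses[0].ligand_names
            nsite = (
                0
                if self.poses[0].site_coords is None
                else len(self.poses[0].site_coords)
            )
            for i, p in enumerate(self.poses):
                if p.ligand_names != names:
                    raise ValueError(f"pose {i}: ligand atom naming differs")
                ns = 0 if p.site_coords is None else len(p.site_coords)
                if ns != nsite:
                    raise ValueError(f"pose {i}: site atom count differs")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


@dataclass
class ClusterTree:
    """Average-linkage merge history with the Kelley penalty per level."""

    linkage_matrix: np.ndarray  # scipy (N-1, 4) format
    n_leaves: int
    penalties: dict[int, float] = field(default_factory=dict)  # k -> K(k)
    selected_k: int | None = None

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def labels(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) at level k."""
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def pose_distance_matrix(poses: PoseSet) -> np.ndarray:
    """Symmetric matrix of pairwise no-fit RMSDs (Å) over ligand heavy atoms
    concatenated with binding-site backbone atoms."""
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    coords = [p.metric_coords() for p in poses]
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd_nofit(coords[i], coords[j])
    return D


def average_linkage(matrix: np.ndarray) -> ClusterTree:
    """UPGMA agglomeration on a symmetric, zero-diagonal distance matrix."""
    D = np.asarray(matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    Z = linkage(squareform(D, checks=False), method="average")
    return ClusterTree(Z, n_leaves=D.shape[0])


def kelley_select(tree: ClusterTree, matrix: np.ndarray) -> int:
    """Choose the cluster count at the minimum of the Kelley penalty.

    For each level k in 2..N−1: the average spread is the mean over clusters
    of size ≥ 2 of the mean pairwise intra-cluster distance; spreads are
    min–max normalised across levels onto [1, N−2]; the penalty is
    K(k) = normalised spread + k.  Ties pick the smaller k.  The tree is
    annotated with the penalties and the selection.
    """
    N = tree.n_leaves
    if N < 4:
        raise ValueError("Kelley selection needs at least 4 items")
    D = np.asarray(matrix, dtype=float)
    spreads: dict[int, float] = {}
    for k in range(2, N):
        labels = tree.labels(k)
        cluster_spreads = []
        for c in np.unique(labels):
            idx = np.nonzero(labels == c)[0]
            if len(idx) < 2:
                continue  # singletons contribute no spread
            sub = D[np.ix_(idx, idx)]
            m = len(idx)
            cluster_spreads.append(sub.sum() / (m * (m - 1)))
        if cluster_spreads:
            spreads[k] = float(np.mean(cluster_spreads))
    if not spreads:
        raise ValueError("degenerate tree: all clusters singletons at every level")
    vals = np.array(list(spreads.values()))
    smin, smax = vals.min(), vals.max()
    penalties: dict[int, float] = {}
    for k, s in spreads.items():
        if smax > smin:
            norm = (s - smin) / (smax - smin) * (N - 3) + 1.0
        else:
            norm = 1.0
        penalties[k] = norm + k
    k_star = min(penalties, key=lambda k: (penalties[k], k))
    tree.penalties = penalties
    tree.selected_k = k_star
    return k_star


# ---------------------------------------------------------------------------
# interaction fingerprints


@dataclass(frozen=True)
class InteractionDef:
    """A named distance-criterion interaction bit.

    ``protein_atoms`` restricts the partner atoms of the residue (None = any
    heavy atom).  Default cutoffs by kind: ionic ≤ 4.0 Å between charged-group
    heavy atoms, H-bond ≤ 3.5 Å donor–acceptor, proximity ≤ 4.5 Å.
    """

    name: str
    ligand_atom: str
    resid: int
    kind: str = "proximity"  # ionic | hbond | proximity
    protein_atoms: tuple[str, ...] | None = None
    cutoff: float | None = None
    chain: str = "A"

    DEFAULT_CUTOFFS = {"ionic": 4.0, "hbond": 3.5, "proximity": 4.5}

    def effective_cutoff(self) -> float:
        return (
            self.cutoff
            if self.cutoff is not None
            else self.DEFAULT_CUTOFFS[self.kind]
        )


def serotonin_fingerprint_defs(
    cationic_n: str = "NZ",
    c6: str = "C6",
    hydroxyl_o: str = "O5",
    indole_n: str = "NE1",
) -> list[InteractionDef]:
    """The four serotonin-recognition bits used to characterise pose clusters:
    the D98 salt bridge to the cationic amine, C6 proximity to A173, the
    5-hydroxyl H-bond to T439, and the indole nitrogen pointing at F341.
    Ligand atom names are arguments because pose files vary in naming."""
    return [
        InteractionDef("D98_ionic", cationic_n, 98, "ionic",
                       ("OD1", "OD2")),
        InteractionDef("A173_C6", c6, 173, "proximity"),
        InteractionDef("T439_5OH", hydroxyl_o, 439, "hbond", ("OG1",)),
        InteractionDef("F341_indoleN", indole_n, 341, "proximity"),
    ]


def fingerprints(
    pose: Pose,
    protein: Structure,
    defs: Sequence[InteractionDef],
) -> pd.DataFrame:
    """Evaluate interaction bits for one pose against the protein.

    Returns a table with one row per definition: the measured minimum
    distance, the cutoff, and the bit (True/False, or None when a named atom
    is unresolvable)."""
    rows = []
    for d in defs:
        cutoff = d.effective_cutoff()
        row = {"name": d.name, "cutoff_A": cutoff}
        try:
            lig = pose.ligand_atom(d.ligand_atom)
        except KeyError:
            row.update({"distance_A": np.nan, "bit": None,
                        "note": f"ligand atom {d.ligand_atom} missing"})
            rows.append(row)
            continue
        res_atoms = [
            a
            for a in protein.residue_atoms(d.chain, d.resid)
            if not a.is_hydrogen
            and (d.protein_atoms is None or a.name in d.protein_atoms)
        ]
        if not res_atoms:
            row.update({"distance_A": np.nan, "bit": None,
                        "note": f"residue {d.chain}/{d.resid} atoms missing"})
            rows.append(row)
            continue
        dist = float(
            min(np.linalg.norm(a.coords - lig) for a in res_atoms)
        )
        row.update({"distance_A": dist, "bit": bool(dist <= cutoff), "note": ""})
        rows.append(row)
    return pd.DataFrame(rows, columns=["name", "distance_A", "cutoff_A",
                                       "bit", "note"])
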