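"""Pathway-hydration analysis: compartment water counts and occupancy grids.

The protein interior is modelled as a residue-anchored 20 × 15 × 25 Å box
split along z (the membrane normal) into three bands: extracellular
vestibule (9 Å), orthosteric binding site (7 Å), and intracellular vestibule
(9 Å).  The orthosteric band is centred between the extracellular lid
anchors (Y176/F335 CA) and the cytoplasmic anchor (F341 CA); x,y are centred
on the same anchors.  Membrane alignment (z = normal) is the caller's
responsibility.

Waters are located by their O atom — one point per molecule, for count
stability.  Compartment intervals are half-open, closed at the *top*
(z_low, z_high], so a water exactly on a shared boundary is assigned to the
lower-z compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures_io import AtomSelection, RoleMap, Structure
from .superpose import kabsch_fit

__all__ = [
    "CompartmentSpec",
    "OccupancyGrid",
    "build_compartments",
    "water_counts",
    "water_oxygens",
    "occupancy_map",
    "write_dx",
]

BOX_X, BOX_Y, BOX_Z = 20.0, 15.0, 25.0
EC_LEN, SITE_LEN, IC_LEN = 9.0, 7.0, 9.0


@dataclass
class CompartmentSpec:
    """The oriented compartment box.

    ``z_bounds`` are the four z values (ascending) delimiting, from the
    bottom: intracellular vestibule, orthosteric site, extracellular
    vestibule.  Extents: 20 (x) × 15 (y) × 25 (z) Å with the z partition
    9 / 7 / 9 Å.
    """

    center_xy: np.ndarray  # (2,)
    z_bounds: np.ndarray  # (4,), ascending: ic_low, site_low, site_high, ec_high
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        self.z_bounds = np.asarray(self.z_bounds, dtype=float)
        if self.z_bounds.shape != (4,) or np.any(np.diff(self.z_bounds) <= 0):
            raise ValueError("z_bounds must be 4 strictly ascending values")
        spans = np.diff(self.z_bounds)
        if not np.allclose(spans, [IC_LEN, SITE_LEN, EC_LEN]):
            raise ValueError("z partition must be 9 / 7 / 9 Å bottom to top")

    def compartment_of(self, xyz: np.ndarray) -> str | None:
        """'ec', 'site', 'ic' or None (outside).  Intervals are (low, high]
        in z so boundary points fall to the lower-z compartment; x and y are
        symmetric half-open boxes."""
        x, y, z = xyz
        cx, cy = self.center_xy
        if not (cx - BOX_X / 2 <= x < cx + BOX_X / 2):
            return None
        if not (cy - BOX_Y / 2 <= y < cy + BOX_Y / 2):
            return None
        z0, z1, z2, z3 = self.z_bounds
        if z0 < z <= z1:
            return "ic"
        if z1 < z <= z2:
            return "site"
        if z2 < z <= z3:
            return "ec"
        return None


def build_compartments(
    structure: Structure,
    roles: RoleMap,
    strict: bool = True,
) -> CompartmentSpec:
    """Anchor the compartment box on the orthosteric-site residues.

    The orthosteric z band is centred between the mean CA z of the
    extracellular lid anchors and the CA z of the cytoplasmic anchor, padded
    to exactly 7 Å.  If the anchor span itself exceeds 7 Å, strict mode
    errors (the structure is probably not membrane-aligned); otherwise a
    warning is issued.
    """
    import warnings

    def anchor_cas(role: str) -> np.ndarray:
        ids = roles.resolve(structure, role)
        pts = []
        for r in ids:
            for a in structure.residue_atoms(roles.chain, r):
                if a.name == "CA":
                    pts.append(a.coords)
        if not pts:
            raise ValueError(f"no CA atoms for anchor role {role!r}")
        return np.stack(pts)

    ec_cas = anchor_cas("site_anchors_ec")
    cyt_cas = anchor_cas("site_anchor_cyt")
    z_top = float(ec_cas[:, 2].mean())
    z_bot = float(cyt_cas[:, 2].mean())
    if z_top < z_bot:
        raise ValueError(
            "extracellular anchors below cytoplasmic anchor: structure is "
            "not membrane-aligned with z as the normal"
        )
    span = z_top - z_bot
    if span > SITE_LEN:
        msg = (f"orthosteric anchor span {span:.2f} Å exceeds the {SITE_LEN} Å "
               f"site band")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    z_mid = 0.5 * (z_top + z_bot)
    site_lo = z_mid - SITE_LEN / 2
    site_hi = z_mid + SITE_LEN / 2
    z_bounds = np.array(
        [site_lo - IC_LEN, site_lo, site_hi, site_hi + EC_LEN]
    )
    all_anchors = np.vstack([ec_cas, cyt_cas])
    center_xy = all_anchors[:, :2].mean(axis=0)
    return CompartmentSpec(
        center_xy,
        z_bounds,
        anchors={
            "site_anchors_ec": ec_cas.tolist(),
            "site_anchor_cyt": cyt_cas.tolist(),
        },
    )


def water_oxygens(frame: Structure) -> list[np.ndarray]:
    """Positions of water oxygen atoms (waters are located by O only)."""
    return [
        a.coords
        for a in frame.atoms
        if a.is_water and a.element.upper() == "O"
    ]


def water_counts(frame: Structure, spec: CompartmentSpec
                 ) -> tuple[int, int, int]:
    """(n_extracellular, n_site, n_intracellular) water counts in the box."""
    counts = {"ec": 0, "site": 0, "ic": 0}
    for pos in water_oxygens(frame):
        comp = spec.compartment_of(pos)
        if comp is not None:
            counts[comp] += 1
    return counts["ec"], counts["site"], counts["ic"]


# ---------------------------------------------------------------------------
# occupancy grid


@dataclass
class OccupancyGrid:
    """Frame-averaged water occupancy on a regular grid.

    Voxel values are occupied-frame fractions in [0, 1]; spacing in Å.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    n_frames: int

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancies must lie in [0, 1]")


def occupancy_map(
    traj,
    ligand_expr: str,
    radius: float = 20.0,
    spacing: float = 2.0,
    protein_fit_expr: str = "backbone",
) -> OccupancyGrid:
    """Water-occupancy grid around the ligand, averaged over frames.

    Every frame is Kabsch-fitted to frame 0 on all protein backbone atoms
    (``protein_fit_expr``); water oxygens within ``radius`` Å of any ligand
    atom are binned at ``spacing`` Å resolution; each voxel's value is the
    fraction of frames in which it held at least one water.
    """
    from .structures_io import select

    frames = traj.frames
    ref = frames[0]
    fit_idx = select(ref, protein_fit_expr).indices
    if len(fit_idx) < 3:
        raise ValueError("protein fit selection too small")
    lig_idx = select(ref, ligand_expr).indices
    if len(lig_idx) == 0:
        raise ValueError("ligand selection empty in frame 0")
    ref_fit = ref.coords[fit_idx]

    # grid covers the frame-0 ligand bounding box padded by the radius
    lig0 = ref.coords[lig_idx]
    lo = lig0.min(axis=0) - radius
    hi = lig0.max(axis=0) + radius
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    counts = np.zeros(shape, dtype=float)

    for fi, frame in enumerate(frames):
        xyz = frame.coords
        lig = xyz[lig_idx]
        if not np.all(np.isfinite(lig)):
            raise ValueError(f"ligand missing or invalid in frame {fi}")
        if fi == 0:
            moved = xyz
        else:
            tf, _ = kabsch_fit(xyz[fit_idx], ref_fit)
            moved = tf.apply(xyz)
        lig_m = moved[lig_idx]
        occupied: set[tuple[int, int, int]] = set()
        waters = [
            moved[i]
            for i, a in enumerate(frame.atoms)
            if a.is_water and a.element.upper() == "O"
        ]
        for w in waters:
            if np.min(np.linalg.norm(lig_m - w, axis=1)) > radius:
                continue
            ijk = np.floor((w - lo) / spacing).astype(int)
            if np.all(ijk >= 0) and np.all(ijk < shape):
                occupied.add(tuple(ijk))
        for ijk in occupied:
            counts[ijk] += 1.0
    return OccupancyGrid(lo, spacing, counts / len(frames), len(frames))


def write_dx(grid: OccupancyGrid, path: str | Path) -> None:
    """Write an occupancy grid in OpenDX volumetric text format."""
    nx, ny, nz = grid.values.shape
    sp = grid.spacing
    ox, oy, oz = grid.origin
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.4f} {oy:.4f} {oz:.4f}",
        f"delta {sp:.4f} 0 0",
        f"delta 0 {sp:.4f} 0",
        f"delta 0 0 {sp:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.reshape(-1)  # C order: z fastest-varying, as DX expects
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")
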