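"""Conformational-state metrics: gate distances, χ1 dihedrals, helix tilts,
RMSD time series, and normalised distributions.

These are the quantities that distinguish outward-open from outward-occluded
states of a LeuT-fold transporter: minimum heavy-atom distances across the
extracellular (R104–E493, Y176–F335) and intracellular (R79–D452, W82–Y350,
Y350–E444, E444–R462) gate pairs, the F335 lid rotamer (χ1), and the tilt of
the mobile bundle helices (TM1b, TM6a) relative to a reference state after
hash-domain superposition.

Gate distances use heavy atoms only: the crystal templates carry no
hydrogens, and the comparisons are against X-ray states.  Distances are Å
internally; series can be emitted in nm (explicit unit field).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import chi_atom_names, dihedral
from .structures_io import AtomSelection, RoleMap, Structure, select
from .superpose import hash_superpose, kabsch_fit

__all__ = [
    "Trajectory",
    "DistanceSeries",
    "Histogram",
    "min_distance",
    "pair_series",
    "replica_mean_sem",
    "chi1",
    "helix_tilt",
    "rmsd_series",
    "normalized_histogram",
]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with times in ns."""

    frames: list[Structure]
    times: np.ndarray  # ns

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames differ in length")
        if len(self.frames) == 0:
            raise ValueError("empty trajectory")
        n0 = len(self.frames[0].atoms)
        if any(len(f.atoms) != n0 for f in self.frames):
            raise ValueError("atom count varies across frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_models(
        cls, models: Sequence[Structure], dt_ns: float = 0.02, t0_ns: float = 0.0
    ) -> "Trajectory":
        """Wrap multi-model PDB output as a trajectory with a fixed time step
        (default 20 ps, a common trajectory-output interval)."""
        times = t0_ns + dt_ns * np.arange(len(models))
        return cls(list(models), times)


@dataclass
class DistanceSeries:
    """A labelled per-frame scalar series with an explicit unit."""

    label: str
    times: np.ndarray
    values: np.ndarray
    unit: str = "A"
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values differ in length")
        if np.any(self.values < 0):
            raise ValueError("distance values must be >= 0")

    def to_unit(self, unit: str) -> "DistanceSeries":
        if unit == self.unit:
            return self
        factor = {("A", "nm"): 0.1, ("nm", "A"): 10.0}.get((self.unit, unit))
        if factor is None:
            raise ValueError(f"cannot convert {self.unit} -> {unit}")
        return DistanceSeries(
            self.label,
            self.times,
            self.values * factor,
            unit,
            None if self.sem is None else self.sem * factor,
        )


@dataclass
class Histogram:
    """Normalised density over bins: densities · bin width sums to 1."""

    edges: np.ndarray
    densities: np.ndarray
    unit: str = "A"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        total = float(np.sum(self.densities * np.diff(self.edges)))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"densities integrate to {total}, not 1")


def min_distance(
    frame: Structure,
    selA: AtomSelection,
    selB: AtomSelection,
    heavy_only: bool = True,
) -> float:
    """Minimum distance (Å) over all cross pairs of two selections."""
    atoms_a = [a for a in selA.atoms if not (heavy_only and a.is_hydrogen)]
    atoms_b = [a for a in selB.atoms if not (heavy_only and a.is_hydrogen)]
    if not atoms_a or not atoms_b:
        raise ValueError("empty selection in min_distance")
    A = np.stack([a.coords for a in atoms_a])
    B = np.stack([a.coords for a in atoms_b])
    d, _ = cKDTree(B).query(A, k=1)
    return float(d.min())


def pair_series(
    traj: Trajectory,
    pairs: Sequence[tuple[int, int]],
    chain: str = "A",
    stride: int = 1,
) -> list[DistanceSeries]:
    """Per-frame minimum heavy-atom distance for each residue pair."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    # resolve atom indices once on the shared topology
    topo = traj.frames[0]
    idx_pairs = []
    for ra, rb in pairs:
        ia = [
            i
            for i, a in enumerate(topo.atoms)
            if a.chain == chain and a.resid == ra and not a.is_hydrogen
        ]
        ib = [
            i
            for i, a in enumerate(topo.atoms)
            if a.chain == chain and a.resid == rb and not a.is_hydrogen
        ]
        if not ia or not ib:
            raise ValueError(f"pair {ra}-{rb} unresolvable in topology")
        idx_pairs.append((ra, rb, np.array(ia), np.array(ib)))
    out = []
    frame_idx = range(0, len(traj), stride)
    times = traj.times[::stride]
    for ra, rb, ia, ib in idx_pairs:
        vals = []
        for fi in frame_idx:
            xyz = traj.frames[fi].coords
            diff = xyz[ia][:, None, :] - xyz[ib][None, :, :]
            vals.append(float(np.sqrt((diff**2).sum(-1)).min()))
        out.append(DistanceSeries(f"{ra}-{rb}", times, np.array(vals)))
    return out


def replica_mean_sem(series: Sequence[DistanceSeries]) -> DistanceSeries:
    """Aggregate replicas at matched times into mean ± standard error."""
    if not series:
        raise ValueError("no replicas")
    t0 = series[0].times
    for s in series[1:]:
        if s.unit != series[0].unit or not np.allclose(s.times, t0):
            raise ValueError("replicas must share times and units")
    stack = np.stack([s.values for s in series])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    )
    return DistanceSeries(
        series[0].label, t0, mean, series[0].unit, sem=sem
    )


def chi1(
    structure: Structure,
    resid: int,
    chain: str = "A",
    branch: str = "principal",
) -> float | None:
    """Side-chain χ1 (degrees) of a residue, or None if unevaluable.

    ``branch='principal'`` reports (−180, 180]; ``branch='negative'`` shifts
    positive angles by −360° — useful when comparing circular means that sit
    near the branch cut (e.g. rotamers reported around ±180°).
    """
    res_atoms = structure.residue_atoms(chain, resid)
    if not res_atoms:
        raise ValueError(f"no residue {chain}/{resid}")
    resname = res_atoms[0].resname
    try:
        names = chi_atom_names(resname, 1)
    except ValueError:
        return None  # GLY/ALA have no chi1
    by_name = {a.name: a for a in res_atoms}
    if any(n not in by_name for n in names):
        return None  # missing side-chain atoms: unevaluable, never guessed
    ang = dihedral(*(by_name[n].coords for n in names))
    if branch == "negative" and ang > 0:
        ang -= 360.0
    elif branch not in ("principal", "negative"):
        raise ValueError(f"unknown branch {branch!r}")
    return ang


def _helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of CA coordinates, oriented N→C."""
    if len(ca_coords) < 6:
        raise ValueError("helix axis needs at least 6 CA atoms")
    centered = ca_coords - ca_coords.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered)
    axis = Vt[0]
    if np.dot(axis, ca_coords[-1] - ca_coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_tilt(
    frame: Structure,
    reference: Structure,
    helix_role: str,
    roles: RoleMap,
    roles_reference: RoleMap | None = None,
) -> float:
    """Tilt (degrees, folded into [0, 90]) of a helix relative to a reference
    state, after hash-domain superposition of the frame onto the reference.

    The helix axis is the dominant principal axis of its CA coordinates,
    oriented N→C — a convention; the angle between the frame and reference
    axes is folded so axis-sign flips cannot produce angles above 90°.
    """
    roles_ref = roles_reference or roles
    tf = hash_superpose(frame, reference, roles, roles_ref)
    moved = tf.apply_structure(frame)

    def ca_coords(st: Structure, rm: RoleMap) -> np.ndarray:
        ids = rm.resolve(st, helix_role)
        pts = []
        for r in ids:
            for a in st.residue_atoms(rm.chain, r):
                if a.name == "CA":
                    pts.append(a.coords)
                    break
        return np.stack(pts)

    ax_f = _helix_axis(ca_coords(moved, roles))
    ax_r = _helix_axis(ca_coords(reference, roles_ref))
    cosang = np.clip(np.dot(ax_f, ax_r), -1.0, 1.0)
    ang = float(np.degrees(np.arccos(cosang)))
    return 180.0 - ang if ang > 90.0 else ang


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: str,
    exclusions: Sequence[str] = (),
    roles: RoleMap | None = None,
    fit_selection: str | None = None,
    unit: str = "A",
) -> DistanceSeries:
    """Per-frame RMSD to a reference over a selection.

    Default mode Kabsch-fits each frame's selection onto the reference
    selection and reports the fitted RMSD.  With ``fit_selection`` (ligand
    mode), the fit is computed on that selection (e.g. protein backbone) and
    the reported RMSD of ``selection`` is measured *unfitted in site* after
    applying the fit transform.  ``exclusions`` name roles (e.g. termini,
    the long extracellular loop) whose residues are removed from the
    selection first.
    """
    excluded: set[int] = set()
    chain = roles.chain if roles is not None else "A"
    for role in exclusions:
        if roles is None:
            raise ValueError("exclusions given without a role map")
        excluded.update(roles.resids(role))

    def indices(expr: str) -> np.ndarray:
        sel = select(reference, expr)
        idx = [
            i
            for i in sel.indices
            if not (
                reference.atoms[i].chain == chain
                and reference.atoms[i].resid in excluded
            )
        ]
        return np.array(idx, dtype=int)

    sel_idx = indices(selection)
    if len(sel_idx) == 0:
        raise ValueError("selection empty after exclusions")
    ref_sel = reference.coords[sel_idx]
    fit_idx = indices(fit_selection) if fit_selection else None
    ref_fit = reference.coords[fit_idx] if fit_idx is not None else None

    vals = []
    for f in traj.frames:
        xyz = f.coords
        if fit_idx is None:
            _, r = kabsch_fit(xyz[sel_idx], ref_sel)
        else:
            tf, _ = kabsch_fit(xyz[fit_idx], ref_fit)
            moved = tf.apply(xyz[sel_idx])
            r = float(np.sqrt(np.mean(np.sum((moved - ref_sel) ** 2, axis=1))))
        vals.append(r)
    series = DistanceSeries("rmsd", traj.times, np.array(vals), unit="A")
    return series.to_unit(unit) if unit != "A" else series


def normalized_histogram(
    values: DistanceSeries | Sequence[DistanceSeries] | np.ndarray,
    bin_width: float,
    unit: str | None = None,
) -> Histogram:
    """Histogram normalised to unit integral; replicas pool by concatenation."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(values, DistanceSeries):
        data = values.values
        unit = unit or values.unit
    elif isinstance(values, (list, tuple)) and values and isinstance(
        values[0], DistanceSeries
    ):
        units = {s.unit for s in values}
        if len(units) > 1:
            raise ValueError("cannot pool series with mixed units")
        data = np.concatenate([s.values for s in values])
        unit = unit or values[0].unit
    else:
        data = np.asarray(values, dtype=float)
        unit = unit or "A"
    if data.size == 0:
        raise ValueError("no values to histogram")
    lo = np.floor(data.min() / bin_width) * bin_width
    hi = np.ceil(data.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens, edges = np.histogram(data, bins=edges, density=True)
    return Histogram(edges, dens, unit=unit)
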