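"""Synthetic structural fixtures with recorded ground truth.

Everything downstream of the file readers can be exercised without any
external data: ideal α-helices with exact screw geometry, two-state toy
transporters whose bundle segments are rotated by *planted* angles, frames
with waters planted in known hydration compartments, and toy trajectories
realising planted distance and dihedral time courses.

Fixtures are poly-ALA backbones (N, CA, C, O, CB) with a PHE-like CG branch
added where χ1 is needed — non-physical side chains, geometrically exact.
Every planted quantity is returned in a ground-truth ledger dictionary, and
all randomness is seeded: the same seed reproduces bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import dihedral, rotation_about_axis
from .hydration import BOX_X, BOX_Y, CompartmentSpec
from .structures_io import AtomRecord, RoleMap, Structure
from .superpose import RigidTransform, Segment, SegmentMap
from .state_diagnostics import Trajectory

__all__ = [
    "FixtureSpec",
    "place_atom",
    "ideal_helix",
    "toy_transporter",
    "hydration_frame",
    "toy_trajectory",
]

# standard backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5


@dataclass
class FixtureSpec:
    """Parameters of the synthetic generators (fully deterministic per seed)."""

    seed: int = 0
    helix_len: int = 15
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    planted_angles: dict[str, float] = field(
        default_factory=lambda: {"TM1b": 17.0, "TM6a": 8.0}
    )
    noise_sigma: float = 0.0  # isotropic Gaussian per atom, Å
    global_transform: RigidTransform | None = None

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def place_atom(a, b, c, bond: float, angle: float, dihed: float) -> np.ndarray:
    """Position a fourth atom from three predecessors by internal coordinates
    (bond length to c, bond angle b–c–new, dihedral a–b–c–new, degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(dihed)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(
    n_res: int, phi: float, psi: float, omega: float = 180.0
) -> dict[str, np.ndarray]:
    """Backbone + CB coordinates of a poly-ALA chain with constant φ/ψ/ω.

    Returns arrays of shape (n_res, 3) for N, CA, C, O, CB."""
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed the first residue explicitly
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        if i + 1 < n_res:
            O[i] = place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)
        else:
            O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        # CB from the backbone frame; -122.6° branch dihedral vs C
        CB[i] = place_atom(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, -122.6)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _screw_parameters(chain: dict[str, np.ndarray]) -> tuple[float, float]:
    """(rise Å, twist degrees) of the screw relating consecutive residues."""
    from .superpose import kabsch_fit

    P = np.stack([chain[k][0] for k in ("N", "CA", "C")] +
                 [chain[k][1] for k in ("N", "CA", "C")])
    Q = np.stack([chain[k][1] for k in ("N", "CA", "C")] +
                 [chain[k][2] for k in ("N", "CA", "C")])
    tf, _ = kabsch_fit(P, Q)
    R, t = tf.rotation, tf.translation
    cos_t = (np.trace(R) - 1.0) / 2.0
    twist = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))
    # rotation axis from the antisymmetric part
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(w)
    if norm < 1e-9:
        return float(np.linalg.norm(t)), twist
    axis = w / norm
    rise = float(np.dot(t, axis))
    return abs(rise), twist


def _solve_phi_psi(rise: float, twist: float) -> tuple[float, float, float]:
    """Invert (φ, ψ, ω) ↦ (rise, twist) numerically, starting at the α-helix.

    ω is freed slightly from planarity so the requested screw geometry is hit
    exactly (the 2-parameter φ/ψ manifold with ideal bond geometry does not
    reach every rise/twist combination)."""

    def resid(x):
        r, tw = _screw_parameters(_build_chain(4, x[0], x[1], x[2]))
        return [(r - rise) * 10.0, tw - twist]

    sol = least_squares(
        resid, x0=[-57.0, -47.0, 180.0], xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(f"no helix with rise {rise} Å and twist {twist}°")
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def _chain_to_structure(
    chain: dict[str, np.ndarray],
    start_resid: int = 1,
    chain_id: str = "A",
    resname: str = "ALA",
    serial0: int = 0,
) -> Structure:
    atoms = []
    serial = serial0
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    n_res = len(chain["CA"])
    for i in range(n_res):
        for name in ("N", "CA", "C", "O", "CB"):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=elements[name],
                    resname=resname,
                    resid=start_resid + i,
                    chain=chain_id,
                    altloc="",
                    coords=chain[name][i],
                )
            )
    return Structure(atoms, source="synthetic")


def ideal_helix(
    n_res: int, rise: float = 1.5, twist: float = 100.0, start_resid: int = 1
) -> Structure:
    """Poly-ALA helix with exact screw geometry (rise Å/residue, twist
    degrees/residue), oriented so the dominant principal axis of its CA
    atoms is +z (N→C) and centred at the origin."""
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    phi, psi, omega = _solve_phi_psi(rise, twist)
    chain = _build_chain(n_res, phi, psi, omega)
    ca = chain["CA"]
    centered = {k: v - ca.mean(axis=0) for k, v in chain.items()}
    ca0 = centered["CA"]
    # orient by the *screw* axis (exact: CA z-spacing equals the rise); the
    # principal CA axis converges to it in the long-helix limit
    from .superpose import kabsch_fit

    P = np.concatenate([centered[k][:-1] for k in ("N", "CA", "C")])
    Q = np.concatenate([centered[k][1:] for k in ("N", "CA", "C")])
    tf, _ = kabsch_fit(P, Q)
    Rm = tf.rotation
    w = np.array([Rm[2, 1] - Rm[1, 2], Rm[0, 2] - Rm[2, 0], Rm[1, 0] - Rm[0, 1]])
    axis = w / np.linalg.norm(w)
    if np.dot(axis, ca0[-1] - ca0[0]) < 0:
        axis = -axis
    # rotate principal axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3)
    else:
        c = np.dot(axis, z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    rotated = {k: v @ R.T for k, v in centered.items()}
    return _chain_to_structure(rotated, start_resid=start_resid)


# ---------------------------------------------------------------------------
# toy transporter

_TOY_LAYOUT = {
    # role -> (start resid, x, y): four hash helices around the origin plus
    # two mobile "bundle" helices offset to one side
    "TM3": (101, -6.0, -6.0),
    "TM4": (121, 6.0, -6.0),
    "TM8": (141, 6.0, 6.0),
    "TM9": (161, -6.0, 6.0),
    "TM1b": (201, 14.0, 0.0),
    "TM6a": (221, 0.0, 14.0),
}


def toy_transporter(
    spec: FixtureSpec,
) -> tuple[Structure, Structure, RoleMap, SegmentMap, dict]:
    """Two-state toy transporter with planted bundle-segment rotations.

    The "open" state is six parallel ideal helices: four hash helices and
    the mobile TM1b/TM6a analogues.  The "occluded" state is the open state
    with each bundle helix rotated rigidly about an axis perpendicular to
    its own axis through its centroid, by the planted angle; the hash is
    identical between states.  An optional global rigid transform is applied
    to the occluded state afterwards.

    Returns (open, occluded, roles, segments, ledger); the ledger records
    every planted transform and angle.
    """
    overlaps = set()
    for role, (start, _, _) in _TOY_LAYOUT.items():
        rng = set(range(start, start + spec.helix_len))
        if overlaps & rng:
            raise ValueError("overlapping segment definitions in layout")
        overlaps |= rng
    atoms = []
    serial = 0
    helix_atoms: dict[str, list[int]] = {}
    for role, (start, x, y) in _TOY_LAYOUT.items():
        h = ideal_helix(spec.helix_len, spec.rise, spec.twist, start_resid=start)
        offset = np.array([x, y, 0.0])
        idx0 = len(atoms)
        for a in h.atoms:
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name=a.name, element=a.element,
                    resname=a.resname, resid=a.resid, chain="A", altloc="",
                    coords=a.coords + offset,
                )
            )
        helix_atoms[role] = list(range(idx0, len(atoms)))
    open_state = Structure(atoms, source="toy_open")

    rng = spec.rng()
    occ_coords = open_state.coords.copy()
    ledger: dict = {"planted_angles": dict(spec.planted_angles),
                    "segment_transforms": {}}
    for role, angle in spec.planted_angles.items():
        if role not in helix_atoms:
            raise ValueError(f"planted angle for unknown helix {role!r}")
        idx = np.array(helix_atoms[role])
        pts = occ_coords[idx]
        centroid = pts.mean(axis=0)
        # rotation axis perpendicular to the helix's principal CA axis, so
        # the planted angle is exactly the tilt a principal-axis measure sees
        ca_pts = np.stack(
            [occ_coords[i] for i in idx if open_state.atoms[i].name == "CA"]
        )
        _, _, Vt = np.linalg.svd(ca_pts - ca_pts.mean(axis=0))
        p_axis = Vt[0]
        theta = rng.uniform(0, 2 * np.pi)
        # orthonormal basis of the plane perpendicular to p_axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, p_axis)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(p_axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(p_axis, e1)
        axis = np.cos(theta) * e1 + np.sin(theta) * e2
        R = rotation_about_axis(axis, angle)
        occ_coords[idx] = (pts - centroid) @ R.T + centroid
        ledger["segment_transforms"][role] = {
            "angle_deg": angle,
            "axis": axis.tolist(),
            "centroid": centroid.tolist(),
        }
    occluded = open_state.with_coords(occ_coords)
    occluded.source = "toy_occluded"
    if spec.global_transform is not None:
        occluded = spec.global_transform.apply_structure(occluded)
        ledger["global_transform"] = {
            "rotation": spec.global_transform.rotation.tolist(),
            "translation": spec.global_transform.translation.tolist(),
        }
    if spec.noise_sigma > 0:
        occluded = occluded.with_coords(
            occluded.coords
            + rng.normal(0.0, spec.noise_sigma, occluded.coords.shape)
        )
        ledger["noise_sigma"] = spec.noise_sigma

    L = spec.helix_len
    roles = RoleMap(
        {
            role: [[start, start + L - 1]]
            for role, (start, _, _) in _TOY_LAYOUT.items()
        },
        chain="A",
    )
    segments = SegmentMap(
        [
            Segment(
                label=role,
                target_range=(start, start + L - 1),
                donor_range=(start, start + L - 1),
            )
            for role, (start, _, _) in _TOY_LAYOUT.items()
            if role in spec.planted_angles
        ]
    )
    return open_state, occluded, roles, segments, ledger


# ---------------------------------------------------------------------------
# hydration frames


def hydration_frame(
    spec: FixtureSpec,
    compartments: CompartmentSpec,
    counts: tuple[int, int, int],
    n_outside: int = 0,
) -> tuple[Structure, dict]:
    """Frame with waters planted strictly inside each compartment band and,
    optionally, outside the box.  The ledger records the per-compartment
    truth."""
    if any(c < 0 for c in counts) or n_outside < 0:
        raise ValueError("water counts must be non-negative")
    rng = spec.rng()
    cx, cy = compartments.center_xy
    z0, z1, z2, z3 = compartments.z_bounds
    bands = {"ec": (z2, z3), "site": (z1, z2), "ic": (z0, z1)}
    eps = 1e-3
    atoms: list[AtomRecord] = []
    serial = 0

    def add_water(pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial, name="OW", element="O", resname="HOH",
                resid=serial, chain="W", altloc="", coords=pos, het=True,
            )
        )

    for comp, n in zip(("ec", "site", "ic"), counts):
        zl, zh = bands[comp]
        if zh - zl <= 2 * eps:
            raise ValueError(f"zero-volume band {comp}")
        for _ in range(n):
            add_water(
                np.array(
                    [
                        rng.uniform(cx - BOX_X / 2 + eps, cx + BOX_X / 2 - eps),
                        rng.uniform(cy - BOX_Y / 2 + eps, cy + BOX_Y / 2 - eps),
                        rng.uniform(zl + eps, zh - eps),
                    ]
                )
            )
    for _ in range(n_outside):
        # shifted well clear of the box in x
        add_water(
            np.array(
                [
                    cx + BOX_X / 2 + rng.uniform(5.0, 25.0),
                    rng.uniform(cy - 20, cy + 20),
                    rng.uniform(z0 - 10, z3 + 10),
                ]
            )
        )
    ledger = {"ec": counts[0], "site": counts[1], "ic": counts[2],
              "outside": n_outside}
    return Structure(atoms, source="hydration_fixture"), ledger


# ---------------------------------------------------------------------------
# toy trajectories


def toy_trajectory(
    spec: FixtureSpec,
    gate_distances: np.ndarray | None = None,
    chi1_schedule: np.ndarray | None = None,
    dt_ns: float = 0.02,
) -> tuple[Trajectory, dict]:
    """Trajectory realising planted per-frame gate distances and χ1 values.

    The topology holds a two-residue "gate" (single CA atoms, residues 1 and
    2, separated along x by the planted distance) and a PHE-like residue 10
    (N, CA, CB, CG) whose χ1 follows the planted schedule exactly.  Optional
    isotropic Gaussian noise (``spec.noise_sigma``) is added after planting;
    the ledger records the noise-free truth.
    """
    if gate_distances is None and chi1_schedule is None:
        raise ValueError("nothing planted")
    n_frames = None
    for sched in (gate_distances, chi1_schedule):
        if sched is not None:
            if n_frames is None:
                n_frames = len(sched)
            elif len(sched) != n_frames:
                raise ValueError("inconsistent schedule lengths")
    gate_distances = (
        np.full(n_frames, 5.0) if gate_distances is None
        else np.asarray(gate_distances, dtype=float)
    )
    chi1_schedule = (
        np.full(n_frames, -60.0) if chi1_schedule is None
        else np.asarray(chi1_schedule, dtype=float)
    )
    rng = spec.rng()
    frames = []
    for fi in range(n_frames):
        serial = 0
        atoms = []

        def add(name, element, resname, resid, pos):
            nonlocal serial
            serial += 1
            atoms.append(
                AtomRecord(serial=serial, name=name, element=element,
                           resname=resname, resid=resid, chain="A",
                           altloc="", coords=np.asarray(pos, dtype=float))
            )

        add("CA", "C", "GLY", 1, [0.0, 0.0, 0.0])
        add("CA", "C", "GLY", 2, [gate_distances[fi], 0.0, 0.0])
        # PHE-like residue at an offset; CG placed by internal coordinates
        base = np.array([0.0, 20.0, 0.0])
        n_pos = base + np.array([0.0, 0.0, 0.0])
        ca_pos = base + np.array([_B_N_CA, 0.0, 0.0])
        cb_pos = place_atom(
            base + np.array([0.0, -1.0, 1.0]), n_pos, ca_pos,
            _B_CA_CB, _A_N_CA_CB, -120.0,
        )
        cg_pos = place_atom(n_pos, ca_pos, cb_pos, 1.52, 113.8,
                            chi1_schedule[fi])
        add("N", "N", "PHE", 10, n_pos)
        add("CA", "C", "PHE", 10, ca_pos)
        add("CB", "C", "PHE", 10, cb_pos)
        add("CG", "C", "PHE", 10, cg_pos)
        st = Structure(atoms, model_id=fi + 1, source=f"toy_traj#{fi}")
        if spec.noise_sigma > 0:
            st = st.with_coords(
                st.coords + rng.normal(0.0, spec.noise_sigma, st.coords.shape)
            )
        frames.append(st)
    traj = Trajectory(frames, dt_ns * np.arange(n_frames))
    ledger = {
        "gate_distances": gate_distances.tolist(),
        "chi1": chi1_schedule.tolist(),
        "noise_sigma": spec.noise_sigma,
    }
    return traj, ledger
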