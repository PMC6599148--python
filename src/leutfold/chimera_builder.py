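"""Assembly of a two-template ("chimeric") modeling template.

The outward-occluded template is built from the outward-open transporter
itself: the extracellular bundle segments are repositioned to match the
corresponding segments of an occluded homologue (after hash-domain
alignment), while every other atom is kept bit-identical to the target
input.  Companion outputs are the PIR alignment consumed by template-based
modeling programs, transferred ions/waters, adjusted side-chain rotamers,
and distance-restraint files.

The chimera is a *template*: junction geometry at segment boundaries is
reported, not repaired — physicochemical cleanup is the modeling engine's
job downstream.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .geometry import chi_atom_names, dihedral, rotation_about_axis
from .structures_io import (
    AtomSelection,
    RoleMap,
    Structure,
    residues_within,
    select,
    write_structure,
)
from .superpose import RigidTransform, SegmentMap, hash_superpose, kabsch_fit

__all__ = [
    "ChimeraRecord",
    "Restraint",
    "RestraintList",
    "build_template",
    "emit_pir_alignment",
    "parse_pir",
    "transfer_ions",
    "set_chi",
    "emit_restraints",
    "parse_restraints",
    "junction_bond_lengths",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ChimeraRecord:
    """A chimeric template with per-atom provenance.

    ``provenance[i]`` is ``"unchanged_target"`` or ``"repositioned_target"``
    for atom *i* of ``structure``; unchanged atoms are bit-identical to the
    target input.
    """

    structure: Structure
    provenance: list[str]
    segment_map: SegmentMap
    transforms: dict[str, RigidTransform]

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.structure.atoms):
            raise ValueError("provenance must tag every atom")
        bad = set(self.provenance) - {"unchanged_target", "repositioned_target"}
        if bad:
            raise ValueError(f"unknown provenance tags {bad}")

    def write_pdb(self, path: str | Path) -> None:
        """Write the chimera as PDB with provenance in the B-factor column
        (0 = unchanged, 1 = repositioned) and a YAML sidecar of transforms."""
        tagged = Structure(
            [
                replace(a, bfactor=0.0 if p == "unchanged_target" else 1.0)
                for a, p in zip(self.structure.atoms, self.provenance)
            ],
            model_id=self.structure.model_id,
            source=self.structure.source,
        )
        write_structure(tagged, path)
        sidecar = {
            "segments": {
                label: {
                    "rotation": tf.rotation.tolist(),
                    "translation": tf.translation.tolist(),
                }
                for label, tf in self.transforms.items()
            }
        }
        Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def build_template(
    target: Structure,
    donor: Structure,
    segments: SegmentMap,
    roles: RoleMap,
    roles_donor: RoleMap | None = None,
) -> ChimeraRecord:
    """Build the chimeric template.

    1. The donor is hash-superposed onto the target.
    2. Each target segment's backbone is Kabsch-fitted onto the corresponding
       donor segment, and *all* atoms of that segment (side chains move
       rigidly with their backbone) are moved by the fitted transform.
    3. All other target atoms are left bit-identical.
    """
    roles_donor = roles_donor or roles
    tf_hash = hash_superpose(donor, target, roles_donor, roles)
    donor_aligned = tf_hash.apply_structure(donor)

    seg_of_resid: dict[tuple[str, int], int] = {}
    for si, seg in enumerate(segments):
        for r in range(seg.target_range[0], seg.target_range[1] + 1):
            seg_of_resid[(seg.target_chain, r)] = si

    transforms: dict[str, RigidTransform] = {}
    for seg in segments:
        t_ids = list(range(seg.target_range[0], seg.target_range[1] + 1))
        d_ids = list(range(seg.donor_range[0], seg.donor_range[1] + 1))
        if len(t_ids) != len(d_ids):
            raise ValueError(f"segment {seg.label}: unequal range lengths")
        from .superpose import _paired_backbone

        try:
            P, Q = _paired_backbone(
                target, donor_aligned, t_ids, d_ids,
                seg.target_chain, seg.donor_chain,
            )
        except ValueError as exc:
            raise ValueError(f"segment {seg.label}: {exc}") from exc
        tf, _ = kabsch_fit(P, Q)
        transforms[seg.label] = tf

    atoms: list = []
    provenance: list[str] = []
    for a in target.atoms:
        si = seg_of_resid.get((a.chain, a.resid))
        if si is None:
            atoms.append(a)  # bit-identical: same record object
            provenance.append("unchanged_target")
        else:
            tf = transforms[segments.segments[si].label]
            atoms.append(replace(a, coords=tf.apply(a.coords)))
            provenance.append("repositioned_target")
    chimera = Structure(atoms, model_id=target.model_id,
                        source=f"chimera({target.source})")
    return ChimeraRecord(chimera, provenance, segments, transforms)


def junction_bond_lengths(record: ChimeraRecord) -> list[dict]:
    """Peptide C–N bond lengths across segment boundaries (reported, not
    repaired)."""
    st = record.structure
    out = []
    for seg in record.segment_map:
        for resid, other in (
            (seg.target_range[0], seg.target_range[0] - 1),
            (seg.target_range[1], seg.target_range[1] + 1),
        ):
            lo, hi = sorted((resid, other))
            try:
                c = st.atom(seg.target_chain, lo, "C")
                n = st.atom(seg.target_chain, hi, "N")
            except KeyError:
                continue
            out.append(
                {
                    "segment": seg.label,
                    "bond": f"{lo}:C-{hi}:N",
                    "length_A": float(np.linalg.norm(c.coords - n.coords)),
                }
            )
    return out


# ---------------------------------------------------------------------------
# PIR alignment


def emit_pir_alignment(
    chimera: ChimeraRecord | Structure,
    full_sequence: str,
    template_id: str = "template",
    target_id: str = "target",
    chain: str = "A",
    width: int = 60,
) -> str:
    """Emit a two-entry PIR alignment: the chimeric template vs the full
    target sequence.  Positions absent from the chimera become gaps in the
    template line.  Residue *i* of the chimera maps to ``full_sequence[i-1]``
    (author numbering is 1-based into the full sequence)."""
    st = chimera.structure if isinstance(chimera, ChimeraRecord) else chimera
    n = len(full_sequence)
    template_seq = ["-"] * n
    seen: set[int] = set()
    first_res = last_res = None
    for key in st.residue_keys():
        ch, resid = key
        if ch != chain:
            continue
        res_atoms = st.residue_atoms(ch, resid)
        if all(a.het for a in res_atoms):
            continue
        letter = THREE_TO_ONE.get(res_atoms[0].resname)
        if letter is None or not (1 <= resid <= n):
            raise ValueError(
                f"residue {res_atoms[0].resname}{resid} cannot be mapped onto "
                f"the full sequence"
            )
        if resid in seen:
            raise ValueError(f"residue {resid} maps twice (non-injective)")
        if letter != full_sequence[resid - 1]:
            raise ValueError(
                f"residue {resid}: template {letter} != sequence "
                f"{full_sequence[resid - 1]}"
            )
        seen.add(resid)
        template_seq[resid - 1] = letter
        first_res = resid if first_res is None else first_res
        last_res = resid
    if not seen:
        raise ValueError("chimera contains no mappable residues")

    def block(seq: str) -> str:
        return "\n".join(textwrap.wrap(seq + "*", width))

    lines = [
        f">P1;{template_id}",
        f"structureX:{template_id}:{first_res}:{chain}:{last_res}:{chain}:::-1.00:-1.00",
        block("".join(template_seq)),
        f">P1;{target_id}",
        f"sequence:{target_id}:1::{n}::::0.00:0.00",
        block(full_sequence),
    ]
    return "\n".join(lines) + "\n"


def parse_pir(text: str) -> dict[str, str]:
    """Parse a PIR alignment back into {entry id: sequence with gaps}."""
    entries: dict[str, str] = {}
    cur: str | None = None
    buf: list[str] = []
    skip_header = False
    for line in text.splitlines():
        if line.startswith(">P1;"):
            if cur is not None:
                entries[cur] = "".join(buf).rstrip("*")
            cur = line[4:].strip()
            buf = []
            skip_header = True
        elif skip_header:
            skip_header = False  # the one description line
        elif cur is not None:
            buf.append(line.strip())
    if cur is not None:
        entries[cur] = "".join(buf).rstrip("*")
    return entries


# ---------------------------------------------------------------------------
# ion / water transfer


def transfer_ions(
    source: Structure,
    dest: Structure,
    ion_exprs: Sequence[str],
    site_cutoff: float = 4.5,
) -> Structure:
    """Copy ions (or tagged waters) from ``source`` into ``dest``.

    For each selection expression (which must resolve to a single residue in
    the source), the binding site is taken as all residues within
    ``site_cutoff`` Å; the source site backbone is Kabsch-fitted onto the
    homologous dest site backbone (same author numbering), and the ion is
    copied under that transform.
    """
    new_atoms = list(dest.atoms)
    next_serial = max((a.serial for a in dest.atoms), default=0)
    for expr in ion_exprs:
        sel = select(source, expr)
        if len(sel) == 0:
            raise ValueError(f"ion selection {expr!r} matches nothing in source")
        site_keys = residues_within(source, sel, site_cutoff)
        if not site_keys:
            raise ValueError(f"ion {expr!r}: no site residues within {site_cutoff} Å")
        P_pts, Q_pts = [], []
        missing = []
        for chain, resid in sorted(site_keys):
            src_bb = {
                a.name: a
                for a in source.residue_atoms(chain, resid)
                if a.name in ("N", "CA", "C", "O")
            }
            dst_bb = {
                a.name: a
                for a in dest.residue_atoms(chain, resid)
                if a.name in ("N", "CA", "C", "O")
            }
            if not dst_bb:
                missing.append(f"{chain}/{resid}")
                continue
            for name in ("N", "CA", "C", "O"):
                if name in src_bb and name in dst_bb:
                    P_pts.append(src_bb[name].coords)
                    Q_pts.append(dst_bb[name].coords)
        if missing and not P_pts:
            raise ValueError(f"ion {expr!r}: site residues absent in dest: {missing}")
        tf, _ = kabsch_fit(np.stack(P_pts), np.stack(Q_pts))
        for a in sel.atoms:
            next_serial += 1
            new_atoms.append(
                replace(a, serial=next_serial, coords=tf.apply(a.coords))
            )
    return Structure(new_atoms, model_id=dest.model_id,
                     source=f"{dest.source}+ions")


# ---------------------------------------------------------------------------
# rotamer setting

_GREEK_RANK = {"A": 0, "B": 1, "G": 2, "D": 3, "E": 4, "Z": 5, "H": 6}


def _position_rank(atom_name: str) -> int | None:
    """Greek-letter side-chain position encoded in an atom name (CB → 1,
    CG/CG1/OG → 2, CD1/SD → 3, ...); None for backbone/unrecognised."""
    name = atom_name.strip()
    if name in ("N", "CA", "C", "O", "OXT"):
        return None
    core = name[1:] if name[0] in "CNOSH" else name
    if not core:
        return None
    return _GREEK_RANK.get(core[0])


def set_chi(
    structure: Structure,
    chain: str,
    resid: int,
    chi_index: int,
    angle: float,
) -> Structure:
    """Return a copy with the named χ dihedral set to ``angle`` (degrees).

    Atoms distal to the rotated bond move rigidly about it; bond lengths and
    angles are untouched.  Setting is absolute: setting twice equals a single
    set to the final value.
    """
    if not -180.0 < angle <= 180.0:
        raise ValueError("angle must lie in (-180, 180]")
    res_atoms = structure.residue_atoms(chain, resid)
    if not res_atoms:
        raise ValueError(f"no residue {chain}/{resid}")
    resname = res_atoms[0].resname
    names = chi_atom_names(resname, chi_index)
    by_name = {a.name: a for a in res_atoms}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValueError(
            f"{resname}{resid}: missing χ{chi_index} defining atoms {missing}"
        )
    a, b, c, d = (by_name[n].coords for n in names)
    current = dihedral(a, b, c, d)
    delta = angle - current
    axis = c - b
    R = rotation_about_axis(axis, delta)
    # distal set: side-chain atoms strictly beyond the bond's far atom
    pivot_rank = _position_rank(names[2])
    assert pivot_rank is not None
    new_atoms = []
    for atom in structure.atoms:
        if atom.chain == chain and atom.resid == resid:
            rank = _position_rank(atom.name)
            if rank is not None and rank > pivot_rank:
                new_atoms.append(
                    replace(atom, coords=R @ (atom.coords - c) + c)
                )
                continue
        new_atoms.append(atom)
    return Structure(new_atoms, model_id=structure.model_id,
                     source=structure.source)


# ---------------------------------------------------------------------------
# restraints


@dataclass(frozen=True)
class Restraint:
    """One pairwise distance restraint.

    Atom references are ``chain/resid/name`` strings; the target distance is
    in Å and the force constant in kcal/mol/Å².
    """

    atom_a: str
    atom_b: str
    distance: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("restraint distance must be > 0")
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")


@dataclass
class RestraintList:
    entries: list[Restraint] = field(default_factory=list)

    #: conventional defaults: 10 kcal/mol/Å² for minimization restraints,
    #: 200 kcal/mol/Å² for equilibration restraints
    MINIMIZATION_K = 10.0
    EQUILIBRATION_K = 200.0

    def add(self, atom_a: str, atom_b: str, distance: float,
            force_constant: float) -> None:
        self.entries.append(Restraint(atom_a, atom_b, distance, force_constant))

    def validate(self, structure: Structure) -> None:
        """Error on any atom reference not present in ``structure``."""
        for r in self.entries:
            for ref in (r.atom_a, r.atom_b):
                chain, resid, name = ref.split("/")
                try:
                    structure.atom(chain, int(resid), name)
                except KeyError:
                    raise ValueError(f"dangling atom reference {ref!r}")


def emit_restraints(
    restraints: RestraintList,
    dialect: str = "generic_tsv",
    structure: Structure | None = None,
) -> str:
    """Serialize a restraint list.

    ``generic_tsv``: one tab-separated line per restraint.  ``plumed_style``:
    pairwise DISTANCE + RESTRAINT lines (distances in nm, κ converted to
    kJ/mol/nm²) referencing atom serial numbers, which requires the companion
    ``structure``.
    """
    if dialect == "generic_tsv":
        if structure is not None:
            restraints.validate(structure)
        lines = ["#atom_a\tatom_b\tdistance_A\tforce_kcal_mol_A2"]
        for r in restraints.entries:
            lines.append(f"{r.atom_a}\t{r.atom_b}\t{r.distance:g}\t{r.force_constant:g}")
        return "\n".join(lines) + "\n"
    if dialect == "plumed_style":
        if structure is None:
            raise ValueError("plumed_style needs the companion structure")
        restraints.validate(structure)
        lines = ["# pairwise distance restraints (nm, kJ/mol/nm^2)"]
        for i, r in enumerate(restraints.entries, start=1):
            serials = []
            for ref in (r.atom_a, r.atom_b):
                chain, resid, name = ref.split("/")
                serials.append(structure.atom(chain, int(resid), name).serial)
            kappa = r.force_constant * 4.184 * 100.0  # kcal/mol/A^2 -> kJ/mol/nm^2
            lines.append(f"d{i}: DISTANCE ATOMS={serials[0]},{serials[1]}")
            lines.append(
                f"r{i}: RESTRAINT ARG=d{i} AT={r.distance / 10.0:g} KAPPA={kappa:g}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown restraint dialect {dialect!r}")


def parse_restraints(text: str) -> RestraintList:
    """Parse the generic_tsv dialect back into a RestraintList."""
    out = RestraintList()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b, d, k = line.split("\t")
        out.add(a, b, float(d), float(k))
    return out
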