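"""Coordinate I/O, atom selection, and the residue role map.

Structures are held as flat, ordered lists of atom records with *author*
residue numbering preserved exactly as in the source file — every residue
label used elsewhere in the package (R104, E493, Y176, F335, ...) refers to
this numbering.  Reading goes through :mod:`gemmi` (PDB and mmCIF); writing
emits fixed-column PDB.

Alternate locations: on read, only the highest-occupancy altloc of each atom
is kept (ties broken alphabetically); discarded altlocs are logged.
Hydrogens are retained but excluded from distance/contact metrics by the
callers (the crystal templates this package targets lack hydrogens).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "AtomSelection",
    "RoleMap",
    "read_structure",
    "write_structure",
    "select",
    "residues_within",
    "default_hsert_rolemap",
]

#: Atom names making up the peptide backbone.
BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL", "TIP"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom, with author residue numbering preserved exactly."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    altloc: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.resid)


@dataclass
class Structure:
    """An ordered collection of atoms from one model of a coordinate file."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (N, 3) array in Å."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with every coordinate replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, model_id=self.model_id, source=self.source)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_atoms(self, chain: str, resid: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain and a.resid == resid]

    def atom(self, chain: str, resid: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.chain == chain and a.resid == resid and a.name == name:
                return a
        raise KeyError(f"no atom {name} in {chain}/{resid}")


@dataclass
class AtomSelection:
    """Ordered, duplicate-free indices into ``structure.atoms``."""

    structure: Structure
    indices: np.ndarray
    expr: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(set(idx.tolist())) != len(idx):
            raise ValueError("selection indices must be duplicate-free")
        if len(idx) and (idx.min() < 0 or idx.max() >= len(self.structure.atoms)):
            raise ValueError("selection index out of range")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.structure.atoms[i] for i in self.indices]

    @property
    def coords(self) -> np.ndarray:
        if not len(self.indices):
            return np.empty((0, 3))
        return np.stack([self.structure.atoms[i].coords for i in self.indices])


# ---------------------------------------------------------------------------
# reading / writing


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy altloc per (chain, resid, name); ties → first
    alphabetically.  Atoms without altloc pass through untouched."""
    best: dict[tuple[str, int, str], AtomRecord] = {}
    order: list[tuple[str, int, str]] = []
    dropped = 0
    for a in atoms:
        key = (a.chain, a.resid, a.name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        else:
            dropped += 1
            if (a.occupancy, _altloc_rank(a.altloc)) > (
                cur.occupancy,
                _altloc_rank(cur.altloc),
            ):
                best[key] = a
    if dropped:
        logger.info("discarded %d alternate-location atoms", dropped)
    return [replace(best[k], altloc="") for k in order]


def _altloc_rank(altloc: str) -> float:
    # later in the alphabet → lower rank, so ties keep the first alphabetically
    return -ord(altloc) if altloc else 0.0


def _from_gemmi_model(model: gemmi.Model, model_id: int, source: str) -> Structure:
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=atom.element.name,
                        resname=res.name,
                        resid=res.seqid.num,
                        chain=chain.name,
                        altloc=atom.altloc if atom.altloc != "\x00" else "",
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        bfactor=atom.b_iso,
                        het=res.het_flag == "H",
                    )
                )
    return Structure(_dedupe_altlocs(atoms), model_id=model_id, source=source)


def read_structure(
    path: str | Path, format: str | None = None
) -> Structure | list[Structure]:
    """Read a coordinate file.

    Parameters
    ----------
    path
        PDB or mmCIF file.
    format
        One of ``pdb``, ``mmcif``, ``multi_model_pdb`` or ``None`` (detect from
        the extension; multi-model PDB files return a list of structures).

    Returns
    -------
    A single :class:`Structure`, or a list of them for multi-model input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty coordinate file")
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif", "multi_model_pdb"):
        raise ValueError(f"unknown format {format!r}")
    try:
        if format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable coordinate file: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    models = [
        _from_gemmi_model(m, i + 1, f"{path.name}#{i + 1}") for i, m in enumerate(st)
    ]
    if format == "multi_model_pdb" or len(models) > 1:
        return models
    models[0].source = path.name
    return models[0]


def _format_atom_line(a: AtomRecord) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = a.name
    # standard PDB rule: atom names start in column 14 unless 4 chars or a
    # 2-letter element symbol
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.coords
    return (
        f"{record}{a.serial % 100000:5d} {name:<4s}{a.altloc or ' '}"
        f"{a.resname:>3s} {a.chain[:1]:1s}{a.resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(
    structure: Structure | Sequence[Structure], path: str | Path
) -> None:
    """Write one structure (or a list, as multi-model PDB) in fixed columns."""
    models = [structure] if isinstance(structure, Structure) else list(structure)
    lines: list[str] = []
    multi = len(models) > 1
    for i, st in enumerate(models):
        if multi:
            lines.append(f"MODEL     {i + 1:4d}")
        lines.extend(_format_atom_line(a) for a in st.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection language

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    """Tiny recursive-descent parser for the selection grammar.

    expr    := term (("or") term)*
    term    := factor (("and") factor)*
    factor  := "not" factor | "(" expr ")" | primitive
    primitive := chain <id>+ | resid <n|n-m>+ | resname <id>+ | name <id>+
               | backbone | heavy | water | all
    """

    _KEYWORDS = {"chain", "resid", "resname", "name", "backbone", "heavy",
                 "water", "all", "and", "or", "not", "(", ")"}

    def __init__(self, tokens: list[str], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.st = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in self._KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise ValueError("selection keyword needs at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        kw = self.take()
        atoms = self.st.atoms
        if kw == "chain":
            vals = set(self._values())
            return np.array([a.chain in vals for a in atoms])
        if kw == "resname":
            vals = set(self._values())
            return np.array([a.resname in vals for a in atoms])
        if kw == "name":
            vals = set(self._values())
            return np.array([a.name in vals for a in atoms])
        if kw == "resid":
            ok: set[int] = set()
            for v in self._values():
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                if not m:
                    raise ValueError(f"bad resid token {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                ok.update(range(lo, hi + 1))
            return np.array([a.resid in ok for a in atoms])
        if kw == "backbone":
            return np.array([a.name in BACKBONE_NAMES and not a.het for a in atoms])
        if kw == "heavy":
            return np.array([not a.is_hydrogen for a in atoms])
        if kw == "water":
            return np.array([a.is_water for a in atoms])
        if kw == "all":
            return np.ones(len(atoms), dtype=bool)
        raise ValueError(f"unknown selection keyword {kw!r}")


def select(structure: Structure, expr: str) -> AtomSelection:
    """Evaluate a selection expression, returning an order-preserving subset.

    The grammar supports ``chain``, ``resid`` (single values and ``n-m``
    ranges), ``resname``, ``name``, the keywords ``backbone`` (N, CA, C, O),
    ``heavy`` (element ≠ H), ``water`` and ``all``, combined with ``and``,
    ``or``, ``not`` and parentheses.  An empty result is not an error.
    """
    tokens = _TOKEN_RE.findall(expr)
    if not tokens:
        raise ValueError("empty selection expression")
    mask = _SelParser(tokens, structure).parse()
    return AtomSelection(structure, np.nonzero(mask)[0], expr=expr)


def residues_within(
    structure: Structure, ref: AtomSelection, cutoff: float
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``cutoff`` Å of any ref atom.

    The reference's own residues are excluded, as are waters and hydrogens
    on both sides.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(ref) == 0:
        raise ValueError("reference selection is empty")
    ref_keys = {a.residue_key for a in ref.atoms}
    ref_xyz = np.stack([a.coords for a in ref.atoms if not a.is_hydrogen])
    cand = [
        a
        for a in structure.atoms
        if not a.is_hydrogen and not a.is_water and a.residue_key not in ref_keys
    ]
    if not cand:
        return set()
    xyz = np.stack([a.coords for a in cand])
    tree = cKDTree(ref_xyz)
    dmin, _ = tree.query(xyz, k=1)
    return {a.residue_key for a, d in zip(cand, dmin) if d <= cutoff}


# ---------------------------------------------------------------------------
# role map


#: Role names that a complete transporter role map must define.
REQUIRED_ROLES = (
    "TM1a", "TM1b", "TM2", "TM3", "TM4", "TM5", "TM6a", "TM6b", "TM7",
    "TM8", "TM9", "TM10", "TM11", "TM12", "hash",
    "EC_gate_salt", "EC_gate_lid", "IC_gate_pairs", "amine_partners",
    "site_anchors_ec", "site_anchor_cyt", "ec_vestibule_limit",
    "ic_vestibule_limit", "EL2_range", "termini_ranges",
)


class RoleMap:
    """Named residue ranges and IDs binding the transporter's residue roles.

    Entries map a role name to a list of residue IDs and/or inclusive
    ``[start, end]`` ranges.  A single ``chain`` applies to all roles unless a
    role carries its own.  ``hash`` must equal the union of TM3, TM4, TM8 and
    TM9 — the quasi-static scaffold used as the superposition frame.
    """

    def __init__(
        self,
        roles: Mapping[str, object],
        chain: str = "A",
        require_complete: bool = False,
    ):
        self.chain = chain
        self.roles: dict[str, list] = {}
        for name, entry in roles.items():
            self.roles[name] = self._normalise(entry)
        if "hash" not in self.roles and all(
            t in self.roles for t in ("TM3", "TM4", "TM8", "TM9")
        ):
            self.roles["hash"] = sum(
                (self.roles[t] for t in ("TM3", "TM4", "TM8", "TM9")), []
            )
        if require_complete:
            missing = [r for r in REQUIRED_ROLES if r not in self.roles]
            if missing:
                raise ValueError(f"role map missing required roles: {missing}")
        self._check_hash()

    @staticmethod
    def _normalise(entry) -> list:
        if isinstance(entry, int):
            return [entry]
        out: list = []
        for item in entry:
            if isinstance(item, int):
                out.append(item)
            elif isinstance(item, (list, tuple)) and len(item) == 2:
                lo, hi = int(item[0]), int(item[1])
                if hi < lo:
                    raise ValueError(f"bad range {item}")
                out.append((lo, hi))
            else:
                raise ValueError(f"bad role entry {item!r}")
        return out

    def _check_hash(self) -> None:
        if "hash" not in self.roles:
            return
        tm_names = ("TM3", "TM4", "TM8", "TM9")
        if not all(t in self.roles for t in tm_names):
            return
        union = set()
        for t in tm_names:
            union |= set(self.resids(t))
        if set(self.resids("hash")) != union:
            raise ValueError("hash role must equal the union of TM3, TM4, TM8, TM9")

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def resids(self, role: str) -> list[int]:
        """Residue IDs of a role, in declaration order (ranges expanded)."""
        if role not in self.roles:
            raise KeyError(f"unknown role {role!r}")
        out: list[int] = []
        for item in self.roles[role]:
            if isinstance(item, tuple):
                out.extend(range(item[0], item[1] + 1))
            else:
                out.append(item)
        return out

    def pairs(self, role: str) -> list[tuple[int, int]]:
        """Interpret a role's entries as consecutive residue pairs."""
        ids = self.resids(role)
        if len(ids) % 2:
            raise ValueError(f"role {role!r} does not define pairs")
        return [(ids[i], ids[i + 1]) for i in range(0, len(ids), 2)]

    def resolve(self, structure: Structure, role: str) -> list[int]:
        """Residue IDs of a role that are present in ``structure``."""
        present = {
            a.resid for a in structure.atoms if a.chain == self.chain and not a.het
        }
        found = [r for r in self.resids(role) if r in present]
        if not found:
            raise ValueError(
                f"role {role!r} resolves to no residues in chain "
                f"{self.chain!r} of {structure.source or 'structure'}"
            )
        return found

    def select_role(
        self, structure: Structure, role: str, extra: str = ""
    ) -> AtomSelection:
        """Atom selection covering a role, optionally refined (e.g. 'backbone')."""
        ids = self.resolve(structure, role)
        expr = f"chain {self.chain} and resid {' '.join(map(str, ids))}"
        if extra:
            expr = f"{expr} and {extra}"
        return select(structure, expr)

    @classmethod
    def from_yaml(cls, path: str | Path, **kw) -> "RoleMap":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(doc["roles"], chain=doc.get("chain", "A"), **kw)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "chain": self.chain,
            "roles": {
                k: [list(i) if isinstance(i, tuple) else i for i in v]
                for k, v in self.roles.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_hsert_rolemap() -> RoleMap:
    """The shipped hSERT role map (chain A, author numbering).

    TM boundaries are approximate, derived from topology annotation of the
    transporter, and are meant to be edited per use case; the functional
    residue roles (gates, binding-site anchors) are the conserved, published
    assignments.
    """
    here = Path(__file__).parent / "data" / "hsert_roles.yaml"
    return RoleMap.from_yaml(here, require_complete=True)
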