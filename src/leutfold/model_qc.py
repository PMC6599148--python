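"""Model-quality checks and the score-filter cascade used for model selection.

External scoring programs (model builders, per-residue quality predictors,
contact validators) are out of scope — their numeric outputs are *inputs*
here, as a score table.  What this module owns is the selection logic
(top-N by builder score, within-k·sd-of-best quality score, exclusion
predicates) and the in-package geometry checks: backbone dihedral
(Ramachandran) classification, steric-clash detection, and ion-coordination
distance checks.

The Ramachandran regions are a shipped, coarse box-union table in the
standard four-class scheme (general / GLY / PRO / pre-PRO).  Percentages are
comparable to, not bit-identical with, any particular plotting program's
contour art — the filter logic is the point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import dihedral
from .structures_io import Structure

__all__ = [
    "ramachandran",
    "clash_report",
    "ion_site_check",
    "filter_models",
    "top_n",
    "within_sd_of_best",
    "exclude_if",
    "VDW_RADII",
]

# ---------------------------------------------------------------------------
# Ramachandran

# Box-union region tables: (phi_min, phi_max, psi_min, psi_max), degrees.
# psi intervals that cross the ±180° seam are split into two boxes.
_FAVORED_GENERAL = [
    (-160.0, -45.0, -70.0, -5.0),    # right-handed helix
    (-180.0, -45.0, 90.0, 180.0),    # extended / sheet
    (-180.0, -45.0, -180.0, -160.0), # sheet, wrapped
]
_ALLOWED_EXTRA_GENERAL = [
    (-180.0, -20.0, -90.0, 40.0),    # broadened helical basin
    (-180.0, -20.0, 60.0, 180.0),
    (-180.0, -20.0, -180.0, -150.0),
    (40.0, 80.0, 0.0, 80.0),         # left-handed helix
]
_FAVORED_GLY = _FAVORED_GENERAL + [
    (45.0, 160.0, 5.0, 70.0),        # mirrored helical region
    (45.0, 180.0, -180.0, -90.0),
    (45.0, 180.0, 160.0, 180.0),
]
_ALLOWED_EXTRA_GLY = _ALLOWED_EXTRA_GENERAL + [
    (20.0, 180.0, -40.0, 90.0),
    (20.0, 180.0, -180.0, -60.0),
]
_FAVORED_PRO = [
    (-100.0, -40.0, -60.0, -10.0),
    (-100.0, -40.0, 100.0, 180.0),
    (-100.0, -40.0, -180.0, -170.0),
]
_ALLOWED_EXTRA_PRO = [
    (-110.0, -30.0, -80.0, 180.0),
    (-110.0, -30.0, -180.0, -160.0),
]

_REGIONS = {
    "general": (_FAVORED_GENERAL, _ALLOWED_EXTRA_GENERAL),
    "GLY": (_FAVORED_GLY, _ALLOWED_EXTRA_GLY),
    "PRO": (_FAVORED_PRO, _ALLOWED_EXTRA_PRO),
    # pre-proline uses the general boxes in this coarse table
    "prePRO": (_FAVORED_GENERAL, _ALLOWED_EXTRA_GENERAL),
}


def _in_boxes(phi: float, psi: float, boxes) -> bool:
    return any(
        p0 <= phi <= p1 and q0 <= psi <= q1 for (p0, p1, q0, q1) in boxes
    )


def _rama_class(phi: float, psi: float, kind: str) -> str:
    favored, allowed_extra = _REGIONS[kind]
    if _in_boxes(phi, psi, favored):
        return "favored"
    if _in_boxes(phi, psi, allowed_extra):
        return "allowed"
    return "disallowed"


def ramachandran(structure: Structure, chain_break_cutoff: float = 4.5
                 ) -> pd.DataFrame:
    """Backbone φ/ψ angles and region classes for every evaluable residue.

    Termini (undefined φ or ψ) are skipped; CA–CA gaps above
    ``chain_break_cutoff`` Å split the dihedral chain rather than erroring.
    Returns a DataFrame with columns chain, resid, resname, phi, psi, class;
    summary percentages are available via ``.attrs['summary']``.
    """
    residues = []
    for chain, resid in structure.residue_keys():
        atoms = {a.name: a for a in structure.residue_atoms(chain, resid)}
        if all(n in atoms for n in ("N", "CA", "C")):
            residues.append((chain, resid, atoms))
    rows = []
    for i in range(1, len(residues) - 1):
        (c_prev, r_prev, prev), (c, r, cur), (c_next, r_next, nxt) = residues[
            i - 1 : i + 2
        ]
        if c_prev != c or c_next != c:
            continue
        # chain-break detection
        if (
            np.linalg.norm(prev["CA"].coords - cur["CA"].coords)
            > chain_break_cutoff
            or np.linalg.norm(cur["CA"].coords - nxt["CA"].coords)
            > chain_break_cutoff
        ):
            continue
        phi = dihedral(prev["C"].coords, cur["N"].coords, cur["CA"].coords,
                       cur["C"].coords)
        psi = dihedral(cur["N"].coords, cur["CA"].coords, cur["C"].coords,
                       nxt["N"].coords)
        resname = next(iter(cur.values())).resname
        if resname == "GLY":
            kind = "GLY"
        elif resname == "PRO":
            kind = "PRO"
        elif next(iter(nxt.values())).resname == "PRO":
            kind = "prePRO"
        else:
            kind = "general"
        rows.append(
            {
                "chain": c,
                "resid": r,
                "resname": resname,
                "phi": phi,
                "psi": psi,
                "class": _rama_class(phi, psi, kind),
            }
        )
    df = pd.DataFrame(rows, columns=["chain", "resid", "resname", "phi", "psi",
                                     "class"])
    n = len(df)
    counts = df["class"].value_counts() if n else pd.Series(dtype=int)
    df.attrs["summary"] = {
        cls: 100.0 * counts.get(cls, 0) / n if n else 0.0
        for cls in ("favored", "allowed", "disallowed")
    }
    return df


# ---------------------------------------------------------------------------
# clashes

#: van der Waals radii (Å) for common elements; unknown elements fall back
#: to 1.7 Å with a warning.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "SE": 1.90,
}

_BOND_CUTOFF = {"S": 2.1, "P": 2.1}  # per-element covalent-bond cutoffs (Å)


def _bond_cutoff(el1: str, el2: str) -> float:
    return max(_BOND_CUTOFF.get(el1.upper(), 1.9), _BOND_CUTOFF.get(el2.upper(), 1.9))


def clash_report(structure: Structure, overlap_cutoff: float = 0.4
                 ) -> list[dict]:
    """Non-bonded heavy-atom pairs overlapping by ≥ ``overlap_cutoff`` Å.

    Overlap = r_i + r_j − d.  Bonds are inferred by interatomic distance, and
    pairs within three bonds (1-2, 1-3 and 1-4 neighbours) are excluded —
    with full vdW radii, 1-4 pairs across an ideal peptide bond would
    otherwise always register.  Unknown elements warn and fall back to a
    1.7 Å radius.
    """
    import warnings

    heavy = [a for a in structure.atoms if not a.is_hydrogen]
    if len(heavy) < 2:
        return []
    xyz = np.stack([a.coords for a in heavy])
    radii = []
    for a in heavy:
        el = a.element.upper()
        if el not in VDW_RADII:
            warnings.warn(f"unknown element {a.element!r}; vdW radius 1.7 Å")
        radii.append(VDW_RADII.get(el, 1.70))
    radii = np.array(radii)
    tree = cKDTree(xyz)

    # bond graph by distance, then 1-2/1-3 exclusion via neighbour expansion
    bonded: dict[int, set[int]] = {i: set() for i in range(len(heavy))}
    for i, j in tree.query_pairs(2.1):
        d = np.linalg.norm(xyz[i] - xyz[j])
        if d <= _bond_cutoff(heavy[i].element, heavy[j].element):
            bonded[i].add(j)
            bonded[j].add(i)

    def excluded(i: int, j: int) -> bool:
        if j in bonded[i]:
            return True
        second = set().union(*(bonded[k] for k in bonded[i])) if bonded[i] else set()
        if j in second:
            return True
        return any(j in bonded[k] for k in second)

    out = []
    max_reach = 2 * radii.max()
    for i, j in sorted(tree.query_pairs(max_reach)):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        overlap = radii[i] + radii[j] - d
        if overlap >= overlap_cutoff and not excluded(i, j):
            a, b = heavy[i], heavy[j]
            out.append(
                {
                    "atom_a": f"{a.chain}/{a.resid}/{a.name}",
                    "atom_b": f"{b.chain}/{b.resid}/{b.name}",
                    "distance_A": d,
                    "overlap_A": float(overlap),
                }
            )
    out.sort(key=lambda r: -r["overlap_A"])
    return out


# ---------------------------------------------------------------------------
# ion coordination


def ion_site_check(
    structure: Structure,
    site_spec: Sequence[tuple[str, str, float, float]],
) -> pd.DataFrame:
    """Check ion-coordination distances against X-ray reference values.

    ``site_spec`` rows are (ion atom ref, coordinating atom ref, reference
    distance Å, tolerance Å) with ``chain/resid/name`` atom references.
    Returns a table with measured distance, deviation, and a pass flag;
    a missing ion fails that row with a reason.  An empty spec is a vacuous
    pass.
    """
    rows = []
    for ion_ref, coord_ref, ref_d, tol in site_spec:
        row = {"ion": ion_ref, "partner": coord_ref, "reference_A": ref_d,
               "tolerance_A": tol}
        try:
            ion = structure.atom(*_split_ref(ion_ref))
            partner = structure.atom(*_split_ref(coord_ref))
        except KeyError as exc:
            row.update({"measured_A": np.nan, "deviation_A": np.nan,
                        "passed": False, "reason": str(exc)})
            rows.append(row)
            continue
        d = float(np.linalg.norm(ion.coords - partner.coords))
        dev = d - ref_d
        row.update({"measured_A": d, "deviation_A": dev,
                    "passed": bool(abs(dev) <= tol), "reason": ""})
        rows.append(row)
    df = pd.DataFrame(rows, columns=["ion", "partner", "reference_A",
                                     "tolerance_A", "measured_A",
                                     "deviation_A", "passed", "reason"])
    df.attrs["all_passed"] = bool(df["passed"].all()) if len(df) else True
    return df


def _split_ref(ref: str) -> tuple[str, int, str]:
    chain, resid, name = ref.split("/")
    return chain, int(resid), name


# ---------------------------------------------------------------------------
# filter cascade


@dataclass(frozen=True)
class top_n:
    """Keep the n best models by a score column (higher better unless
    ``ascending``)."""

    score: str
    n: int
    ascending: bool = False


@dataclass(frozen=True)
class within_sd_of_best:
    """Keep models whose score is within k sample standard deviations of the
    best score in the set entering this rule."""

    score: str
    k: float = 1.0


@dataclass(frozen=True)
class exclude_if:
    """Drop models for which ``predicate(row)`` is true."""

    predicate: Callable[[pd.Series], bool]
    label: str = "exclude_if"


def filter_models(
    scores: pd.DataFrame,
    rules: Sequence[top_n | within_sd_of_best | exclude_if],
) -> tuple[list, list[dict]]:
    """Apply an ordered rule cascade to a score table.

    ``scores`` must have one row per model (index = model ID) with finite
    score columns.  Returns the selected model IDs (input order preserved)
    and an audit trail recording the set size after each rule.
    """
    if scores.index.has_duplicates:
        raise ValueError("score table has duplicate model IDs")
    current = scores.copy()
    audit = [{"rule": "input", "n_models": len(current)}]
    for rule in rules:
        if isinstance(rule, (top_n, within_sd_of_best)) and rule.score not in current:
            raise ValueError(f"rule references absent score {rule.score!r}")
        if isinstance(rule, top_n):
            order = current[rule.score].sort_values(
                ascending=rule.ascending, kind="stable"
            )
            keep = set(order.index[: rule.n])
            current = current.loc[[i for i in current.index if i in keep]]
            desc = f"top_n({rule.score}, {rule.n})"
        elif isinstance(rule, within_sd_of_best):
            vals = current[rule.score]
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            threshold = float(vals.max()) - rule.k * sd
            current = current[vals >= threshold]
            desc = (f"within_sd_of_best({rule.score}, k={rule.k}, "
                    f"threshold={threshold:.6g})")
        else:
            mask = current.apply(lambda row: not rule.predicate(row), axis=1)
            current = current[mask]
            desc = rule.label
        audit.append({"rule": desc, "n_models": len(current)})
    return list(current.index), audit
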