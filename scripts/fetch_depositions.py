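#!/usr/bin/env python
"""Fetch the deposited coordinate sets and down-sample them into small
plain-text fixtures used by the printed-value validation tests.

Requires network access.  Produces, under ``src/leutfold/data/fixtures/``:

- ``5I71_F335.pdb``, ``6DZV_F335.pdb``, ``3F48_F253.pdb`` — single aromatic
  lid residues for χ1 rotamer checks (downsampled from the depositions).
- ``5I6X_site.pdb`` — paroxetine plus every residue within 6 Å of it
  (a superset of the 4.5 Å binding-site shell), downsampled from 5I6X.
- ``6DZY_helices.pdb``, ``6DZV_helices.pdb`` — backbone atoms of the hash
  domain plus TM1b/TM6a for hash-superposed helix-tilt comparisons.
- ``occluded_final_rep*.pdb`` — gate/tilt-relevant residues extracted from
  the deposited MD end states (outward-occluded runs), if retrievable.

Each output is a fixed-column PDB under 64 KB; the tests that consume these
fixtures fail with a pointer to this script when they are absent.
"""

from __future__ import annotations

import io
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from leutfold.structures_io import (  # noqa: E402
    Structure,
    read_structure,
    residues_within,
    select,
    write_structure,
)

FIXTURE_DIR = Path(__file__).resolve().parents[1] / "src/leutfold/data/fixtures"
RCSB = "https://files.rcsb.org/download/{}.pdb"
ZENODO_RECORD = "https://zenodo.org/api/records/3241982"

# helix ranges used for the tilt fixtures (hash + mobile bundle helices)
HELIX_RANGES = [(101, 119), (158, 193), (239, 260), (322, 337),
                (425, 455), (461, 484)]


def fetch(url: str) -> bytes:
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=120) as fh:
        return fh.read()


def fetch_pdb(code: str, cache: Path) -> Structure:
    path = cache / f"{code}.pdb"
    if not path.exists():
        path.write_bytes(fetch(RCSB.format(code)))
    st = read_structure(path)
    return st[0] if isinstance(st, list) else st


def subset(st: Structure, expr: str, source: str) -> Structure:
    sel = select(st, expr)
    return Structure(list(sel.atoms), source=source)


def main() -> None:
    cache = Path(__file__).resolve().parents[1] / "scratch"
    cache.mkdir(exist_ok=True)
    FIXTURE_DIR.mkdir(parents=True, exist_ok=True)

    # chi1 rotamer residues
    for code, resid in (("5I71", 335), ("6DZV", 335), ("3F48", 253)):
        st = fetch_pdb(code, cache)
        out = subset(st, f"chain A and resid {resid}",
                     f"{code} chain A residue {resid} (downsampled)")
        write_structure(out, FIXTURE_DIR / f"{code}_F{resid}.pdb")

    # paroxetine binding-site shell from 5I6X (ligand resname 8PR)
    st = fetch_pdb("5I6X", cache)
    parox = select(st, "chain A and resname 8PR")
    if len(parox) == 0:
        raise SystemExit("no paroxetine (8PR) atoms found in 5I6X chain A")
    keys = residues_within(st, parox, 6.0)
    resids = sorted({r for c, r in keys if c == "A"})
    expr = f"chain A and (resname 8PR or resid {' '.join(map(str, resids))})"
    write_structure(subset(st, expr, "5I6X site shell (downsampled)"),
                    FIXTURE_DIR / "5I6X_site.pdb")

    # helix-tilt fixtures: hash + TM1b + TM6a backbone of the cryo-EM pair
    ranges = " ".join(f"{a}-{b}" for a, b in HELIX_RANGES)
    for code in ("6DZY", "6DZV"):
        st = fetch_pdb(code, cache)
        out = subset(st, f"chain A and resid {ranges} and backbone",
                     f"{code} helix backbone (downsampled)")
        write_structure(out, FIXTURE_DIR / f"{code}_helices.pdb")

    # MD end states of the outward-occluded runs (Zenodo deposition)
    try:
        import json

        record = json.loads(fetch(ZENODO_RECORD))
        files = {f["key"]: f["links"]["self"] for f in record["files"]}
        print("zenodo files:", sorted(files))
        # heuristics: final-frame structure files of the occluded runs
        candidates = [k for k in files
                      if "occl" in k.lower() and
                      (k.endswith(".gro") or k.endswith(".pdb"))]
        for i, key in enumerate(sorted(candidates), start=1):
            raw = cache / key.replace("/", "_")
            if not raw.exists():
                raw.write_bytes(fetch(files[key]))
            extract_end_state(raw, FIXTURE_DIR / f"occluded_final_rep{i}.pdb")
    except Exception as exc:  # zenodo layout may change; report and move on
        print(f"zenodo retrieval failed: {exc}", file=sys.stderr)

    for p in sorted(FIXTURE_DIR.glob("*.pdb")):
        size = p.stat().st_size
        print(f"{p.name}: {size} bytes")
        if size > 64_000:
            print(f"  WARNING: {p.name} exceeds the 64 KB fixture budget")


def extract_end_state(raw: Path, out: Path) -> None:
    """Extract gate/tilt residues from a simulation end state.

    The deposited states renumber the protein from 1 (the constructs start
    at author residue 74), so author numbering is restored by offset before
    extraction of W82, Y350, the TM1b range and the hash backbone.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(raw))
    protein = u.select_atoms("protein")
    offset = 74 - int(protein.residues.resids.min())
    keep = []
    gate = {82, 350}
    for res in protein.residues:
        auth = res.resid + offset
        if auth in gate:
            keep.append((res, auth, None))
        elif any(a <= auth <= b for a, b in HELIX_RANGES):
            keep.append((res, auth, ("N", "CA", "C", "O")))
    from leutfold.structures_io import AtomRecord

    atoms = []
    serial = 0
    for res, auth, names in keep:
        for atom in res.atoms:
            if atom.element == "H" or atom.name.startswith("H"):
                continue
            if names is not None and atom.name not in names:
                continue
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=atom.name,
                element=atom.element if atom.element else atom.name[0],
                resname=res.resname[:3], resid=auth, chain="A", altloc="",
                coords=atom.position.astype(float),
            ))
    write_structure(Structure(atoms, source=f"{raw.name} (downsampled)"), out)


if __name__ == "__main__":
    main()
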