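# leutfold

Analysis toolkit for conformational states of LeuT-fold transporters,
built around the workflow of modeling the human serotonin transporter
(hSERT) in an outward-occluded state from two templates.

Secondary active transporters of the SLC6/NSS family move their substrate by
alternating access: a mobile four-helix *bundle* (TM1, TM2, TM6, TM7) rocks
against a quasi-static *hash* scaffold (TM3, TM4, TM8, TM9), opening and
closing gated pathways on either side of the membrane.  Characterising an
intermediate such as the outward-occluded state requires a set of well-defined
geometric computations around the heavy external engines (comparative
modeling, induced-fit docking, molecular dynamics): building the hybrid
template itself, filtering candidate models, clustering docked ligand poses,
and measuring gates, rotamers, helix tilts and hydration in the resulting
coordinates.  `leutfold` implements exactly that computational skeleton; it
does not model, dock, or simulate.

## What it computes

- **`structures_io`** — PDB/mmCIF reading (via gemmi), fixed-column PDB
  writing, a small selection grammar, proximity queries, and a *role map*
  binding residue labels (TM helices, the R104–E493 salt bridge and
  Y176–F335 lid of the extracellular gate, the intracellular gate network
  R79–D452 / W82–Y350 / Y350–E444 / E444–R462, binding-site anchors) to
  author residue numbers.
- **`superpose`** — Kabsch least-squares superposition (SVD with the proper-
  rotation correction), no-fit RMSD, hash-domain alignment, and the
  segment-fit table that ranks candidate segment decompositions by "largest
  combination of fragments, smallest combined RMSD".
- **`chimera_builder`** — assembly of the chimeric template: bundle segments
  of the outward-open structure are rigidly repositioned onto the
  corresponding segments of an occluded homologue (hash-superposed first),
  everything else stays bit-identical.  Also: PIR alignment emission, ion and
  water transfer by binding-site superposition, absolute χ-dihedral setting,
  and distance-restraint files (10 kcal/mol/Å² minimisation /
  200 kcal/mol/Å² equilibration defaults).
- **`model_qc`** — Ramachandran classification (coarse shipped region
  table), distance-inferred clash detection, ion-coordination checks, and
  the ordered score-filter cascade (`top_n`, `within_sd_of_best`,
  `exclude_if`) with an audit trail.
- **`pose_cluster`** — pairwise no-fit RMSD over ligand heavy atoms plus
  binding-site backbone, average-linkage (UPGMA) clustering, cluster-count
  selection at the minimum of the Kelley penalty
  `K(k) = normalised mean intra-cluster spread + k`, and distance-criterion
  interaction fingerprints (D98 salt bridge, A173/C6 proximity, T439
  5-hydroxyl H-bond, F341/indole-N proximity for serotonin).
- **`state_diagnostics`** — minimum heavy-atom gate distances, per-frame
  distance series with replica mean ± s.e.m., side-chain χ1 (both principal
  and negative branches), hash-superposed helix tilt (principal CA axis,
  folded to [0°, 90°]), fitted/ligand-mode RMSD series, normalised
  histograms.
- **`hydration`** — the residue-anchored 20 × 15 × 25 Å interior box split
  9 / 7 / 9 Å along z into extracellular vestibule / orthosteric site /
  intracellular vestibule, per-frame water counts, and frame-averaged
  occupancy grids (OpenDX output).
- **`synthetic_fixtures`** — seeded generators (ideal screw helices,
  two-state toy transporters with planted segment rotations, hydration
  frames with planted counts, trajectories with planted distance/χ1
  schedules), each returning a ground-truth ledger.
- **`leutfold` CLI** — `build-template`, `qc`, `cluster-poses`, `diagnose`,
  `hydrate`, `make-fixtures`.

## Worked example

```python
import numpy as np
from leutfold import build_template, hash_superpose, helix_tilt
from leutfold.synthetic_fixtures import FixtureSpec, toy_transporter

open_st, occluded, roles, segments, ledger = toy_transporter(FixtureSpec(seed=7))
print(ledger["planted_angles"])
for helix in ("TM1b", "TM6a"):
    print(helix, round(helix_tilt(occluded, open_st, helix, roles), 3))
rec = build_template(open_st, occluded, segments, roles)
print("hash unchanged:", hash_superpose(rec.structure, open_st, roles).is_identity())
```

prints

```
{'TM1b': 17.0, 'TM6a': 8.0}
TM1b 17.0
TM6a 8.0
hash unchanged: True
```

The generator rotated the two mobile bundle helices of the toy transporter
by 17° and 8°; `helix_tilt` recovers both angles exactly after hash-domain
superposition, and the chimeric template built from the pair leaves the hash
scaffold untouched — the same measurements used to compare an occluded model
against an outward-open reference structure.

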