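# Methods

## Scope and model of the problem

`leutfold` treats a LeuT-fold transporter as two rigid-body ensembles: a
quasi-static hash scaffold (TM3, TM4, TM8, TM9) that defines the reference
frame, and a mobile bundle whose extracellular halves (TM1b, TM6a, and the
outer parts of TM2/TM7 with their loops) reposition between the outward-open
and outward-occluded states.  Everything the package computes — template
assembly, tilts, gates, hydration compartments — is defined relative to this
decomposition, which the user supplies as a *role map* of residue ranges in
author numbering.  External engines (comparative modeling, docking, MD) are
out of scope by design: the package prepares their inputs (templates, PIR
alignments, restraints) and analyses their outputs (score tables, poses,
trajectories).

## Coordinate handling

Structures are flat ordered atom lists; author residue numbering is never
altered, so residue labels like R104 or F335 mean the same thing in every
module.  On read (gemmi; PDB and mmCIF), only the highest-occupancy altloc
per atom is kept, ties resolved alphabetically.  Hydrogens are retained but
excluded from all distance and contact metrics: the crystallographic
templates these analyses compare against carry no hydrogens, so including
them in one side of a comparison would bias it.  Distances are Å internally;
series can be emitted in nm through an explicit unit field, never silently.

Operations that need side-chain atoms (χ1, interaction fingerprints) report
a residue as *unevaluable* when atoms are missing rather than guessing
coordinates.

## Superposition and the chimeric template

The rigid-fit primitive is the Kabsch algorithm: SVD of the covariance
matrix of centred point sets with the determinant correction that excludes
reflections.  Collinear point sets are rejected (the rotation about the line
is undefined).  Hash alignment runs this fit on the backbone atoms (N, CA,
C, O) of the hash roles; residue pairing between different numbering schemes
(e.g. a transporter vs its bacterial homologue) is positional within each
role range — the i-th residue to the i-th residue.  Alignment-based pairing
is deliberately not implemented: segment maps are explicit user inputs, and
an automatic pairing would hide the decision that matters most.

The chimeric template is built in three steps: (1) hash-superpose the donor
onto the target; (2) Kabsch-fit each target segment's backbone onto its
donor segment and move *all* atoms of the segment (side chains ride rigidly
with their backbone); (3) leave every other target atom bit-identical.
Junction geometry at segment boundaries is reported (C–N bond lengths), not
repaired — the template is input to a modeling engine whose job is
physicochemical cleanup.  Candidate segment decompositions are ranked by
descending total residues, then ascending combined (atom-count-weighted
RMS) segment RMSD: the "largest combination of fragments with the smallest
RMSD" rule.

χ-dihedral setting is absolute: atoms distal to the rotated bond (identified
by the Greek-letter position encoded in standard atom names) rotate rigidly
about it until the measured dihedral equals the target.  Setting twice
equals one set to the final value, and all intra-group distances are
preserved to machine precision.

## Model QC and the filter cascade

The score-filter cascade applies ordered rules to a model-score table:
`top_n` (e.g. best 100 by builder score), `within_sd_of_best` (keep scores
within k sample standard deviations of the best), and `exclude_if`
predicates (e.g. any disallowed backbone dihedral).  The standard deviation
in `within_sd_of_best` is computed over the set *entering* that rule; this
is what reproduces a 0.822–0.827 selection window from a 100-model table
with best score 0.827 and sd 0.005.  A consequence worth stating: this rule
is not idempotent — reapplying it to its own output tightens the threshold,
because the entering set changed.  `top_n` and `exclude_if` are idempotent.

Ramachandran classification uses a shipped, coarse box-union region table in
the four-class scheme (general / GLY / PRO / pre-PRO).  Percentages from
this table are comparable between models but not bit-identical to any
specific plotting program's contour art; the filter logic, not the region
art, is the computation that matters here.  Termini are skipped and CA–CA
gaps above 4.5 Å split the chain rather than erroring.

Clash detection infers bonds from interatomic distance (1.9 Å cutoff, 2.1 Å
for S/P) and excludes pairs within three bonds (1-2, 1-3, 1-4).  The 1-4
exclusion is deliberate: with full van der Waals radii, the O(i)–CA(i+1)
and C(i)–C(i+1) pairs across every ideal peptide bond would register as
≥ 0.4 Å overlaps, which is geometry, not error; non-bonded treatments
conventionally special-case 1-4 pairs.

## Pose clustering

Poses are compared by no-fit RMSD over the ligand's heavy atoms concatenated
with the binding-site backbone atoms — no superposition, because poses from
the same receptor share a frame and relative displacement is the signal.
Agglomeration is average-linkage (UPGMA), delegated to
`scipy.cluster.hierarchy`; merge decisions are deterministic, though the
order among exactly tied merges follows scipy's convention rather than a
lowest-index rule (the resulting partitions are identical).

The cluster count is selected at the minimum of the Kelley–Gardner–
Sutcliffe penalty.  For each level k ∈ [2, N−1], the average spread is the
mean over clusters of size ≥ 2 of their mean pairwise intra-cluster
distance (singletons contribute nothing); spreads are min–max normalised
across levels onto [1, N−2]; the penalty is the normalised spread plus k,
and ties resolve to the smaller k.  One property of this normalisation is
worth knowing when building test cases: if every level's spread derives
only from noise within already-pure clusters, min–max scaling amplifies
those noise-scale differences and the minimum can land at a k larger than
the number of visually obvious groups.  Fixtures with coincident points
inside groups (zero spread at every level) exercise the intended behaviour
— the penalty then reduces to 1 + k below the group count and jumps when
clusters are forced to merge across groups.

Interaction fingerprints are distance criteria with defaults of 4.0 Å for
ionic contacts (charged-group heavy atoms), 3.5 Å for donor–acceptor heavy
atoms, and 4.5 Å for proximity bits; distances are always reported next to
the bits so thresholds can be revisited without recomputation.

## State diagnostics

Gate metrics are minimum heavy-atom distances between residue pairs; series
over trajectories support strides and replica aggregation as mean ±
standard error at matched times.  χ1 follows the standard heavy-atom
convention (N–CA–CB–γ) with the praxeolitic dihedral formula, reported in
(−180°, 180°]; a negative-branch option (positive angles shifted by −360°)
supports comparisons of rotamer populations whose circular mean sits near
the branch cut, e.g. values reported around −187°.  Both branches are
computed; the package does not assert which convention an external report
used.

The helix axis is the dominant principal axis of the helix's CA
coordinates, oriented N→C — a convention, chosen because it is stable for
kinked helices and independent of terminal-residue choice.  Tilt is the
angle between frame and reference axes after hash superposition, folded
into [0°, 90°] so axis-sign ambiguities cannot flip a small tilt into a
large one.  For a finite helix the principal axis and the ideal screw axis
differ by a small, length-dependent angle; tilts are therefore meaningful
as *differences* between states measured with the same convention.

RMSD series Kabsch-fit each frame's selection onto the reference by
default; ligand mode fits on the protein backbone and reports the ligand
RMSD unfitted-in-site, which measures motion of the ligand relative to its
pocket rather than of the complex in space.  Exclusion roles (termini, the
long extracellular loop between TM3 and TM4) remove residues whose disorder
would dominate the average.

## Hydration compartments

The interior box is 20 × 15 × 25 Å, partitioned along z (membrane normal)
into a 9 Å extracellular vestibule, 7 Å orthosteric site, and 9 Å
intracellular vestibule.  The site band is centred midway between the mean
CA z of the extracellular lid anchors (Y176, F335) and the CA z of the
cytoplasmic anchor (F341), padded to exactly 7 Å; x,y are centred on the
same anchors.  Membrane alignment is the caller's responsibility, as the
box orientation is taken from the coordinate frame.  If the anchor span
itself exceeds 7 Å, strict mode raises (the structure is likely not
membrane-aligned) and non-strict mode warns.

Waters are located by their O atom — one point per molecule keeps counts
stable under hydrogen naming differences.  Compartment intervals are closed
at the top, (z_low, z_high], so a water exactly on a shared boundary counts
toward the lower-z compartment; any convention works, but only a stated one
is testable.  Occupancy grids fit every frame to frame 0 on all protein
backbone atoms, bin water oxygens within 20 Å of any ligand atom at 2 Å
resolution, and report per-voxel occupied-frame fractions.

## Synthetic data: what it emulates, and what it does not

The generators produce the geometric regimes the analyses must resolve, with
exact ground truth:

- `ideal_helix` builds a poly-ALA backbone with exact screw symmetry.  The
  requested rise (default 1.5 Å/residue) and twist (100°/residue) are hit
  exactly by solving for (φ, ψ, ω) numerically — ω relaxes slightly from
  planarity (≈ 177.8° at the defaults) because the φ/ψ manifold alone does
  not reach every screw geometry with ideal bond lengths and angles.  The
  helix is oriented by its screw axis, so the CA z-span is exactly
  (n−1) × rise; the principal CA axis coincides with the screw axis only in
  the long-helix limit.
- `toy_transporter` arranges four hash helices and two bundle helices in
  parallel, then rotates each bundle helix by a planted angle about a random
  axis perpendicular to that helix's principal axis — making the planted
  angle exactly the tilt a principal-axis measure sees.  The hash is
  bit-identical between states; an optional global rigid transform tests
  frame recovery.
- `hydration_frame` plants waters strictly inside each compartment band and
  outside the box; `toy_trajectory` realises planted gate-distance and χ1
  schedules exactly before optional isotropic Gaussian noise.

Fixtures are deterministic per seed and each returns a ledger of every
planted quantity.  They are deliberately non-physical: no side-chain
chemistry beyond what χ1 needs, no membrane, no solvent structure, no
correlated dynamics.  Passing tests therefore demonstrate that the
*measurements* are exact and self-consistent, not that the science of any
particular system is reproduced; validation against deposited experimental
coordinates is a separate layer that requires fetching those depositions
once (`scripts/fetch_depositions.py`), after which the same tests pin the
printed rotamer, tilt, and binding-site values.

## Numerical choices

- Kabsch: proper rotations enforced (det +1); < 3 points or collinear input
  rejected; orthonormality asserted at 1e-8.
- Dihedrals: praxeolitic formula; output branch (−180°, 180°]; degenerate
  central bonds rejected.
- Tie rules: boundary waters to the lower-z compartment; Kelley penalty
  ties to the smaller k; altloc occupancy ties to the alphabetically first;
  segment-fit table sorted stably so equal candidates keep input order.
- Problem sizes in the validation suite (toy helices of 15 residues,
  ≤ 8-pose clustering sets, 100-frame hydration sweeps, 20-instance Kabsch
  oracle comparisons) were chosen as the smallest sets that still exercise
  every code path with non-trivial geometry.

## Known limitations

- Residue pairing across species is positional within role ranges; an
  explicit alignment must be expressed as segment ranges.
- The Ramachandran region table is coarse; absolute favored percentages on
  real structures will differ from contour-based tools by a few percent.
- The shipped hSERT role-map helix boundaries are approximate,
  topology-annotation-derived, and meant to be edited; analyses that depend
  on exact helix ends (tilts of short helices) should use curated ranges.
- `mmCIF` is read but not written; trajectories are consumed as multi-model
  PDB (XTC/DCD readers are not bundled).
- Interaction fingerprints are heavy-atom distance criteria only — no
  angular hydrogen-bond terms, by design, since the upstream comparisons are
  to structures without hydrogens.
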