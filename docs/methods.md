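# Methods

`tetherdock` re-implements, at desk scale, the integrative pipeline used to
build and validate a C2-symmetric A2B2 complex between the DID–DD fragment
of the formin DIAPH1 (a homodimer, the "receptor") and the cytosolic
fragment of mitofusin-2 (MFN2, the "ligand"): cross-linking-MS-derived
distance restraints, interface-derived ambiguous restraints, symmetric
rigid-body docking with restraint-violation analysis, the construct
property calculators used for protein chemistry bookkeeping, and the
saturation-binding model behind the reported dissociation constants.

## Geometry substrate

Structures are flat atom tables read from and written to PDB v3.3 via
gemmi. Residue numbering is preserved verbatim; callers map to UniProt
numbering with explicit offsets. Distances use every atom present (input
models are typically hydrogen-free) and all boundary comparisons are
inclusive. Alternate locations keep the highest-occupancy copy. Kabsch
superposition uses an SVD with sign correction so the returned rotation is
always proper (determinant +1), including when the unconstrained optimum is
a reflection. Writing more than 99,999 atoms is refused rather than
wrapping serial numbers.

## Distance restraints

A bifunctional cross-linker bridges two reactive side chains; its spacer
arm length is an upper bound on the distance between the reactive atoms.
The built-in reagent table covers the amine–amine linkers DSG (7.7 Å), BS3
(11.4 Å), BS(PEG)5 (21.7 Å), BS(PEG)9 (35.8 Å) and the amine–sulfhydryl
linkers KMUS (16.3 Å), SMCC (8.3 Å), SMPB (11.6 Å). Bridge masses are
computed from elemental compositions (the parent di-acid or maleimido acid
minus the water lost on conjugation) with pyteomics mass tables; the DSG
bridge, for example, is C5H4O2 = 96.02113 Da monoisotopic.

**Unambiguous interaction restraints (UIRs).** Each identified cross-link
becomes a distance restraint between reactive atoms (Lys NZ, Cys SG, the
backbone N for a protein N-terminus), lower bound 0, upper bound equal to
the spacer length exactly. When a side-chain atom is absent (coarse or
backbone-only models) the evaluation falls back to the Cα and widens the
bound by a configurable 1 Å per fallen-back side; for Cα-bead synthetic
models, where planted distances *are* bead distances, the pipeline passes
`fallback_slack=0`.

**Symmetric copies.** In an A2B2 assembly a link between proteins REC and
LIG cannot be attributed to a specific chain pair. When both proteins have
the same copy number, the generator emits one restraint per *register*
pairing (copy i of REC with copy i of LIG) and ties them into one
`symmetry_group`. Under exact C2 symmetry the two register copies measure
the identical distance, and the off-register pairings describe the same
physical restraint with the copy labels swapped — the docking search
reaches them by rotating the ligand placement. Admitting off-register
pairings as independent alternatives inside the group minimum would allow
"bridging" solutions in which one ligand copy satisfies different links
against different receptor chains simultaneously; we exclude them by
construction. Grouped evaluation is satisfied-through-any-copy; the default
violation report still lists every copy separately.

**Ambiguous interaction restraints (AIRs).** An interface residue list
(here standing in for an NMR-mapped surface) becomes one AIR per anchor
residue against the union of the partner's active atoms, evaluated with
the standard r⁻⁶-pooled effective distance, `(Σ d_ij⁻⁶)^(−1/6)`, which is
always at most the minimum pair distance. The default upper bound is
2.0 Å, the convention of ambiguity-driven docking.

**Violation analysis.** For each restraint, violation =
max(0, d − upper, lower − d); a restraint is *followed* when its violation
is at or below the bound correction (default 5.0 Å), inclusive at the
boundary — a 5.0 Å violation is followed, 5.1 Å is not. The count of
followed restraints is non-decreasing in the correction and reaches the
total as the correction grows.

## C2-symmetric rigid-body docking

The receptor dimer is prepared once: the two-fold axis is computed from
the Kabsch transform between its chains (the rotation angle must be within
5° of 180°), moved onto the z-axis through the origin, with the axis sign
canonicalized so preparing an already-prepared receptor is the identity.
A pose is the rigid placement (unit quaternion + translation) of ligand
copy 1; copy 2 is generated by the exact 180° rotation about z, so every
candidate assembly is C2-symmetric by construction.

**Score.** `total = w_r·E_restraint + w_c·E_clash + w_e·E_elec +
w_contact·E_contact` with defaults w_r = 10, w_c = 1, w_e = 0,
w_contact = 0.02:

* `E_restraint`: flat-bottom quadratic, k = 1 per Å², on the per-group
  minimum distance (UIR) or pooled effective distance (AIR).
* `E_clash`: soft-sphere overlap, `Σ max(0, r_i + r_j − d)²` over
  cross-body atom pairs. Radii are per-element (C 1.7, N 1.55, O 1.52,
  S 1.8 Å); Cα-only bodies use 3.0 Å beads, so flush bead contact sits at
  6.0 Å.
* `E_contact`: an attractive Gaussian well centred 0.5 Å outside flush
  contact (σ = 0.8 Å), summed over cross-body pairs. This is the coarse
  stand-in for the attractive van der Waals / buried-surface terms every
  practical docking score carries. Without it the objective is flat across
  the entire restraint-feasible set and ranking among feasible poses would
  be arbitrary; its weight is deliberately small so that restraint
  violations of a fraction of an Ångström already outweigh any achievable
  contact gain.
* `E_elec` (optional, off by default): Debye–Hückel screened Coulomb on
  residue formal charges (Lys/Arg +1, Asp/Glu −1) with solvent dielectric
  80 and κ from the ionic strength (default 0.3 M); this replaces a full
  Poisson–Boltzmann treatment, which is out of scope.

The receptor's exact symmetry is exploited: the copy2/receptor clash and
contact terms equal the copy1/receptor terms and are counted by doubling.

**Search.** Multi-start local refinement: `n_starts` (default 64) initial
poses with Shoemake-uniform random orientations and centroids sampled in a
shell of 0.6–1.2 × (receptor radius + ligand radius); each start is
refined by Nelder-Mead over the 6 rigid degrees of freedom (rotation
vector increment + translation) with an initial simplex of 0.4 rad / 4 Å
steps. Everything is driven by one seeded generator, so a run is
deterministic given (seed, config).

**Clustering and ranking.** Poses are single-linkage clustered on pairwise
ligand RMSD minimized over the C2 copy swap (cutoff 7.5 Å). Clusters and
their representatives are ranked by (1) fewest strictly violated restraint
groups, (2) lowest total score, (3) lowest restraint energy, then
lexicographic pose parameters as a deterministic tie-break. Preferring the
solutions with the least violations mirrors how the original analysis
selected its representative models.

## Synthetic study system

The generator builds everything the pipeline needs without external data:

* **Toy tetramer.** Receptor chains are smoothed self-avoiding random
  walks of Cα beads (3.8 Å bonds, 3.5 Å exclusion, 30 beads per chain by
  default), duplicated by an exact C2 about z; the ligand (24 beads) is
  placed against one receptor chain. Candidate placements are slid to
  contact along random approach directions, *settled* into a local optimum
  of the packing energy (clash + contact reward — a native pose is a
  packing optimum, not a tangent graze), and the best-packed candidate
  whose interface offers spread anchor beads on both bodies is kept. The
  default closest approach (6.0 Å) is flush contact for 3.0 Å beads, so
  the ground truth is clash-free under the docking score. Residue names
  are drawn from a charged/reactive alphabet and interface bead pairs are
  labeled lysine so a cross-linking experiment has sites to find.
* **Planted cross-links.** True links are sampled from reactive bead pairs
  whose ground-truth register distance is within the linker spacer,
  greedily maximizing the worst-case anchor separation on both bodies
  (clumped anchors carry almost no orientation information). Decoys —
  simulated false-positive identifications — are sampled from pairs beyond
  the spacer by a 5 Å margin and labeled.
* **Binding plates.** Saturation curves follow the one-site
  total+nonspecific model with Gaussian noise of a given fraction of Bmax
  (default 2%), 12 log-spaced concentrations per curve.

Every generator is a pure function of its spec, seed included.

**What the toy does and does not emulate.** It reproduces the *topology*
(a symmetric dimer flanked by two ligand copies), the *information
structure* (a handful of spacer-bounded residue-pair restraints plus an
interface patch), and the *statistics* of the binding assay. It does not
emulate protein folds, side chains, or real surface complementarity. Sizes
were chosen so that the planted-recovery benchmark is identifiable: four
distance inequalities with a 7.7 Å radius cannot pin a pose on any
geometry unless the restraint anchors are spread and the native pose is
also the packing optimum of its neighborhood; the generator enforces
exactly that, so recovery failures indicate defects in restraint handling,
scoring, search, or clustering rather than an underdetermined benchmark.
Passing tests therefore validate the machinery, not the information
content of sparse real cross-link data.

## Sequence properties and cross-linked peptide masses

Molecular weights (average and monoisotopic) come from pyteomics mass
tables (residues + one water). Extinction coefficients at 280 nm use the
Trp 5500 / Tyr 1490 / cystine 125 M⁻¹cm⁻¹ increments, reported both for
the reduced and the all-cystine convention; the all-cystine value is what
matches the printed DID coefficient (10,220 = 5500 + 3×1490 + 2×125). The
isoelectric point bisects the Bjellqvist fixed-pKa net charge model
(side-chain pKa: K 10.0, R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0;
residue-specific terminal pKa as in the ExPASy tool) on pH ∈ [0, 14] to
0.01 pH; the charge is strictly decreasing in pH, so the root is unique.

Conventions for the study constructs: MW is computed on the full tagged
construct (the printed 29,078 Da for DID is only consistent with the
MGSSERSHHHHHHSGSE tag included), while pI is computed on the untagged
domains (the electrostatic complementarity argument concerns the domains);
a flag allows tag inclusion. Construct builders slice user-supplied
full-length UniProt parents (DIAPH1 residues 142–380; MFN2 minus residues
1–19 and 401–705) and carry per-position parent numbering, so spliced
constructs map residue numbers exactly.

Tryptic digestion cleaves C-terminal to K/R except before P and enumerates
peptides with up to a configurable number of missed cleavages; a
cross-linked lysine counts as a missed cleavage. The theoretical mass of a
bridged pair is mono(pepA) + mono(pepB) + bridge + fixed modifications,
with carbamidomethyl (+57.02146 Da) applied to every cysteine except a
sulfhydryl-bridged one, and m/z(z) = (M + z·1.007276)/z.

## Saturation binding

The one-site total+nonspecific model is
`Y = Bmax·X/(Kd + X) + NS·X + B0`. A constant background B0 is included
because plate blanks are subtracted imperfectly; it can be disabled. The
fit is unweighted nonlinear least squares (lmfit Levenberg–Marquardt) with
Kd log10-parameterized (positivity by construction) and Bmax, NS bounded
below by zero; optional 1/Y² weighting is available. Standard errors come
from the Jacobian at the optimum; the Kd error is transformed from the log
scale (SE_Kd = ln10 · Kd · SE_logKd). Initialization: B0 from the lowest
concentration, NS from the top-two-point slope, Bmax from the remaining
span, Kd from the first concentration reaching half of it. Non-convergence
is flagged, not raised; a fitted Bmax indistinguishable from zero sets an
unidentifiable-Kd flag. The competitor condition is fitted with the same
model as an *apparent* Kd, exactly as the study reports it; a
Cheng–Prusoff conversion to Ki is provided but not used for comparisons.

## Problem sizes and numerical choices

The test and acceptance workloads run on one CPU in minutes: binding
recovery refits 200 simulated plates per affinity regime (~1 s each
regime); docking recovery runs 20 toy complexes at 64 starts (~15 s each).
Nelder-Mead uses xatol 1e-3, fatol 1e-6, and at most 4× the configured
refine_iterations function evaluations. Coincident atoms give an effective
distance of 0 rather than a singularity. Ties in cluster ranking are
broken deterministically. Bisection tolerances: pI 0.001 pH internally,
reported to 0.01.

## Known limitations

* Rigid bodies only: no flexible refinement, desolvation, or explicit
  solvent; the score is not calibrated to any published docking potential.
* The electrostatic term is screened-Coulomb on formal charges, not
  Poisson–Boltzmann; it is off by default and plays no part in the
  validated benchmarks.
* The AIR file dialect stores a single chain per selection side; grouped
  multi-chain AIRs are constructed programmatically.
* Restraint information content is not assessed statistically (no FDR on
  planted decoys); decoys are bookkeeping only.
* The construct calculators reproduce printed constants only when the
  third-party UniProt parent sequences are supplied by the user; they are
  not redistributed.
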