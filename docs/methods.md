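# Methods

This note documents the models, conventions and numerical choices behind
templateprobe: what each component computes, which constants are fixed and
why, what the synthetic generator does and does not emulate, and where the
design was genuinely open.

## Structure model and standardization

Structures are chains → residues → heavy atoms with Ångström coordinates.
Parsing (PDB/mmCIF, via gemmi) keeps the first model only, drops waters
and hetero molecules, and retains every protein chain.  Standardization
collapses altlocs to the highest-occupancy conformer (ties resolve to the
lexicographically first label, so results are deterministic), removes
hydrogens, maps a fixed table of modified residues to their standard
parents (MSE→MET with SE→SD, SEC/CSO→CYS, SEP→SER, TPO→THR, PTR→TYR,
MLY→LYS, HYP→PRO) and drops anything unmappable with a log entry, because
the side-chain metrics need standard topology.  Standardization is
idempotent and never adds atoms.  Sequences are extracted gaplessly: one
letter per resolved residue, numbering gaps insert nothing.

## Synthetic structures

The generator exists so every perturbation and metric can be exercised
without downloading benchmark targets.  Three layers:

**Backbones** are built by internal-coordinate chain extension with ideal
bond lengths (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å) and angles;
presets fix (φ, ψ) at (−57°, −47°) for helix and (−120°, +120°) for
strand, with ω = 180° throughout; `coil` samples from five
Ramachandran-region bins with ±15° jitter and `mixed` alternates
helix/strand/coil segments.  The default sequence cycles through all 20
amino acids so every χ convention is exercised.

**Side chains** are grown from a single ideal-geometry Z-matrix table
(one row per heavy atom: bond, angle, and either a fixed torsion or a χ
reference).  Cβ is placed with the improper dihedral C–N–CA–Cβ = +122.7°
(L-chirality) at 1.53 Å / 110.4°; proline uses a tighter N–CA–Cβ of 102°
together with pucker angles (χ1 = −19.5°, χ2 = 36°) chosen so its ring
closes exactly (CD–N = 1.473 Å).  Because proline's Cβ geometry is
intrinsically non-standard, the generic backbone Cβ heuristic reproduces
ideal Cβ positions to < 0.01 Å for all residue types except proline
(≈ 0.2 Å there).  Rotamer policy is either one fixed common rotamer per
residue type (`ideal_single`) or seeded draws from a small discrete
library (`random_library`).  By default, side chains that collide with
other residues (heavy atoms closer than 1.6 Å across residues, bonded
peptide and proline-ring neighbour pairs excepted) are re-rotamerized over
a deterministic χ1/χ2 grid; residues that stay irreparably clashed are
shrunk to ALA (or GLY when even Cβ clashes) as steric relief.  Explicit
χ overrides are exempt from repair, so requested angles always round-trip
exactly.

**Globules** target the compact-fold regime: the CA trace follows a
box-filling serpentine polyline (lanes 6 Å apart, box edge sized so the
path holds L residues at the 3.8 Å CA step), which by construction puts
the radius of gyration near the 2.2·L^⅓ Å scaling of compact proteins.
The backbone is fitted to that curve in torsion space: at each residue
the pair (φᵢ, ψᵢ) is scanned on a 9°×6° joint grid to bring the next CA
closest to its target point, under hard floors — CA–CA ≥ 4.2 Å at
sequence separation > 2 (3.8 Å at separation 2), backbone atoms ≥ 2.4 Å
at separations 2–4, adjacent carbonyl oxygens ≥ 2.2 Å — with local
backtracking and target re-jitter when the fit walls in.  Bond lengths
and angles remain exactly ideal because only torsions are searched.  A
seeded random rotation and 0.3 Å target jitter decorrelate different
seeds; generation is bitwise deterministic in (length, seed).

What the generator does *not* emulate: real secondary-structure statistics
(the serpentine trace is not Ramachandran-weighted), packing energetics,
hydrogens, missing density, alternate conformers, or experimental noise.
Tests passing on these fixtures show the *operations* are correct — exact
geometry, known χ angles, clash-free hard-sphere packing — not that any
metric value transfers to experimental structures, with one deliberate
exception: the σ = 1 Å Gaussian-noise lDDT is structure-independent by
construction (see below), so its value on synthetic fixtures is the value
on any structure.

## Perturbations

* **Gaussian noise** adds an independent N(0, σ²) draw to every coordinate
  component (default σ = 1 Å), one seeded generator, atoms in file order,
  x→y→z — reproducible and topology-preserving.
* **PCA projection** mean-centers the atom cloud, takes the principal
  axes of all heavy atoms (CA-only is available as an option; the fit set
  is a genuine ambiguity and all-atom is the least arbitrary reading),
  zeroes all but the first 1 or 2 components and restores the mean.
  Eigenvectors are sign-fixed (largest-magnitude entry positive) and ties
  resolve to original axis order, so the projection is deterministic.
* **Side-chain stripping** keeps N, CA, C, O per residue plus a Cβ by
  policy: `absent`; `origin` places every Cβ at the documented constant
  (0.1, 0.1, 0.1) Å — "next to" rather than exactly at the origin to
  avoid exact-coincidence degeneracies; `heuristic` rebuilds Cβ from the
  backbone frame as Cβ = CA + w_a·(b×c) + w_b·b + w_c·c with b = CA−N,
  c = C−CA and weights (−0.58273431, 0.56802827, −0.54067466) — linear in
  a local frame, hence exactly rigid-motion equivariant; `template` keeps
  the original Cβ.  Glycine receives a Cβ in `origin`/`heuristic` modes
  (consistent with glycine-extension template semantics) and none in
  `template`/`absent`.
* **Glycine-Cβ reduction** renames every residue GLY and keeps backbone
  plus Cβ (original where present, else heuristic), erasing amino-acid
  identity; idempotent, backbone untouched.
* **Hit filtering** keeps m8 rows with id_min ≤ identity ≤ id_max
  (inclusive) and query coverage (qend−qstart+1)/qlen ≥ cov_min, then one
  best survivor per query by e-value, ties by higher identity then
  lexicographic target id.  Coverage is measured on the query because the
  template must cover the modeling target; the alternative (target
  coverage) is exposed through the record fields.  Defaults 30%/70%/0.8.

## Metrics

**Kabsch superposition** minimizes RMSD over proper rotations; the SVD
determinant correction forbids reflections, so mirror images keep a
positive residual.

**TM-score** = max over superpositions of (1/L_ref) Σ 1/(1+(dᵢ/d₀)²) with
d₀ = max(1.24·(L_ref−15)^⅓ − 1.8, 0.5) Å and L_ref the reference residue
count — the published convention, restated here because the toolkit
re-implements the score rather than wrapping a binary.  The search seeds
superpositions from gapless mapped fragments of lengths L, L/2, L/4, …
(≥ 4; exhaustive lengths when L ≤ 32), refines each by iterating
"superpose on pairs closer than max(d₀, 4.5 Å), re-select" to a fixed
point, and finally polishes the five best transforms by direct
Nelder–Mead maximization of the TM objective over the six rigid degrees
of freedom.  The first seed evaluated is the full-mapping Kabsch fit, so
the searched score can never fall below it.  Correctness is anchored to a
brute-force multi-start optimizer on small problems in the test suite,
not to bit-compatibility with any existing program.

**Rectified Cα-RMSD** superposes mapped CAs by Kabsch, clips per-residue
deviations at a cap before squaring, and returns the root mean square.
The cap bounds any single residue's contribution by cap/√n.  The exact
rectification rule used by reference implementations is not normative
here; the default cap is 5 Å and is exposed as a parameter.

**All-atom RMSD** pairs atoms by (mapped residue, atom name) — no name
remapping across residue types — fits the superposition on shared
backbone atoms and evaluates over all shared heavy atoms or side-chain
atoms only; unmatched atoms are skipped and counted.

**lDDT** is superposition-free.  Candidate pairs are reference heavy-atom
pairs within the 15 Å inclusion radius belonging to different residues;
a pair is conserved at tolerance t iff both atoms exist in the model and
|d_model − d_ref| < t; the per-pair score averages the four thresholds
{0.5, 1, 2, 4} Å.  The global score averages pairs (not per-residue
means, which are reported separately) — the two differ and pair-averaging
follows the metric's reference definition.  Atoms missing from the model
count as non-conserved, penalizing incomplete models.  Two toggles:
`stereo_checks` (default off) excludes side chains of model residues that
fail the stereochemistry check; `symmetry_resolution` (default on)
chooses, per ambiguous residue (ASP OD1/OD2, GLU OE1/OE2, PHE/TYR
CD1/CD2+CE1/CE2, ARG NH1/NH2), whichever 2-fold naming conserves more of
that residue's pairs, applied globally to all its pairs.

**χ-MAE** compares χ1–χ4 per residue pair (same residue type, both sides
defining the angle), wrapping differences on the circle and additionally
allowing the 180° flip for the 2-fold symmetric terminal groups {ASP χ2,
GLU χ3, PHE χ2, TYR χ2}.  ASN/GLN/HIS amide/imidazole flips are *not*
treated as symmetric: the atoms are chemically distinguishable.

**Stereochemistry check** flags residues whose bonds deviate more than
tolerance_sigmas × 0.02 Å or angles more than tolerance_sigmas × 2.5°
from the same ideal tables the generator builds from (default 5σ), or
with heavy atoms closer than 1.5 Å to another residue.  Deriving bonded
topology from the builder's Z-matrix keeps the two components consistent:
an unperturbed synthetic structure is violation-free by construction,
while σ = 1 Å noise (bond-length changes of order √2 Å) flags essentially
every residue — the behaviour that motivates disabling stereochemistry
screening when scoring deliberately distorted templates.

**Burial** counts, per residue, other residues' Cβ (CA for glycine)
within 10 Å of its own Cβ/CA, with quartile bins for stratified
reporting.  A neighbor count was chosen over solvent-accessible surface
area deliberately: it needs no mesh geometry, is monotone in depth for
compact folds, and suffices for stratifying metric tables; it is a proxy,
not a SASA reproduction.

## Alignment

Residue mappings come from position (identical sequences) or global
Needleman–Wunsch under BLOSUM62 with affine gaps, computed by Biopython's
`PairwiseAligner`.  'X' is made neutral (scores 0 against everything).
Gap defaults are open −10, extend −0.5 — a widely used global-alignment
default, exposed as parameters since no single "default" is canonical.
The engine's first optimal alignment is taken; its tie order among
co-optimal alignments is the library's own deterministic enumeration.
The optimal score is verified against an independent Gotoh three-matrix
dynamic program in the tests.

## The σ = 1 Å fingerprints

For two atoms much farther apart than the noise scale, the change in
their distance under independent per-coordinate N(0, σ²) noise on both
atoms is asymptotically N(0, 2σ²) (the difference vector projected on the
unit separation vector).  The expected lDDT is then
mean_t P(|N(0, 2σ²)| < t) = mean_t erf(t/2σ) ≈ 0.659 at σ = 1 Å —
independent of the structure, because at a 15 Å inclusion radius distant
pairs dominate.  Measured values on 150–300-residue synthetic globules
agree to < 0.01.  The TM-score of a noisy copy follows from the
displacement distribution d² ~ σ²·χ²₃ under the near-identity optimal
superposition: E[1/(1+d²/d₀²)] rises with chain length through d₀, from
≈ 0.83 at 100 residues to ≈ 0.95 at 400, averaging ≈ 0.90 over that
range.

## Pipeline and adapter

`run_experiment` executes targets × perturbations, evaluates every
perturbed template against its unperturbed reference (stage "perturbed"),
and, when an external predictor command is configured, evaluates its
output as stage "refined".  Undefined metrics are explicit nulls, never
zeros.  Per-perturbation seeds derive from (global seed, target index,
perturbation index) through `SeedSequence`, so reruns are bitwise
reproducible and every random draw is traceable.  Adapter contract: a
shell command with `{template}`, `{sequence}`, `{workdir}` placeholders
that must deposit exactly one new PDB/mmCIF file in the work directory,
parseable and covering ≥ 50% of the template's residues; failures mark
the row and the run continues.  Predictors are never bundled or
downloaded; without an adapter the run is perturbation-only.  Multi-chain
structures are evaluated whole by default (chains flattened in order);
per-chain evaluation is a caller-side split.

## Problem sizes and determinism

The shipped verification uses 20 structures per benchmark signature
(150–300 residues for the lDDT mean, 100–400 for the TM mean), enough to
put the standard error of both means well inside their tolerance bands
while keeping a full run in the minutes range on one CPU.  All stochastic
components (coil sampling, globule targets, rotamer draws, noise) consume
`numpy` `default_rng` streams seeded explicitly; no global RNG state is
touched.

## Known limitations

* Synthetic side-chain geometry is a single idealized set; rotamer-library
  realism and bond-length/angle variance of real structures are absent.
* Globule fits occasionally mutate a handful of residues to ALA/GLY for
  steric relief; composition is therefore only approximately the 20-cycle.
* The TM-score search is stochastic-free but heuristic; on adversarial
  inputs the polished value can sit marginally below the global optimum
  (bounded in tests at 10⁻³ on small problems).
* lDDT ambiguous-naming resolution is greedy per residue; interacting
  ambiguous residues are not jointly optimized.
* The burial measure is a neighbor-count proxy, not SASA.
* Only single-model files are considered; NMR ensembles beyond model 1
  are ignored.
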