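# Methods

## Scope and model

The package quantifies conformational differences between atomic models of
a pentameric ligand-gated ion channel and summary statistics of
ligand-bound trajectories. It does not build, refine or simulate models;
inputs are coordinate files (PDB/mmCIF) assumed to share a reference frame
(models refined into maps of the same aligned reconstruction do; otherwise
the pipeline superposes every model onto the closed reference over all
shared receptor C-α, unweighted, and records that choice in the run
manifest). Hydrogens are excluded from all distance, RMSD and pore
computations by default, since cryo-EM models generally lack them.

## Rigid-body domain motion

Subunit-domain motion between two states is summarised by three numbers
per domain: COM shift, tilt and rotation.

* COM shift: difference of unweighted centroids of the domain's heavy
  atoms. Heavy atoms (rather than C-α only) are the default because the
  centroid of a rigid body is best estimated from every atom it contains;
  a `ca_only` flag restricts to C-α for comparison.
* Tilt/rotation: both domain copies are centred on their own C-α centroid;
  the optimal proper rotation is found by least-squares superposition
  (Kabsch via quaternion alignment, reflections rejected); that rotation is
  decomposed against the reference state's pore axis into a twist T about
  the axis and a residual swing S with R = S·T (quaternion projection:
  the twist quaternion is the normalised projection of the rotation
  quaternion onto the axis). The twist angle is reported as *rotation*,
  signed right-handed about the ECD-ward axis (counterclockwise positive
  viewed from the extracellular side); the swing angle is *tilt* in
  [0°, 180°]. Recomposition S·T reproduces the input to < 1e-9, which the
  property tests enforce over uniform random rotations.

An equivalent description of domain motion in the literature extracts
rigid rotations from a PCA of COM-aligned coordinates; the swing–twist
decomposition is the closed-form counterpart and is preferred here because
it is exactly defined, exactly invertible, and needs no eigenvector
interpretation. Residual RMSD after the rigid fit is reported so that
non-rigid deformation is visible rather than silently absorbed.

The pore axis is the largest-variance principal direction of all receptor
C-α (the channel is prolate), through the all-C-α centroid, oriented so the
ECD centroid lies on the positive side. By 5-fold pseudosymmetry the
lateral directions are nearly degenerate and orthogonal to it, which makes
the estimate stable (< 0.5° deviation at σ = 0.3 Å coordinate noise in the
tests). A user-supplied axis in the config overrides it.

## State projection

fraction_i = (x_q − x_c)·v̂_i / |v_i| with v_i = x_d − x_c per paired C-α.
Residues with |v_i| < ε = 0.2 Å are flagged undefined instead of dividing
by near-zero; both the absolute projection (Å) and the fraction are
emitted, since either may be wanted for a heatmap. Fractions are not
clipped to [0, 1]: overshoot past the desensitized position is real
signal. The operation is exactly linear — a λ-blend of the end states
yields fraction λ at every defined residue — which the acceptance tests
check to 1e-9 on in-memory models (through PDB files the fixed-width
0.001 Å coordinate rounding limits agreement to ~1e-3).

## Pore profile

r(z) = max_{c ∈ plane, |c−axis| ≤ L} min_a (|c − x_a| − vdW_a), sampled
every z_step = 0.25 Å with lateral bound L = 5 Å. The plane-wise maximum
is found by Nelder–Mead refinement from a fixed 9-point start grid plus
the previous plane's optimum (continuity); there is no randomness, so
profiles are bit-reproducible. Established pore-profiling tools use a
stochastic (Monte Carlo) search for the same quantity; the deterministic
scheme was chosen so tests can pin exact values, and the tests verify the
optimizer never falls more than 0.05 Å below an exhaustive 0.1 Å planar
grid search. vdW radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, default
1.70 Å — config-overridable and recorded in the output; different radius
files shift absolute radii at the ±0.1–0.2 Å level, so cross-tool
comparisons carry that tolerance. Waters and ligands are excluded by
default so a bound modulator cannot occlude the measurement. Planes whose
optimum is negative (atom overlap) are clamped to 0 and flagged; planes
with no atom within axial reach are flagged empty, never interpolated.
The default z-range is the axial extent of the TMD padded by 1.5 Å so the
gate windows at the helix termini are covered.

Gate windows span the axial coordinates of the five gate residues'
side-chain heavy atoms (C-α if no side chain is modelled) ± 1 Å; the gate
radius is the profile minimum in the window. State rule, using the Born
radius of Cl⁻ (2.3 Å) and the hydrated-Cl⁻ radius (3.2 Å) as the bounds
bracketing a permeation-compatible minimum radius: 9′ < 2.3 Å → closed;
else −2′ < 2.3 Å → desensitized-like; else open-like; indeterminate if a
gate window is uncovered.

## Trajectory metrics

Trajectories are multi-model PDB with fixed atom order; inputs are assumed
whole/imaged (no periodic-boundary handling — re-imaging is a user
pre-step). Ligand RMSD fits each frame to the reference on the
binding-site backbone (backbone atoms within 10 Å of the ligand in the
reference frame) and measures over ligand heavy atoms without re-fitting —
a ligand-only fit would hide pose drift, which is the signal of interest.
Stability: mean ligand RMSD over the final 20% of frames, stable iff
≤ 2.0 Å (boundary inclusive); window and threshold are exposed and logged.
RMSF is computed after superposing every frame on the protein backbone of
frame 0, aggregated per residue. Contact persistence deliberately
simplifies typed interaction fingerprints (H-bond, π-stacking, …) to "any
heavy-atom pair within 4.0 Å": the persistence statistic — fraction of
frames with a contact — is the quantity of interest and the simplification
is recorded in the output metadata, so typed-fingerprint percentages are
not numerically comparable. Pocket volume is a deterministic grid
flood-fill from a seed point: points ≥ vdW + 1.4 Å probe from every atom,
inside the padded bounding box of the lining residues, and buried (≥ 9 of
14 fixed ray directions hit protein within 10 Å), counted × grid³ at
0.5 Å spacing. It is a surrogate for alpha-sphere pocket finders: volumes
are method-dependent and should be read as relative (closed vs
desensitized site), not absolute.

## Synthetic data: what it emulates and what it does not

The generator builds exactly what the metrics consume and nothing more: a
C5-symmetric pentamer (4 α1-like + 1 β chain, identical geometry) with a
40-residue ECD pseudo-C-α slab and a 120-residue TMD of four ideal
α-helices (rise 1.5 Å/residue, helical radius 2.3 Å, 100°/residue), M2
lining the pore with gate rings whose pseudo side-chain atoms sit on
circles of prescribed geometric radius (defaults 3.0/3.5 Å → pore radii
1.3/1.8 Å, the closed pattern); a rigid 24-heavy-atom dummy ligand at an
inter-subunit ECD site; scripted trajectories (Gaussian jitter for the
stable regime, a linear drift to 6 Å RMSD for the unstable one, contact
schedules enforced exactly by marker atoms parked far away outside their
scheduled frames). Rigid motions are applied as twist-then-swing about the
domain's heavy-atom centroid so that the transition metrics are their
exact inverses.

Real data differ in ways the generator does not model: sequence and
side-chain chemistry, α1/β numbering offsets, imperfect pseudosymmetry,
non-rigid domain deformation, model-building error correlated with map
quality, and force-field dynamics. Passing tests therefore demonstrate
that the *metrics* are correct and well-conditioned (exact inversion
noiseless; 0.5°/0.05 Å recovery at σ = 0.2 Å coordinate noise), not that
any particular biological conclusion follows from real models.

## Numerical choices and degenerate inputs

* Superposition requires ≥ 3 non-collinear points in both sets; rank < 2
  raises a degenerate-geometry error rather than returning a meaningless
  rotation. Reflections are never returned.
* Alt-locs collapse to the highest-occupancy record, ties to the
  lexicographically smallest identifier. Residue identity is
  (chain, number, insertion code); residue-name mismatches across models
  warn but do not fail, because cross-role pairing legitimately crosses
  numbering offsets via the config.
* Twist angles are mapped to (−180°, 180°]; a 180° swing exactly
  orthogonal to the axis has twist 0 by convention.
* Angle outputs are degrees; tables are written with 6 significant
  digits; TSV column order is fixed, so identical inputs give
  byte-identical tables.
* Problem sizes used in the shipped analyses: 2 430-atom pentamers,
  0.25 Å pore sampling (~165 planes/profile), 500-frame scripted
  trajectories for stability/contacts and 10⁴ frames for the
  Gaussian-statistics checks — small enough to run in about a minute end
  to end while leaving the Monte-Carlo expectations within their 5%
  bands.

## Known limitations

* The pore-state rule uses only the two gate radii; intermediate
  constrictions elsewhere in the pore affect the profile but not the call.
* Conformations are compared after a whole-receptor superposition; a
  perfectly symmetric global twist of all subunits is partially absorbed
  by that alignment, so per-subunit angles are best measured on models
  sharing a map-derived frame (the CLI's `--no-align` path).
* Pocket volumes depend on grid registration at the ±half-spacing level;
  for cavities a few grid cells wide this quantization dominates the
  error budget.
* No mmCIF writer; the PDB writer exists for synthetic fixtures and
  caps serial numbers at 99 999.
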