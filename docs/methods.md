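# Methods

## The SIE model

The solvated interaction energy is an end-point estimator: it scores
bound-state snapshots only, with the free receptor and ligand kept
rigid at their bound-pose coordinates (single-trajectory convention).
Per snapshot,

ΔG_bind = α · [ E_c(D_in) + ΔG_R + E_vdW + γ·ΔMSA(ρ) ] + C

with the fixed coefficients α = 0.104758 (dimensionless), γ =
0.012894 kcal/(mol·Å²), C = −2.89 kcal/mol, D_in = 2.25 and ρ = 1.4 Å.
These were calibrated once, externally, against absolute binding
affinities; the package treats them as constants (`SIEParameters`) and
does no refitting. The solvent dielectric is not part of that published
coefficient set; we default to 78.5 and expose it.

Averaging order: the headline ΔG_bind is the mean of the per-snapshot
combinations, with the SD over the same per-snapshot values; the window
means of the four components are also emitted. Because the combination
is affine, combining the averaged components reproduces the averaged
combination exactly — both forms are kept for table-style reporting.
Replica pooling concatenates windows (5 replicas × 200 snapshots →
n = 1000) before averaging.

## Electrostatics

`E_c` is the strictly intermolecular Coulomb sum k_e/D_in · Σ q_iq_j/r_ij
with k_e = 332.0636 kcal·Å/(mol·e²). No exclusions are needed because
only cross-partner pairs enter. Any pair below 0.1 Å raises an error
naming the atoms: a distance that small means a corrupt structure, and
silently returning ±10⁶ kcal/mol would poison window averages.

The reaction-field term is a Generalized-Born surrogate for the
boundary-element Poisson solvation used in classic SIE
parameterisations. Effective Born radii come from Hawkins–Cramer–Truhlar
pairwise descreening with **zero radius offset and unit scaling
factors**, so an isolated atom's effective radius equals its intrinsic
radius and the single-ion energy reduces to the analytic Born
expression — the standard unit test for continuum codes. Pair energies
use the Still function f_GB = sqrt(r² + a_i a_j exp(−r²/4a_i a_j)),
including self terms. Overdescreened (deeply buried) atoms are clamped
to an effective radius of 50 Å. ΔG_R = G_R(complex) − G_R(receptor) −
G_R(ligand) at bound-pose coordinates.

GB and a finite/boundary-element Poisson solution are not
interchangeable: GB typically deviates by a few percent on polar
solvation free energies of compact solutes and more for highly charged
ones (a −4 e RNA is exactly that case). The package therefore treats
ΔG_R as internally consistent within its own model; no claim is made
that its values match Poisson-based ones, and nothing in the test suite
compares them to externally computed solvation energies.

## Surface areas

`ΔMSA` is approximated by solvent-accessible surface area differences
(Shrake–Rupley, 480 Fibonacci sphere points per atom, probe 1.4 Å,
biotite's implementation with the package's per-atom radii). SASA and
the molecular (contact) surface differ by a roughly constant scale for
compact solutes; since γ multiplies a *difference* of areas, this
scale is absorbed into the interpretation of γ·ΔMSA and is documented
rather than corrected.

Two numerical choices matter:

* **Canonical orientation.** A fixed point mesh makes raw Shrake–Rupley
  areas drift by O(1/√points) under global rotation. All areas are
  evaluated in a deterministic principal-axes frame (eigenvectors of
  the coordinate covariance, signs fixed by the third moment of the
  projections), which makes them exactly rigid-motion invariant. For
  near-symmetric clouds the sign rule is ambiguous, but then the flip
  maps the cloud onto itself and the area is unaffected.
* **Shared frame for differences.** ΔMSA evaluates all three terms in
  the complex's canonical frame, so per-atom sampling noise cancels
  between bound and free states; for fully separated partners the
  difference vanishes to single-precision accumulation (~10⁻³ Å²).

## Separated-partner limits

ΔG_R and ΔMSA must vanish as the partners separate. For ΔMSA this is
geometric. For ΔG_R it holds only when both partners are net-neutral:
the GB cross term between monopoles decays as 1/r and is still ~1
kcal/mol at 500 Å for a (−4 e, +2 e) pair — correct continuum
electrostatics, not an artefact. The limit checks therefore use the
generator's net-neutral charge model (`charge_model="zero-net"`), where
the leading dipole–dipole tail is ~10⁻⁵ kcal/mol at 500 Å.

## Decompositions

*Per nucleotide* (the per-unit ΔG_bind of each RNA base): by default
each nucleotide is scored as a standalone SIE calculation against the
receptor, with the remaining nucleotides **removed from both end
states** — each row is then a genuine single-nucleotide binding energy,
and the gas-phase columns still sum exactly to the full intermolecular
totals because Coulomb and LJ are pairwise. A context-retaining mode
keeps the other nucleotides present as environment (they then
contribute to solvation, surface and the gas-phase cross terms); which
convention a study intends is usually unstated, so both are available
and labelled.

*Per residue* (ΔG_bind,res): a receptor residue's contribution is its
pairwise intermolecular Coulomb + LJ energy with the ligand plus half
of the receptor–ligand GB screening cross terms (computed with
complex-state Born radii), the other half being attributable to the
ligand — standard practice for GB-based decomposition. The surface term
is not decomposed. Rows at or below −0.90 kcal/mol or at or above
+0.60 kcal/mol are flagged, mirroring the usual labelling thresholds of
per-residue contribution plots. Gas-phase additivity to the totals
holds to < 10⁻⁶ kcal/mol by construction and is asserted in the tests.

## Trajectory statistics

Superposition is the least-squares Kabsch fit (scipy's quaternion
solver), uniform weights by default, mass weighting optional; the
returned rotation is always proper. RMSD series superpose each frame on
a fit selection before measuring over the analysis selection. RMSF is
taken about the mean structure after optional per-frame fitting;
per-residue RMSF is the mean over the residue's atoms. Radius of
gyration and centre-of-mass distances are mass-weighted with standard
atomic masses by element (an unknown element is an error, never a
silent zero mass). Percentiles use linear interpolation between closest
ranks (numpy's default); distance distributions are summarised by
5/25/75/95th percentiles, mean and extrema, with "outliers" defined as
values outside the 5–95 whiskers.

The inter-domain comparison (`aligned_backbone_rmsd`) globally aligns
the one-letter sequences of two domains (BLOSUM-type scoring) and
superposes the Cα atoms of all aligned residue pairs. Inter-domain RMSD
values of this kind are sensitive to the residue subset: trimming
flexible termini or loops at the alignment stage can move the value by
tenths of an Å, so the number of fitted residues is reported with the
RMSD.

## Interaction fingerprints

Donor/acceptor typing is element + connectivity: any N/O with a
covalently attached hydrogen donates, any N/O accepts. Hydrogen
attachments are inferred once from the reference coordinates (nearest
heavy atom within 1.25 × the summed covalent radii) so the topology is
identical across frames. Defaults, in the range used by common
pharmacophore tools and configurable per call: H···A ≤ 3.0 Å with
D–H···A ≥ 120°; ring-centroid distance ≤ 5.5 Å with plane angles ≤ 30°
(parallel) or 60–90° (T-shaped), intermediate tilts unclassified;
charged-group (phosphate, guanidinium, ammonium, carboxylate) minimum
atom distance ≤ 5.6 Å, opposite signs only. H-bond direction is
labelled from the RNA's perspective (HBD = RNA donates).

Occurrence identity is (kind, protein residue, nucleotide,
canonicalised atom set); chemically equivalent atom permutations (the
two guanidinium NH₂ groups, OP1/OP2, carboxylate oxygens, amino and
ammonium hydrogens) are collapsed so a salt bridge that migrates
between equivalent oxygens is one interaction, not two. Occurrence is
100 × frames-present / window-size, exactly.

## The synthetic generator

`make_toy_complex` builds a ~200-atom complex: an extended 3–5 nt RNA
(reduced representation: phosphate, a sugar trace, idealised planar
base rings with polar hydrogens; one nucleotide every 8.5 Å, bases in a
common plane) and a pseudo-peptide receptor whose side chains are
placed against the actual RNA geometry so that every detector class has
ground-truth positives: aromatic rings stacked 3.4 Å over base rings,
guanidinium/ammonium groups 3.2–3.3 Å from phosphate oxygens, hydroxyl
donors 3.05 Å from base acceptors, carboxylates accepting base N–H.
Construction enforces no inter-residue contact below 2.0 Å (covalently
linked backbone pairs exempt) and fails loudly otherwise. The default
receptor (10 residues, net +2 e) cycles aromatic, charged, polar and
inert types over the nucleotides from two approach lanes (±z).

Charges are a simplified model, not a force field: bundled per-atom
values renormalised per residue to exact integer nets — each
phosphate-bearing nucleotide −1 e (a pentamer is −4 e), Arg/Lys +1,
Asp/Glu −1, all else 0; `charge_model="zero-net"` renormalises every
residue to 0 while keeping local dipoles. Radii and LJ parameters are
per-element values in the range of common biomolecular force fields.

Pseudo-trajectories add i.i.d. Gaussian noise (default σ = 0.25 Å per
coordinate; frame 0 is the unperturbed reference). This emulates the
*magnitude* of equilibrated thermal fluctuation (per-atom RMSF = σ√3 ≈
0.43 Å), not its correlation structure: real dynamics move contacting
atoms collectively, while i.i.d. noise shrinks individual contact
distances by up to several σ, so the Lennard-Jones term acquires a
heavy positive tail and window SDs of pooled ΔG_bind are much larger
than MD-derived ones. That is the main caveat on what passing tests
show about real data: they validate the estimator's arithmetic,
invariances and bookkeeping on known ground truth, not the statistics
of physical sampling. σ was chosen below the contact scale for exactly
this reason. All stochastic draws derive from the spec's master seed
via numpy `default_rng([seed, stream])`; replicas use consecutive
master seeds.

Base threading (`mutate_nucleotide`) keeps the sugar-phosphate atoms
bit-identical and replaces the base with an idealised template placed
on the glycosidic frame: the glycosidic nitrogen stays exactly in
place, the template's N→C1′ axis is matched to the existing bond
direction, and the ring-plane normal's sign is fixed by two declared
ring atoms — so an identity mutation reproduces the original
coordinates and the frame is intrinsic (mutating a rotated complex
yields the rotated mutant). Threading can create close contacts, as
any template-based base swap without minimisation can; these are
returned in a `clash_report` and warned about, never silently dropped.

## Structure I/O conventions

Coordinates are Å; residue indices are the author-assigned PDB numbers,
never renumbered. Multi-model files split on MODEL/ENDMDL; model 1 is
the default working model. Alternate locations resolve to the highest
occupancy, ties to the first encountered. Charges/radii come from PQR
(matched by serial, then by residue/atom name; unmatched atoms are an
error by default, zero-filled with a warning on request) and LJ
parameters from a bundled per-element table — atom typing belongs to
the upstream preparation pipeline. Trajectories are multi-model PDB or
`.npz` (the one binary format supported; written only to scratch
locations). Writing is fixed-width PDB, so write→read round-trips are
exact at format precision (10⁻³ Å).

## Problem sizes

The analysis drivers use the four pentamer complexes (GUAGU and the
three central-trinucleotide variants) with 5 replicas × 200 frames
(pooled n = 1000) for statistics, energies and fingerprints, and
5 × 100 for the decompositions, which evaluate one GB calculation per
nucleotide per frame. The acceptance script uses 5 × 40 pooled
snapshots for the headline toy ΔG_bind and 2000 frames for the RMSF
recovery check. These sizes were picked so a full run stays in the
seconds-to-minutes range on one core while the pooled-window
bookkeeping (including the 5 × 200 → 1000 case) is still exercised in
the test suite.

## Interfaces

The numbered drivers under `analysis/` plus the library functions are
the package's interface; a separate shell CLI would only wrap
`build_complex`/`sie_trajectory` calls that the drivers already show in
context, so none is provided.

## Known limitations

* GB is not a Poisson solver; ΔG_R values are model-internal (above).
* SASA stands in for molecular surface area (above).
* The toy receptor has no peptide connectivity between residues and no
  force-field-consistent internal geometry; it exists to exercise
  interface contracts, not to be simulated.
* Fingerprint percentages depend on the (configurable) geometric
  cutoffs; absolute occurrence values are therefore convention-bound.
* The inter-domain RMSD check requires the two deposited NMR ensembles
  (network or a local `data/` copy) and cannot run fully offline.
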