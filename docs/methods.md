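# Methods

This note documents the model behind `ddgforge`, the provenance of its
parameters, the conventions adopted where the published calibration leaves
a functional form open, and what the synthetic fixtures do and do not
demonstrate.

## Overview of the energy model

The free energy of a structure is a sum of empirical terms evaluated on a
typed chain/residue/atom model augmented with *dummy interaction sites*:
protons and acceptor lone-pair ("free orbital") points for hydrogen-bond
geometry, ring and guanidinium centroids for π–π stacking, and ±0.5 e
point charges at helix caps for the macro-dipole. Hydrogens present in
input files are discarded; protons are always rebuilt from ideal covalent
geometry (N–H and lone-pair lengths 1.00 Å). Their directions follow the
donor/acceptor hybridization: single outward protons for amides and ring
NH groups, paired in-plane protons for sp² NH₂ groups, azimuthal cones for
hydroxyls and sp³ amines, paired in-plane lone pairs (plus the axial
direction) for carbonyl and carboxylate oxygens. The published source
never states these placement rules; they are this package's documented
convention, chosen so that canonical secondary-structure hydrogen bonds
score near the optimum of the published angle windows.

## Versioning

Revisions v1…v10 are cumulative deltas on a single parameter file
(`data/parameters.yaml`); `get_params(tag)` resolves a concrete set.

| from | change |
|------|--------|
| v2 | double-salt-bridge hydrogen bonds ×1.5 |
| v3 | charge–helix-dipole term divided by d² (v1/v2 kept the 1/d form) |
| v4 | N-cap multipliers: Ser/Asn ×1.5, Thr ×2 of the 1.32 kcal/mol bond |
| v5 | Met side-chain entropy raised to the Lys value 0.0073667 |
| v6 | π–π stacking term; pH machinery extended to all ionizable residues |
| v7 | −0.2 kcal/mol on all apolar Trp side-chain atoms |
| v8 | three-class hydrogen-bond angle boundary table |
| v9 | aromatic ring-atom volumes ×0.9 in the burial sum |
| v10 | +10 on every minimum buried volume; Pro ring minimums raised |

## Hydrogen bonds

Candidates are donor/acceptor heavy atoms within 3.5 Å (a standard
practice cutoff; not stated in the source). Three angles are measured per
proton/orbital combination and the best-scoring combination is kept:
*freeProtDon* at the proton between proton→orbital and proton→donor,
*protFreeAcc* at the orbital between orbital→proton and orbital→acceptor,
and the donor–proton–orbital–acceptor dihedral. Each of the two bond
angles carries a trapezoidal weight — 1 inside the optimal window, a
linear ramp between the hard and optimal bounds, 0 outside the hard window
(the pair is then not a hydrogen bond). The dihedral weight is 1 at the
class optimum falling linearly to 0 at a deviation equal to the optimum.
The combined weight is the product of the three; only the window semantics
and the "more deviation, more penalty" behaviour are published, so ramp
shape and product combination are package conventions. The neutral base
energy is −1.32 kcal/mol (pinned by the N-cap bonus); the charged
(nitrogen-to-carboxylate) base energy is unpublished and defaults to
−2.0 kcal/mol in the parameter file.

A FRONT double salt bridge requires both Arg NH nitrogens bonded to both
carboxylate oxygens; SIDE is any other network of ≥2 N–O bonds. Both
modes scale the participating bond energies by 1.5 from v2 on.

The N-cap residue is the residue preceding the first helical one; the
bonus requires one of its side-chain oxygens within hydrogen-bond range
of the backbone N three residues into the helix.

## Electrostatics and pH

All charge interactions use a screened Coulomb form
`E = 332.0637 q₁q₂ exp(−d/λ_D) / (ε d^p)` with an effective permittivity
ε = 40 (an empirical choice placing contact salt bridges at ~2 kcal/mol)
and a Debye length λ_D = 3.04/√I Å. Charge–charge terms use p = 1;
charge–dipole terms use p = 2 from v3 (the 1/d variant is retained for
version comparisons). The exact published equation lives in an
unavailable supplement; this form satisfies every constraint the main
text states.

Ionizable groups carry a point charge at the centroid of their terminal
heavy atoms. Intrinsic pKas: His 6.8 and Cys 8.5 (published); the others
(Asp 3.5, Glu 4.2, Tyr 10.3, Lys 10.5, Arg 12.0, N-ter 7.7, C-ter 3.3)
are a substituted standard experimental compilation, shipped editable.
The environment shifts each pKa by ΔG_elec/(2.303RT) computed against the
full formal charges of neighbours within 8 Å — stabilization of the
ionized form lowers acid pKas and raises base pKas. Ionization follows
Henderson–Hasselbalch, and an ionized group buried to fractional
accessibility ς pays `P(1−ς)` with P = 2 kcal/mol by default (the
published cost is "related to solvent accessibility" without a printed
form; linear is the simplest monotone choice). Sites titrate
independently; coupled titration is out of scope.

## π–π stacking

Groups: one centroid per Phe/Tyr/His ring and Arg guanidinium, and a
single nine-atom centroid for Trp (a two-ring mode is intentionally not
default). Pairs beyond 5 Å centroid separation score zero. Pairs
involving His or a guanidinium group additionally require the inter-plane
angle ≤ 30° and are scaled by ϑ = cos²(angle); purely aromatic pairs use
ϑ = 1 (published). The optimum magnitude is 2.5 kcal/mol minus 0.25 per
Phe. The distance factor is 1 up to d_opt = 3.8 Å and Gaussian beyond
(σ = 0.8 Å); only "an exponential correction based on the distance" is
published, so d_opt, σ and the cos² form are package conventions
satisfying the printed constraints.

## Burial, solvation, entropy

Burial of atom *i* is `B_i = Σ_j V_j (1 − d_ij/6 Å)` over neighbours
within 6 Å — the published description names the inputs (neighbours,
their volumes, their distances) but not the kernel; the linear occlusion
kernel is this package's choice. Elemental volumes (C 20, N 15, O 14,
S 24 Å³) are standard van der Waals values. The burial fraction clamps
`(B − min)/(max − min)` to [0, 1] with per-atom minimum/maximum buried
volumes: defaults 150/500, with the published per-atom minimums for Pro
(CB 157, CG 147, CD 170) and aromatic CB 197 / CG 209. From v9 aromatic
ring atoms contribute ×0.9 of their volume; v10 raises Pro CB/CG to 197
and CD to 207 (the published prose on the Pro assignments is ambiguous —
this reading keeps CD ten units above CB — and the alternative readings
can be expressed by editing the parameter file), then adds 10 to every
minimum.

Solvation is linear in the buried fraction with per-atom-class
hydrophobic/polar constants. The original per-atom table is unpublished;
the shipped class values are chosen so that full-burial side-chain sums
rank-correlate strongly with water→octanol transfer hydrophobicity, which
the test suite checks against an independent scale. The v7 change is
exact: −0.2 kcal/mol added to every apolar Trp side-chain atom, ring NH
excluded.

Side-chain conformational entropy costs `T·ΔS·burial` with a per-residue
ΔS table anchored at the published values (Met 0.0051 → 0.0073667,
Gln 0.0067333, Glu 0.0055, Arg 0.0071, Lys 0.0073667); the remaining
residues are interpolated by rotatable-bond count and respect the
published ordering argument (Met above Gln from v5).

## Mutation engine

Mutation is rigid-backbone by construction: backbone atoms are copied
bit-identically, the target side chain is rebuilt from ideal internal
coordinates, and its χ angles are optimized by a greedy, seeded grid
search (30° steps, χ by χ, random scan order as the tie-break) scoring
soft-repulsion clashes plus a small polar-contact reward. Side chains
with atoms within 6 Å of the mutated residue are re-optimized by the same
search. The reference wild type is rebuilt by the identical procedure
(a self-mutation), so a self-mutation ΔΔG is exactly zero and the
mutant/reference pair shares its seed. `numberOfRuns`-style replication
evaluates n seeded pairs and aggregates by mean or median. `repair`
applies the same search to every residue, accepting only total-energy
improvements. The true engine this emulates uses an unpublished move set;
the χ-grid search is the package's largest acknowledged divergence from
it, adequate for the fixture scale exercised here.

The clash term is `0.02·((3.2/d)¹² − 1)` per non-bonded heavy-atom pair
closer than 3.2 Å, capped at 100 kcal/mol per pair, which places
structurally impossible substitutions well above the 5 kcal/mol curation
threshold.

## Curation and evaluation

Curation removes, in documented order: multi-site mutants, non-X-ray
structures, resolution worse than 2.5 Å, metal/cofactor contacts, reverse
mutations, and clash energies above the threshold (default 5 kcal/mol;
a 6 kcal/mol variant is selectable since both values appear in the
published description). Duplicate measurements merge toward 25 °C and
average. The retained set is independent of rule order; only the per-rule
attribution changes, and the pipeline is idempotent.

Benchmark statistics: Pearson R, slope and intercept of experimental ΔΔG
regressed on predicted (the reported-table convention; the orientation is
switchable since the prose does not fix the axes), RMSE of raw
predictions, a two-sided Wilcoxon signed-rank test on paired absolute
errors (exact null for n ≤ 25, continuity-corrected normal above — the
paired quantity is a package choice, as the source does not name it), the
accuracy-vs-error curve, and the ROC AUC for sign classification.

## Synthetic fixtures — what they show and don't

The generators produce ideal geometry: exact ring separations and
inter-plane angles, ideal α-helices (φ = −57°, ψ = −47°) with the cap
residue in the canonical extended N-cap conformation, a coplanar FRONT
salt bridge, a five-helix bundle for burial-dependent terms, and
benchmark tables with known generating parameters (latent predictions
~N(1.0, 1.5²) kcal/mol, experimental values slope·pred + intercept +
Gaussian noise, so the regression recovers the generating line exactly at
zero noise and the noise level for any target population R is available
in closed form). Helix detection falls back to the geometric criterion
O(i)···N(i+4) ≤ 3.5 Å with runs of ≥4 marked residues forming a helix.

Passing tests on these fixtures demonstrates that the terms implement
their stated functional forms, gates and version deltas, and that the
statistics agree with independent oracles. They do not demonstrate
predictive accuracy on real mutant datasets: that requires hundreds of
experimental structures and the unpublished remainder of the original
parameterization, both outside this package's scope. For the same reason
the published dataset-level correlations are not reproduction targets
here.

## Numerical choices

Angle and plane computations use SVD plane fits (degenerate inputs raise)
and the atan2 dihedral convention with the positive sign for clockwise
rotation viewed along the bond. Problem sizes in the tests and the
acceptance script are deliberately small — peptides of 10 residues,
bundles of 5 helices, benchmark tables of ≤2000 rows — which keeps every
check well under a minute while exercising each term end to end. All
randomness flows through explicit integer seeds (`numpy` Generators);
equal seeds give bit-identical results.

## Known limitations

- Side-chain placement explores a χ grid without a rotamer library or
  backbone relaxation; strained or tightly coupled repacking problems are
  out of reach.
- Electrostatics is pairwise-screened Coulomb, not Poisson–Boltzmann, and
  titratable sites do not couple.
- Solvation/volume constants are substituted standard values: relative,
  version-to-version behaviour is faithful, absolute per-residue
  desolvation energies are approximate.
- mmCIF input, ligands, metals, waters, nucleic acids and binding ΔΔG
  are unsupported.
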