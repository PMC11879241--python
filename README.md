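# ddgforge

An open, versioned empirical force field for protein stability: per-term
free-energy evaluation on protein structures, a rigid-backbone
mutate-and-score ΔΔG engine, curation filters for experimental mutant
tables, and the benchmark statistics used to judge stability predictors.

## Who this is for

Structural bioinformaticians and protein engineers who want a transparent,
scriptable implementation of the classic empirical-force-field approach to
predicting the change in unfolding free energy upon point mutation
(ΔΔG, kcal/mol, destabilizing positive), and a harness for calibrating and
benchmarking such predictors against curated experimental datasets.

## The model

The total free energy of a structure is a sum of physically motivated
empirical terms:

- **Hydrogen bonds** — donor–acceptor pairs are accepted and weighted by
  three angles measured on proton and acceptor lone-pair dummy sites
  (*freeProtDon*, *protFreeAcc*, *dihed*), with per-class boundary tables
  (backbone–backbone, backbone–side-chain, side-chain–side-chain).
  Delocalized Arg–carboxylate double salt bridges (FRONT/SIDE patterns)
  carry a 1.5× bonus; a Ser/Thr/Asn/Asp N-cap hydrogen-bonding the
  (Ncap+3) backbone amide contributes −1.32 kcal/mol scaled ×1.5
  (Ser/Asn) or ×2 (Thr).
- **Electrostatics** — screened Coulomb interactions between ionized
  groups, helix macro-dipoles modeled as ±0.5 e dummy charges at the
  helix caps (charge–dipole term ∝ 1/d²), environment-corrected pKas,
  Henderson–Hasselbalch ionization at the working pH, and an
  accessibility-scaled ionization penalty.
- **π–π stacking** — ring/guanidinium centroid dummies with a 5 Å
  distance gate; His and Arg-guanidinium pairs additionally require the
  planes within 30° of coplanar. Optimal magnitude E_opt = 2.5 kcal/mol,
  reduced by 0.25 per Phe in the pair.
- **Solvation and entropy** — per-atom occluded-volume burial mapped to a
  0–1 fraction through minimum/maximum buried volumes (aromatic ring
  atoms count ×0.9; v10 raises every minimum by 10), linear per-atom
  desolvation energies (Trp apolar atoms −0.2 kcal/mol from v7), and a
  burial-scaled side-chain conformational entropy (Met raised to the Lys
  value 0.0073667 from v5).
- **Clashes** — a soft Lennard-Jones-like repulsion that also feeds the
  curation filter for structurally impossible mutants.

Force-field revisions v1…v10 are expressed as cumulative deltas over a
single shipped parameter file; `--ff-version` (or
`ddgforge.get_params("v8")`) selects any stage. Mutations replace a side
chain with idealized geometry via a seeded χ-grid search, re-optimize
side chains within 6 Å and never move the backbone; ΔΔG can be aggregated
over repeated runs (mean or median of 5 is the recommended mode).

## Worked example

```python
import ddgforge as dg

s = dg.make_helix_peptide(10, ncap_aa="SER")       # ideal capped helix
params = dg.get_params("v10")
report = dg.total_energy(s, dg.PHContext(ph=7.0), params)
print({k: round(v, 3) for k, v in report.terms.items()})
print("total:", round(report.total, 3))

value = dg.ddg(s, dg.Mutation("A", 6, "ALA", "TRP"),
               n_runs=5, aggregate="median", seed=1, params=params)
print("ddG(A6W):", round(value, 3), "kcal/mol")
```

prints

```
{'hbond': -9.258, 'electrostatics': 0.0, 'helix_dipole': 0.13,
 'ncap': -1.98, 'pipi': 0.0, 'solvation': 0.339, 'entropy': 0.0,
 'clash': 0.061}
total: -10.708
ddG(A6W): 0.009 kcal/mol
```

The H-bond term collects the six helical backbone i→i+4 bonds, the Ncap
term is the Ser capping bonus −1.32 × 1.5 = −1.98 kcal/mol, and the helix
dipole term is the (unfavourable, here) interaction of the cap charges
with the peptide's ionizable groups. The Ala→Trp ΔΔG on this fully
exposed model helix is near zero: a surface substitution neither packs
nor clashes.

The same operations are exposed as a CLI:

```
ddgforge fixtures --kind helix --ncap SER --out helix.pdb
ddgforge stability --pdb helix.pdb --ff-version v10
ddgforge ddg --pdb helix.pdb --mut A:A6W --runs 5 --aggregate median --seed 1
ddgforge curate --table mutants.tsv --out curated.tsv --report report.json
ddgforge evaluate --pred pred.tsv --exp exp.tsv
```

## Layout

```
src/ddgforge/
  structure.py       typed model, PDB I/O, dummy sites, geometry kernels
  residues.py        amino-acid chemistry tables, side-chain construction
  params.py          versioned parameter resolution (v1..v10)
  data/parameters.yaml
  hbond.py           detection, Table-of-boundaries weighting, special cases
  electrostatics.py  Coulomb terms, pKa machinery, pH dependence
  pipi.py            stacking term
  solvation.py       burial model, solvation, side-chain entropy
  engine.py          total energy, mutate, repair, ddG
  curation.py        mutant-table filters
  evaluation.py      benchmark statistics
  fixtures.py        synthetic structures and benchmark tables
  cli.py             command-line interface
```

See `docs/methods.md` for the modelling choices, parameter provenance and
known limitations.
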