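# Versioned force-field parameter sets.
#
# The base (v1) values and every later delta live here; ddgforge.params
# resolves a concrete parameter set for a requested version tag.
# Values printed in the published calibration are used verbatim; tables the
# publication keeps in unpublished supplements (atomic volumes, solvation
# constants, intrinsic pKas other than His/Cys) are SUBSTITUTED with standard
# literature defaults and are editable here.

versions: [v1, v2, v3, v4, v2-4, v5, v6, v7, v8, v9, v10]

hbond:
  # base energy of a fully optimal neutral H-bond (kcal/mol); the Ncap
  # discussion pins the neutral value at 1.32
  neutral_energy: -1.32
  charged_energy: -2.0
  donor_acceptor_cutoff: 3.5     # heavy-atom D...A candidacy cutoff, Angstrom
  salt_bridge_factor: 1.5        # delocalized Arg-carboxylate double bridge, v2+
  ncap_base: 1.32                # kcal/mol, magnitude of the Ncap H-bond
  ncap_multipliers:              # v4+; v1 uses 1.0 for all
    SER: 1.5
    ASN: 1.5
    THR: 2.0
    ASP: 1.0
  geometry:
    # angle boundaries in degrees, per interaction class
    v1:
      ALL-ALL:
        maxFreeProtDon: 180
        minFreeProtDon: 115
        optMaxFreeProtDon: 160
        optMinFreeProtDon: 145
        maxProtFreeAcc: 155
        minProtFreeAcc: 80
        optMaxProtFreeAcc: 110
        optMinProtFreeAcc: 90
        optDihed: 130
    v8:
      BB-BB:
        maxFreeProtDon: 180
        minFreeProtDon: 115
        optMaxFreeProtDon: 170
        optMinFreeProtDon: 145
        maxProtFreeAcc: 135
        minProtFreeAcc: 75
        optMaxProtFreeAcc: 115
        optMinProtFreeAcc: 90
        optDihed: 145
      BB-SC:
        maxFreeProtDon: 180
        minFreeProtDon: 90
        optMaxFreeProtDon: 170
        optMinFreeProtDon: 120
        maxProtFreeAcc: 180
        minProtFreeAcc: 70
        optMaxProtFreeAcc: 145
        optMinProtFreeAcc: 90
        optDihed: 160
      SC-SC:
        maxFreeProtDon: 180
        minFreeProtDon: 90
        optMaxFreeProtDon: 170
        optMinFreeProtDon: 115
        maxProtFreeAcc: 180
        minProtFreeAcc: 70
        optMaxProtFreeAcc: 160
        optMinProtFreeAcc: 90
        optDihed: 170

electrostatics:
  coulomb_constant: 332.0637     # kcal*Angstrom/(mol*e^2)
  dielectric: 40.0               # effective relative permittivity
  debye_factor: 3.04             # Debye length = debye_factor/sqrt(I) Angstrom
  dipole_charge: 0.5             # helix-cap dummy charge magnitude, e
  pka_neighbour_cutoff: 8.0      # Angstrom, environment correction
  ionization_penalty: 2.0        # P in cost = P*(1-sigma), kcal/mol
  # Intrinsic pKas. His and Cys are the published fixed values; the rest are
  # a SUBSTITUTED standard experimental compilation (editable).
  intrinsic_pka:
    ASP: 3.5
    GLU: 4.2
    HIS: 6.8
    CYS: 8.5
    TYR: 10.3
    LYS: 10.5
    ARG: 12.0
    NTER: 7.7
    CTER: 3.3

pipi:
  e_opt: 2.5                     # kcal/mol optimum stacking magnitude
  phe_penalty: 0.25              # per Phe in the pair (0.5 when both are Phe)
  distance_cutoff: 5.0           # Angstrom, centroid-centroid hard gate
  angle_cutoff: 30.0             # degrees, His/guanidinium pairs only
  d_opt: 3.8                     # Angstrom, distance of maximal interaction
  sigma: 0.8                     # Angstrom, width of the distance fall-off

solvation:
  # Per-atom-class desolvation energies, kcal/mol at full burial.
  # SUBSTITUTED standard values (unpublished originals not reproducible);
  # chosen so side-chain sums track water->octanol transfer hydrophobicity.
  classes:
    apolar_C:   {hydrophobic: -0.50, polar: 0.00}
    aromatic_C: {hydrophobic: -0.45, polar: 0.00}
    polar_O:    {hydrophobic: 0.00, polar: 0.75}
    polar_N:    {hydrophobic: 0.00, polar: 0.60}
    charged_O:  {hydrophobic: 0.00, polar: 1.10}
    charged_N:  {hydrophobic: 0.00, polar: 1.00}
    sulfur:     {hydrophobic: -0.40, polar: 0.00}
    backbone_C: {hydrophobic: -0.20, polar: 0.00}
    backbone_N: {hydrophobic: 0.00, polar: 0.40}
    backbone_O: {hydrophobic: 0.00, polar: 0.40}
  trp_apolar_shift: -0.2         # v7+: added to every apolar Trp side-chain atom

volumes:
  # atomic volumes by element, Angstrom^3 (standard van der Waals volumes)
  element_volume: {C: 20.0, N: 15.0, O: 14.0, S: 24.0}
  ring_volume_factor: 0.9        # v9+: multiplies ring-atom volumes
  occlusion_cutoff: 6.0          # Angstrom, neighbour kernel range
  min_buried_default: 150.0      # Angstrom^3
  max_buried_default: 500.0      # Angstrom^3
  # published per-atom minimum buried volumes (pre-v10 baseline)
  min_buried_overrides:
    PRO: {CB: 157.0, CG: 147.0, CD: 170.0}
    PHE: {CB: 197.0, CG: 209.0}
    HIS: {CB: 197.0, CG: 209.0}
    TYR: {CB: 197.0, CG: 209.0}
  # v10: proline ring minimums raised to the aromatic values (CD keeps the
  # 10 units above CB), then +10 added to every atom's minimum
  v10_pro_overrides:
    PRO: {CB: 197.0, CG: 197.0, CD: 207.0}
  v10_min_buried_increment: 10.0

entropy:
  # Side-chain conformational entropy scale (Abagyan-style), paid on burial;
  # cost = T * dS * burial, kcal/mol with T in Kelvin.
  table:
    GLY: 0.0
    ALA: 0.0
    PRO: 0.0
    SER: 0.0019
    CYS: 0.0019
    THR: 0.0019
    VAL: 0.0015
    LEU: 0.0032
    ILE: 0.0032
    ASP: 0.0036
    ASN: 0.0036
    HIS: 0.0033
    PHE: 0.0033
    TYR: 0.0036
    TRP: 0.0033
    MET: 0.0051       # v1..v4; v5+ replaces with the Lys value
    GLN: 0.0067333
    GLU: 0.0055
    ARG: 0.0071
    LYS: 0.0073667
  met_v5: 0.0073667

clash:
  r0: 3.2                        # Angstrom, soft-repulsion onset
  scale: 0.02                    # kcal/mol prefactor
  pair_cap: 100.0                # kcal/mol cap per atom pair
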