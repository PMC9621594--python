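# Default force-field parameter set (version 1).
#
# Geometric equilibria (bonds A, angles/dihedrals degrees) are measured from
# the package's ideal B-form CG template (P at phosphate, C at C4', N at
# N1/N9; rise 3.38 A, twist 36 deg, paired N-N 8.9 A).  Stacking strengths
# combine experimental nearest-neighbour dimer thermodynamics with a
# conformational-entropy correction ds_c estimated once by Monte Carlo
# sampling of a free dinucleotide (see forcefield.estimate_stack_entropy).
# The base-pairing strength eps_bp is calibrated against experimental
# melting temperatures of the standard four calibration systems.
version: 1
bead_radii: {P: 1.9, C: 1.7, N: 2.2}

bonded:
  equilibrium:          # bonds in Angstrom, angles/dihedrals in degrees
    PC: 3.900
    CP: 3.700
    CN: 3.400
    PCP: 116.2843
    CPC: 95.7259
    NCP5: 132.3264
    NCP3: 99.2865
    PCPC: 149.2671
    CPCP: -175.0071
    NCPC: 1.9437
  strength_helical:     # kcal/mol/A^2, kcal/mol/rad^2, kcal/mol
    bond: 20.0
    angle: 3.0
    dihedral: 0.6
  nonhelical_factor: 0.5

excluded_volume:
  epsilon: 0.3          # kcal/mol
  cap: 1000.0           # kcal/mol, coincident-bead cap

pairing:
  eps_bp: 4.1           # kcal/mol; calibrated (run_calibrate protocol)
  r0_nn: 8.900          # optimum paired N-N distance, A
  d0_cross: 11.883      # optimum C-N / N-C cross distances, A
  alpha_r: 1.2          # 1/A^2, Gaussian width of the N-N factor
  alpha_d: 0.3         # 1/A^2, Gaussian width of the orientation factors
  window: 3.0           # A, hard window about r0_nn outside which no pair
  min_loop: 3           # minimum intra-strand loop length (residues)
  detect_fraction: 0.5  # pair detected when E < -detect_fraction * eps_bp

stacking:
  sigma_st: 4.497       # optimum neighbour N-N distance, A (template)
  cutoff: 9.0           # A
  ds_c: -4.4            # cal/mol/K per stack; MC estimate, frozen

# Unified nearest-neighbour dimer thermodynamics (dH kcal/mol, dS cal/mol/K),
# keys are 5'->3' top-strand steps; the 6 missing WC steps follow by
# reverse-complement symmetry.
thermo_table:
  AA: [-7.9, -22.2]
  AT: [-7.2, -20.4]
  TA: [-7.2, -21.3]
  CA: [-8.5, -22.7]
  GT: [-8.4, -22.4]
  CT: [-7.8, -21.0]
  GA: [-8.2, -22.2]
  CG: [-10.6, -27.2]
  GC: [-9.8, -24.4]
  GG: [-8.0, -19.9]

electrostatics:
  b_charge_spacing: 4.4   # A, per-strand contour charge spacing (Manning)
  mg_competition: 20.0    # dimensionless Mg2+/Na+ competition weight
  exclude_bonded: false   # include all distinct P-P pairs
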