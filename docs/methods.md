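# Methods

## Model

Each deoxynucleotide is reduced to three beads placed on real atom
positions: P (phosphate phosphorus, radius 1.9 Å, charge −e), C (sugar
C4', 1.7 Å) and N (glycosidic nitrogen N1 for C/T or N9 for A/G, 2.2 Å).
The potential has eight terms,

U = U_b + U_a + U_d + U_exc + U_bp + U_bs + U_cs + U_el,

- **Bonded** (`U_b`, `U_a`, `U_d`): harmonic virtual bonds (P–C, C–P,
  C–N) and angles (PCP, CPC, N–C–P), periodic dihedrals
  (k[1−cos(φ−φ₀)]; PCPC, CPCP, NCPC).  Equilibrium values are measured
  from the package's ideal B-form CG template (rise 3.38 Å, twist 36°,
  paired N–N 8.9 Å).  Two regimes share these equilibria:
  **Para_helical** (full strength) is applied to consecutively paired
  residues during refinement, **Para_nonhelical** (half strength) to
  everything else, including the whole chain while folding.
- **Excluded volume** (`U_exc`): purely repulsive truncated
  Lennard-Jones, zero at and beyond the sum of bead radii, capped at
  10³ kcal/mol for coincident beads.
- **Base pairing** (`U_bp`): Watson–Crick only (G–C, A–T).  A candidate
  pair scores −ε_bp·exp[−α_r(r−r₀)² − α_d((d₁−d₀)² + (d₂−d₀)²)], where
  r is the N–N distance (r₀ = 8.9 Å) and d₁, d₂ are the two C–N cross
  distances (d₀ = 11.88 Å) that encode the antiparallel pairing
  orientation; candidates outside a ±3 Å window on r score zero.  A
  best-energy greedy matching enforces one partner per base.
  Intra-strand partners must be ≥4 residues apart (minimum loop 3 nt).
- **Base stacking** (`U_bs`): for neighbouring pairs (i·j, i+1·j−1),
  ½|G|·{[5(σ/r)¹²−6(σ/r)¹⁰] + …} over the two strand-side N–N gaps
  (σ_st = 4.497 Å, the template rise distance), with the
  sequence-dependent strength G(T) = ΔH − T(ΔS − ΔS_c) built from the
  unified nearest-neighbour dimer table.  ΔS_c is the share of the
  experimental stacking entropy that the explicit chain degrees of
  freedom already pay in the simulation; it is estimated once by
  Metropolis sampling of a free dinucleotide (probability of visiting
  the stacking well, ΔS_c = R ln p ≈ −4.4 cal/mol/K) and frozen in the
  parameter file.
- **Coaxial stacking** (`U_cs`): the same functional form applied across
  the interfaced terminal pairs of two distinct helices.  An interface
  whose two stack contacts are both sequence-adjacent is intra-helix
  territory and excluded, and each helix end joins at most one
  interface — without these rules, mis-registered "ladders" of isolated
  pairs harvest spurious coaxial energy and become a dominant trap.
- **Electrostatics** (`U_el`): screened Coulomb repulsion between P
  beads, (Qe)²·e^(−r/l_D)/(4πε₀ε(T)r), truncated beyond 10 Debye
  lengths.  ε(T) is the temperature-dependent water dielectric; the
  Debye length uses the charge-weighted ionic strength I = [Na⁺] +
  3[Mg²⁺]; the reduced charge Q follows Manning condensation
  (Q = b/l_B, contour spacing b = 4.4 Å) with an empirical Mg²⁺
  competition factor interpolating to the divalent plateau b/(2l_B).

## Sampling

Metropolis Monte Carlo with pivot moves (rotate a contiguous chain
segment about a random axis through a random backbone bead) and, for
two-chain systems, rigid whole-chain translations inside a cubic box
whose side (2/(N_A·c_s))^(1/3) encodes the strand concentration
(149 Å at 1 mM); moves that leave the box are rejected (reflecting
walls).  Bond lengths are set exactly at their equilibrium values when
chains are generated and are invariant under both move types, so the
bonded bond term carries no fluctuation — the sampled degrees of freedom
are angles, dihedrals and rigid-body placement.  A sweep is one
attempted move per bead.  Move amplitudes adapt toward 30–50% acceptance
during the first 10% of each temperature block and are then frozen.

Folding anneals from 120 °C to the target temperature (5 °C default
ladder) under Para_nonhelical; the final conformation is the structure
prediction.  Refinement continues at the target temperature with
Para_helical on residues paired in the majority pairing of the trailing
annealing frames, and returns the sampled ensemble for mean/minimum
CG-RMSD statistics (Kabsch superposition over beads matched by strand,
residue and kind).

## Melting temperatures

Frames at each ladder temperature (second half of each block) are
classified against the lowest-temperature prediction: folded (≥80% of
reference pairs), unfolded (≤1 pair), else intermediate.  The denatured
base-pair fraction f(T) is fitted to the two-state logistic
(f = 1 − f_F, midpoint Tm) or, when the intermediate-state fraction
peaks above 0.2, to the two-transition combination with plateau f_I
(midpoints Tm1 < Tm2), weighted by binomial standard errors.  Duplex
melting simulated at a high strand concentration c_s^h maps to the
experimental concentration through the dilution transform
f → λf/(1+(λ−1)f) and Tm(c_s) = Tm(c_s^h) − dT₁ ln λ, λ = c_s^h/c_s.

Single cooling runs show pronounced hysteresis — near Tm a block
typically contains at most one folding/unfolding transition, so a single
replica yields an almost binary melting curve.  `run_melt` therefore
(i) pools the state fractions of several independent cooling replicas,
(ii) heats fresh replicas from the best predicted fold back up the
ladder and pools those too, and (iii) reports Tm as the mean of the two
branches' half-denaturation points, each located as the 0.5 crossing of
the isotonic regression of f(T) (a robust median-type statistic; the
logistic fit then supplies the width dT).  f(T) itself is the
pair-count fraction relative to the reference structure — the
register-agnostic analogue of experimental hypochromicity — and an
intermediate (f_I > 0, two transitions) is entertained only when the
reference fold contains at least two helices, since simple hairpins and
short duplexes are two-state.

## Parameters and calibration

All force-field constants live in a versioned, checksummed YAML file
(`cgdnafold/parameters/default.yaml`).  Geometric values (bonded
equilibria, σ_st, pairing distances) are measured from the B-form
template.  Values that the geometry does not fix were set as follows,
in this order, and then frozen:

1. **Bonded strengths.**  Helical bond 20 kcal/mol/Å² (irrelevant to
   sampling, see above), angle 3.0 kcal/mol/rad², dihedral 0.6 kcal/mol
   (nonhelical = half).  Stiffer chains (angle ≥5) bury so much of the
   folding entropy in the bonded pre-organisation that hairpins stop
   melting below 120 °C and the loop-length dependence of hairpin
   stability almost vanishes; the soft set reproduces the qualitative
   melting regime of the GCGC(T)_N hairpin series.
2. **Pairing widths.**  α_r = 1.2 Å⁻², α_d = 0.3 Å⁻²: tight enough to
   hold B-form register in refined stems, loose enough that folding
   still finds the pairing wells at desk-scale sweep counts.
3. **ΔS_c** from the dinucleotide estimator under (1): −4.4 cal/mol/K.
4. **ε_bp** by the calibration protocol (grid search minimising the Tm
   error of the standard calibration systems, chiefly the 13-nt hairpin
   GCGC(T)₅GCGC at 1 M Na⁺) under the frozen desk-scale melting
   protocol below.

The desk-scale melting protocol used by the acceptance script and tests
is 4 independent replicas, 6·10³ sweeps per 6 °C ladder step from 120 °C
to 30 °C, with both cooling and heating branches (the library default
for production-quality runs is 2·10⁵ sweeps per 5 °C step, scaled
linearly with length beyond 30 nt).  Because cooling undercools and
heating overheats the transition when sampling is short, the reported
Tm averages the two branch crossings; calibrating ε_bp under the same
protocol keeps the predictions internally consistent.

## What the synthetic fixtures do and do not show

The ideal B-form duplex/hairpin builders provide strain-free reference
geometries used to verify energy-term optima, pair detection and RMSD
plumbing, and they stand in for experimental natives in the structure
pipeline test (crystal-structure references are not bundled).  They
reproduce the template geometry exactly but say nothing about real
sequence-dependent fine structure, loop conformations or crystal-packing
effects.

## Known limitations

- No stacking between unpaired bases, no noncanonical pairs, no
  triplex/quadruplex/junction support; loop-sequence effects on
  stability are invisible to the model.
- The soft bonded set that makes desk-scale melting tractable leaves
  refined stems much floppier than B-DNA: equilibrium ensembles of a
  13-nt hairpin spread 5–7 Å (CG-RMSD) about their centroid, so
  crystal-structure-level ensemble RMSDs (~3 Å) are not reached at this
  sampling scale.
- Apparent melting temperatures carry replica-median statistics; with
  8 replicas the seed-to-seed standard error is a few °C, and the
  17-nt, 9-T-loop hairpin is systematically the least stable relative
  to the reference data.
- The dilution transform slightly broadens curves inferred from high
  strand concentration; this is inherent to the transform and is
  reproduced, not corrected.
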