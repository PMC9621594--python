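# cgdnafold

Three-bead coarse-grained DNA folding: 3D structure prediction and
melting thermodynamics for single- and double-stranded DNA from
sequence, in explicit Na⁺/Mg²⁺ ionic conditions.

Short DNAs — duplexes, hairpins, pseudoknots — are the building blocks
of both genomic regulation and DNA nanotechnology, and their stability
is exquisitely sensitive to sequence, strand concentration and salt.
`cgdnafold` represents each nucleotide by three beads on real atom
positions (phosphate P, sugar C4', glycosidic N1/N9), folds chains by
Metropolis Monte Carlo simulated annealing from 120 °C to the target
temperature, and computes melting curves from the sampled ensembles.

The energy function has eight terms

```
U = U_b + U_a + U_d + U_exc + U_bp + U_bs + U_cs + U_el
```

bonded geometry (two parameter regimes: Para_nonhelical for folding,
Para_helical for refined stems), excluded volume, orientation-dependent
Watson–Crick pairing, sequence-dependent base stacking with strength
G(T) = ΔH − T(ΔS − ΔS_c) from nearest-neighbour dimer thermodynamics,
coaxial stacking between discontiguous helices, and a Debye–Hückel
screened Coulomb repulsion between phosphates with a Manning-reduced
charge Q([Na⁺], [Mg²⁺], T).  Melting follows the two-state model
f_F(T) = 1/(1+e^{(T−Tm)/dT}); duplex predictions at low strand
concentration use the dilution transform Tm(c_s) = Tm(c_s^h) − dT·ln λ.
See `docs/methods.md` for the full model description.

## Worked example

Predict the melting temperature of the 13-nt hairpin GCGC(T)₅GCGC in
1 M Na⁺ (experimental value 76.4 °C):

```python
from cgdnafold.cli import RunConfig, run_melt

cfg = RunConfig(mode="melt", sequences=["GCGCTTTTTGCGC"], na_molar=1.0,
                t_start=120.0, t_target=30.0, t_step=6.0,
                sweeps_per_t=6000, replicas=4, thin=40, seed=17)
fit, report = run_melt(cfg)
print(f"Tm = {report['tm']:.1f} C, transition width dT = {fit.dt1:.1f} C")
```

```
Tm = 82.9 C, transition width dT = 19.9 C
```

Four independent annealing replicas are cooled over a 120→30 °C ladder
and heated back from the predicted fold; at each temperature the
sampled conformations are classified against the lowest-temperature
structure, and `Tm` is the half-denaturation point of the two
hysteresis branches averaged (here 82.9 °C against a measured 76.4 °C —
at this reduced sampling the seed-to-seed spread is about ±4 °C, and
the transition is broader than experiment).  The same interface folds
structures (`mode="fold"`, writing CG-PDB files viewable in PyMOL) and
the console script exposes it all as

```bash
cgdnafold melt GCGCTTTTTGCGC --na 1.0 --seed 17
cgdnafold fold GCGCTTTGCGC --na 0.1 --t-target 25 --out run1/
cgdnafold rmsd run1/predicted.pdb native.pdb
cgdnafold calibrate --grid 4.0:5.0:0.25
```

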