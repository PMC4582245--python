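# ssbwrap

Analysis of single-molecule optical-tweezers experiments on the *E. coli*
single-stranded DNA binding protein (SSB) wrapping a (dT)₇₀ site: from raw
extension-change traces to discrete wrapping states, a force-tilted
free-energy landscape with barriers, RecA-displacement intermediates, and
reptation diffusion constants.

It is written for single-molecule biophysicists who record constant-force
or force-ramp traces of a protein–ssDNA tether and want a reproducible,
tested route from trace to landscape. Because raw instrument traces for
this system are not publicly deposited, the package ships a first-class
synthetic-data generator that emulates the experiment (Gillespie state
hopping with Bell–Evans kinetics, 66 kHz Gaussian noise, 65 nm/s ramps
with 0.3 pN/nm traps, reptation-FRET photon counts, stepwise RecA
displacement), so every estimator can be validated against ground truth.

## The model

A dsDNA/ssDNA tether has bare extension (XWLC for dsDNA, a calibrated
snake-like-chain law for ssDNA)

    x_bare(F) = ξ_ds(F)·N_ds + ξ_ss(F)·N_ss .

An SSB wrapping N_w nucleotides removes them from the tether and adds the
orientation-averaged size of the complex,

    x_wrap(F) = ξ_ds(F)·N_ds + ξ_ss(F)·(N_ss − N_w) + x_SSB·L(F·x_SSB/kBT),

with `L(z) = coth z − 1/z` the Langevin factor. The measured compaction
Δx(F) = x_bare − x_wrap inverts exactly to

    N_w = (Δx + x_SSB·coth(F·x_SSB/kBT) − kBT/F) / ξ_ss(F),

a one-parameter curve in (N_w, x_SSB) that structure-derived constraints
(protein size, end-to-end scan of the crystallographic wrapping path,
hotspot contact groups at Trp-54/His-55/Arg-56) narrow to the four binding
modes (SSB)₆₅, (SSB)₅₆, (SSB)₃₅ and (SSB)₁₇.

State occupancies give free energies through Boltzmann ratios corrected
for the stretching term, `p_i/p_j = exp(−(ΔG_ij + ΔG_stretch)/kBT)`, and
dwell times give Bell–Evans rates
`k_{i→j}(F) = k₀·exp(−(ΔG‡ + ∫₀^F Δx‡ dF′)/kBT)` along the single
nearest-neighbour pathway 0 ⇄ 17 ⇄ 35 ⇄ 56 ⇄ 65, fitted globally for the
three resolvable barriers.

## Worked example

```python
import numpy as np, pandas as pd
from ssbwrap import EnergyLandscape, WrappingLandscapeModel
from ssbwrap.simulate import sample_state_occupancy

truth = EnergyLandscape.reference()   # EcoSSB/(dT)70 reference landscape
rows = []
for force, seed in zip((3.0, 5.0, 7.0, 9.0), (1, 2, 3, 4)):
    rng = np.random.default_rng(seed)
    for state, count in sample_state_occupancy(truth, force, 10_000, rng).items():
        rows.append((force, state, count))
occ = pd.DataFrame(rows, columns=["force_pN", "state", "count"])

res = WrappingLandscapeModel(occ).fit(fit_barrier_pairs=())
print(res.summary())
print(f"F_1/2 = {res.half_unwrapping_force():.1f} pN, "
      f"G_wrap = {res.wrap_free_energy():.1f} kBT")
```

prints

```
Wrapping energy-landscape fit
==============================================
  state (nt)    G (kBT)       SE
           0       0.00     0.00
          17      -6.76     0.02
          35     -15.20     0.17
          56     -20.20     0.17
          65     -21.02     0.20
==============================================
F_1/2 = 10.7 pN, G_wrap = 20.7 kBT
```

The chained occupancy estimator recovers the generating state energies
(e.g. the 35-nt state at −15.20 ± 0.17 kBT against the −15.38 kBT
input); the half-unwrapping force of ~10.7 pN falls in the measured
dissociation range, and the area-based wrapping free energy of ~21 kBT
matches the depth of the fully wrapped state.

The same objects drive the command-line pipeline:

```
ssbwrap simulate --seed 1 --force 5 --output run/
ssbwrap segment --input run/trace.tsv --output run/
ssbwrap invert --level 1 --force 4 --dx 14 --structure fixture
ssbwrap diffusion --input run/truth.json
```

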