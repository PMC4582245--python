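# Methods

This note records the models implemented in `ssbwrap`, their assumptions,
the defaults that matter, and the places where a design choice was
genuinely open. Units throughout: force in pN, length in nm, energy in
pN·nm or kBT (stated per quantity); thermal energy defaults to
kBT = 4.09 pN·nm (23 °C).

## Polymer elasticity

**dsDNA (XWLC).** The 3260-bp handles follow the Marko–Siggia
interpolation with an enthalpic stretch term: the entropic fraction ℓ
solves `F·P/kBT = 1/(4(1−ℓ)²) − 1/4 + ℓ` by bracketed root finding
(Brent, xtol 1e-13), and the extension per base pair is
`c·(ℓ + F/K)` with persistence length P = 53 nm, stretch modulus
K = 1200 pN and contour c = 0.338 nm/bp. For integral evaluations a
memoized 0.01 pN grid with trapezoid cumulative sums is used; the exact
solver and the grid agree to < 1e-6 nm/bp.

**ssDNA (snake-like-chain style law).** The published snake-like-chain
parameterization is tabulated in its original reference against salt
concentration and is not reproduced here; we implement a calibrated
stand-in with the same qualitative shape: a low-force power regime
`ξ(F) = ξ_c (F/F_c)^γ` crossing C¹-continuously at F_c = 5 pN into
logarithmic growth `ξ(F) = a + b ln F`. The two free constants of the log
regime are fixed exactly by the calibration anchors 0.5 nm/nt at 20 pN
(35 nm for 70 nt) and 0.334 nm/nt at 5 pN; γ follows from slope
continuity. The law then passes the independent RecA consistency check —
`(1.5 ξ_ds − ξ_ss)·70 ≈ 10 nm` at 5 pN — without further adjustment, and
gives ξ_ss(0.8 pN) ≈ 0.17 nm/nt, consistent with the low-force worked
inversion. Outside 0.1–30 pN evaluations carry a `CalibrationWarning`;
internal tilt integrals extrapolate the smooth power regime to 0 silently.

**Sign convention.** The extension change on wrapping is
compaction-positive (`Δx = x_bare − x_wrap`). Display layers may negate
it to match the instrument's bare-referenced traces.

The degenerate no-wrap case (N_w = 0) is defined as "no complex on the
tether": the protein size term vanishes and Δx ≡ 0, so the wrapped model
reduces exactly to the bare model rather than keeping a phantom x_SSB
contribution.

## Complex geometry and constraints

The complex's contribution to the extension is its entry/exit separation
x_SSB projected by the Langevin factor L(z) = coth z − 1/z at
z = F·x_SSB/kBT (rotational Boltzmann averaging of a rigid body under
torque). L is evaluated by series below z = 1e-4; its force integral has
the closed form kBT·ln(sinh z / z), used as a cross-check for the grid
integrals.

Constraints on (N_w, x_SSB) come at three nested levels:

1. protein size, 0 ≤ x_SSB ≤ 6.5 nm;
2. minimum/maximum distance between nucleotide pairs N_w apart on the
   wrapping path (all-pairs scan of one reference atom per nucleotide —
   phosphate P, falling back to C1′ at a 5′ terminus);
3. hotspot contours: distances between groups of nucleotides within a
   contact cutoff (default 0.6 nm, the midpoint of the 5–7 Å range) of
   the Trp-54/His-55/Arg-56 cluster on each monomer. Pair points are
   clustered into contiguous N_w bands (gaps > 2 nt split regions) and
   each band smoothed into its convex envelope — the "smooth contour"
   operation is otherwise unspecified, and the convex hull is the
   weakest smoothing that yields a closed band.

Nesting is enforced by clipping level 3 into level 2 into level 1.

**Fixture path.** PDB structures cannot be assumed available offline, so
a synthetic stand-in (`fixture_wrapping_path`) provides the geometry: a
baseball-seam curve on a 6.5 nm-diameter sphere, resampled at uniform
0.56 nm arc steps, with total seam length set so the wrap closes after 65
nucleotides — reproducing the two topological facts the analysis uses
(the 65-nt wrap exits < 2 nm from its entry; the 35-nt wrap spans
~5.5 nm) — and four hotspot anchors a quarter-wrap apart whose contact
sets generate four contour bands near N_w ≈ 17, 35, 56 and 65. It is
labelled synthetic in code and metadata and is not derived from any
deposited structure. Real structures load through `geometry.load_structure`
(Bio.PDB), which records the chain join order and cutoff in the metadata
because the deposited complex contains two (dC)₃₅ chains whose junction
into one 65-nt path is a configuration choice, not an inferred fact.

## Inversion and mode assignment

The compaction model inverts in closed form;
`N_w = (Δx + x_SSB coth(F x_SSB/kBT) − kBT/F)/ξ_ss(F)` is monotone in
x_SSB, so each integer N_w bin maps to an exact x interval which is
intersected with the envelope band at that N_w (interval arithmetic;
bands thinner than any sampling grid — which arise on the nearly closed
fixture — are never missed). Values outside [0, N_ss] raise an
infeasibility error naming the constraint level; nothing is clamped
silently. The best estimate is the centre of the feasible interval,
rounded half-up, reported alongside the real value and the ranges at all
levels.

Mode bands are declared (the literature gives centres, not edges):
≥ 60 → 65, (45, 60) → 56, [25, 45] → 35 (the 45 tie rounds down),
[8, 25) → 17, < 8 → unbound.

## Trace analysis

Traces are boxcar averaged (non-overlapping windows; photon channels are
summed, signals averaged) from the native 66 kHz to the 10 Hz analysis
bandwidth. States are found by PELT change-point detection with L2 cost,
written in-package and validated on synthetic ground truth. The penalty
defaults to `1.5·σ̂²·ln n` with σ̂ from the median absolute first
difference — chosen on synthetic two-state data as the smallest penalty
that produces no spurious splits on featureless noise while recovering
≥ 95% of second-scale dwells at SNR 3; dwells at or below the 0.3 s
detectability bound are not reliably recovered at that bandwidth, which
mirrors the instrument analysis this emulates. The minimum dwell is
0.3 s. Plateaus are assigned to the nearest canonical level when levels
are supplied, and adjacent same-label segments merge.

Mixture fits of extension-change histograms use scikit-learn Gaussian
mixtures with BIC component selection (bin width 0.5 nm for display);
occupancies are the mixture weights. Peak-mean uncertainties come from a
seeded bootstrap over traces (1000 resamples).

Dwell statistics censor the first and last segment of every trace. Rates
are `k_{i→j} = p_{i→j}/τ_i` with τ_i the mean completed dwell; states
never seen in a completed dwell are absent from the output rather than
reported as zero.

## Energy landscape

States are labelled by wrapped nucleotides {0, 17, 35, 56, 65} on the
single nearest-neighbour pathway; intermediates with similar N_w are
merged into one state before energetics. Free-energy differences come
from occupancy ratios, `ΔG_ij = −kBT ln(p_i/p_j) − ΔG_stretch`, with the
stretch term integrated on a 0.01 pN trapezoid grid from the per-state
compaction curves Δx_i(F). Per-force estimates of each adjacent link are
averaged; the chain is anchored at G_0 = 0 and link variances propagate.
Pairs where either state has fewer than 5 counts are censored rather
than estimated.

In the compaction-positive convention the tilted energy is
`G_i(F) = G_i + ∫₀^F Δx_i dF′/kBT` — wrapped states rise with force —
and the rates
`k_{i→j} = k₀ exp(−[(G‡ + x‡F) − (G_i kBT + ∫Δx_i dF)]/kBT)` satisfy
detailed balance against those occupancies identically (verified to
1e-8 relative on a force grid). One sign convention is used everywhere
and serialized in the landscape JSON; consistency is guaranteed by the
detailed-balance identity rather than by matching any particular
display convention.

Per-state entry/exit separations for the tilt (level-3 geometry):
x_SSB = 1.5 nm (65-nt wrap; the closure bound is < 2 nm), 3.5 nm
(56 nt; ssDNA on all four subunits with the 3′ end unraveled to the
nearest hotspot, between adjacent and spanning geometries), 5.5 nm
(35 nt; the strand exits at opposite ends of the tetramer), 4.0 nm
(17 nt; two-monomer wrap). These are fixed model inputs, not fitted.

The barrier fit is least squares in log-rate space over six parameters
(G‡ and force-independent x‡ for the 0/17, 17/35 and 35/56 barriers) with
the attempt rate fixed at k₀ = 10⁷ s⁻¹ and state energies/extensions
taken as known inputs; covariance comes from the Gauss–Newton
approximation at the optimum. The 56/65 exchange is faster than the
detectability bound, so its barrier is not fittable; the reference
landscape stores a fast-exchange placeholder (−10 kBT, i.e. ~10–11 kBT
above the flanking wells, below the < 15 kBT bound) that is excluded from
fits and used only to let simulations exchange those states realistically.

The total wrapping free energy is the trapezoid integral of the
equilibrium (Boltzmann-averaged) compaction from zero force to the
half-unwrapping force F₁/₂, the root of equal bound/unbound occupancy
(Brent on the log bound weight). With the reference landscape this gives
F₁/₂ ≈ 10.7 pN and G_wrap ≈ 20.8 kBT, consistent with the depth of the
fully wrapped state within the tilt-integral identity.

## RecA competition

RecA-coated ssDNA extends at 1.5× the dsDNA per-bp extension. The five
displacement intermediates are modelled as: (i) 56-nt wrap, no RecA;
(ii) 35-nt wrap, no RecA; (iii) 35-nt wrap, remainder RecA-coated;
(iv) 17-nt wrap, remainder coated; (v) bare-of-SSB, fully coated
(≈ +10 nm vs the bare tether at 5 pN). States i/ii use the wrapped-tether
model, iii/iv add the 1.5ξ_ds term for the unwrapped remainder, v is the
full filament. State ii reuses the 35-nt geometry of state iii (whether
their x_SSB differ is not established; one value is the parsimonious
choice). The iSp18 spacers flanking the site are treated as zero-length.
RecA kinetics are not modelled mechanistically — the simulator uses
configurable per-step displacement rates (defaults ~0.1–0.5 s⁻¹, chosen
to produce staircases resolvable at 10 Hz) with nucleation allowed only
from the 35-nt mode (> 14 nt of exposed ssDNA).

## FRET and diffusion

FRET efficiency follows the Förster relation `E = 1/(1 + (r/R₀)⁶)` with
R₀ = 6 nm ≈ 18 nt on poly(dT). Reptation is a reflected 1D random walk
on the unwrapped-nucleotide lattice with hop rate D per direction (MSD
slope 2D). The diffusion estimator uses the 1D mean-first-passage
convention `D = L²/(2τ̄)`: a junction-departure dwell starts at ssDNA
junction contact (separation 0, the high-FRET extreme) and ends when the
separation first reaches one Förster radius (the E = 0.5 boundary), whose
continuum MFPT is exactly L²/2D; the same convention is used by simulator
and estimator, so recovery is self-consistent up to the (L+1)/L
discrete-lattice factor (~5% at L = 18). The separate threshold E = 0.25
(midpoint of the reported E ≈ 0.5 and E ≈ 0 levels) serves only to
binarize FRET for the joint wrap×FRET states i–iv; sliding is a FRET flip
at fixed wrap state, a mode change is any wrap flip, and rolling is the
specific triple i→iii→ii (or its mirror).

## Synthetic data

Constant-force traces are exact Gillespie paths over the pathway with
rates from the landscape, emitted at the native rate with additive white
Gaussian noise (default 25 nm at 66 kHz, i.e. ~1 nm after boxcar to
10 Hz; the instrument's true noise spectral shape is unknown, so white
noise is the declared stand-in). Force ramps are quasi-static: the trap
separation grows at 65 nm/s, force balances tether elasticity against the
0.15 pN/nm series stiffness of the two 0.3 pN/nm traps, and hopping uses
time-inhomogeneous thinning with a majorizing rate over 20 ms windows;
the unbound state is absorbing because ramps run in protein-free buffer,
and the rupture force is the force at the final unbinding transition.
Every simulator returns its ground truth (event times, state path,
positions) beside the observable trace, and all randomness flows from the
mandatory seed, making runs bit-reproducible.

What the generator does **not** emulate: instrument drift, bead
hydrodynamics and PID-clamp dynamics, coloured noise, photophysics beyond
Poisson counts (no blinking, crosstalk or γ-correction), multi-protein
binding, and sequence-dependent elasticity. Passing tests therefore
demonstrate estimator correctness under the stated statistical model, not
robustness to instrument artefacts.

## Problem sizes and known limitations

Tests and the acceptance script run at desk scale: 10⁴ occupancy samples
per force, 66 noisy rate points for the barrier fit, 50 first-passage
dwells for the diffusion round trip, hundreds of dwells per segmentation
scenario, and 20 seeded ramps for rupture statistics — sizes at which the
estimators' standard errors are comfortably inside the scientific
tolerances being checked.

Known limitations:

* With the fitted barrier parameters and k₀ = 10⁷ s⁻¹, simulated 65 nm/s
  ramps rupture near ~18 pN, above the measured ~10 pN dissociation band,
  while the equilibrium F₁/₂ (~10.7 pN) matches it; the discrepancy is
  kinetic, of the size the ~3 kBT systematic uncertainty in the barrier
  heights (from the assumed attempt rate) readily produces, and is
  reported honestly by the corresponding test rather than absorbed into a
  parameter change.
* The fixture path's smooth seam lacks the local meandering of the real
  crystallographic path, so its level-2/3 constraints at small N_w are
  tighter than the crystal's; the low-force and high-force worked points
  invert to their expected modes at level 1, while the 56-band point also
  inverts at level 3.
* The ssDNA law is a calibrated stand-in, accurate at the anchors and
  smooth between them; per-salt tabulated values would shift ξ_ss by a
  few percent.
* The diffusion estimator carries the (L+1)/L lattice bias and assumes
  dwells begin at junction contact; lifetimes defined by other FRET
  thresholds would need a different conversion constant.
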