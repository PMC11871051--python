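# Methods

## Model overview

The package chains four components:

1. **Synthetic geometries** (`tucei.generator`): a planar 12-atom
   2-thiouracil reference structure and kinematic deformation operators
   that emulate the geometric signatures of the first picosecond of
   excited-state dynamics.  No electronic structure is computed; the
   generator's job is to provide controlled study conditions whose
   momentum-space signatures the rest of the pipeline must recover.
2. **Coulomb explosion** (`tucei.explosion`): instantaneous ionization of
   every atom to a point charge (default +1 each), Newtonian dynamics
   under pairwise Coulomb repulsion, integrated to asymptotic momenta.
3. **Molecular frames** (`tucei.frames`): the recoil frame (z ∥ p_S,
   momenta scaled by |p_S|) and the sum/difference frame (polar axis
   ∥ p_S + p_O), with Newton plots and (Φ, cos Θ) proton angular maps.
4. **Delay-scan statistics** (`tucei.scan`): pump–probe event simulation
   with a detector model, per-delay normalized maps, pumped-minus-unpumped
   differences, region integrals with Poisson errors, and onset detection.

## Ground-state geometry

The S0 fixture (`tucei/data/s0_2thiouracil.xyz`) is a planar 2-thiouracil
with standard pyrimidine numbering (N1–C2–N3–C4–C5–C6; C2=S thione, C4=O
carbonyl; protons H9 on N1, H10 on N3, H11 on C5, H12 on C6).  Bond
lengths are force-field-typical (C2=S 1.66 Å, C4=O 1.23 Å, ring C–N
1.37 Å, N–H 1.01 Å, C–H 1.08 Å); after flattening, the sulfur was rotated
in-plane about C2 so that the angle between the C2→S and C4→O bond
vectors is exactly 116.0°, the one quantitative ground-state constraint
the analysis relies on.  `build_s0` accepts internal-coordinate overrides
(exocyclic/X–H bond lengths and the C–S/C–O angle) and validates the
12-atom / C₄H₄N₂OS / no-clash contract.

## Deformation operators and their composition

* `apply_c2_pyramidalization(g, angle)` rotates C2 — and, in the G2
  preset, the N1/N3-attached protons — about the N1–N3 axis.  The rotation
  angle equals the measurable improper dihedral change about that axis.
* `apply_sulfur_oop(g, angle, stretch, target_co_cs_angle)` tilts the
  C2→S bond towards the ring normal by `angle`, lengthens it by
  `stretch`, and (when a target is given) rotates its in-plane component
  so the total C–S/C–O bond-vector angle hits the target exactly; the
  solve accounts for the C4→O bond no longer lying in the (post-pucker)
  ring plane.

Both operators use the ring-circulation normal (oriented by the
N1→C2→…→C6 cycle), which co-rotates with the molecule; they therefore
commute with global rotations to machine precision, conserve composition,
and leave their anchor atoms untouched.

**Relative sign.** The staged composition applies the sulfur bend on the
*opposite* side of the ring plane from the C2 pucker.  This is the
sp³-like arrangement (pyramidalization at C2 places the substituent anti
to the displaced ring atom) and it is the composition under which the two
motions reinforce in momentum space: cos α evolves from −0.40 towards
−0.16 at the full late-time geometry and H11 migrates into the filament
band.  Composing both motions on the same side largely cancels these
signatures.

**Onset ramps.** Each motion follows a causal cubic smoothstep
(3s² − 2s³) rising over the `ramp_width` = 30 fs *preceding* its onset
time and saturating exactly at it: zero deformation before the rise
(the t = 0 frame always equals the thermally sampled ground state) and
the full preset amplitude at τ.  This encodes the intended semantics of
"onset at τ": a measurement at the onset delay already sees the complete
deformation.  A symmetric ramp centered at τ was rejected — its acausal
early tail gives the sulfur motion ~10 % amplitude at 65 fs, whose frame
tilt cancels the pucker-driven H9 shift, and its half-developed amplitude
at τ cannot produce a full-size depletion at the onset delay.

Default preset amplitudes: pucker 30°, sulfur bend 40° with 0.1 Å C–S
stretch and a 104° late-time bond-vector-angle target; τ_pucker = 65 fs,
τ_s = 130 fs.  The amplitudes are free parameters chosen to produce
clearly resolvable angular-map changes, not derived quantities.

## Thermal ensemble

`thermal_ensemble` adds independent zero-mean Gaussian out-of-plane
displacements, default σ_oop = 0.05 Å per atom along the ring normal —
a plausible RMS out-of-plane amplitude for a vibrationally warm molecule
evaporated from a ~515 K oven, and the scale that reproduces the observed
sharp-but-finite proton features.  Options: mass-weighted amplitudes
(∝ √(m_H/m)) and isotropic 3-D smearing.  In-plane structure is left
untouched by default because the molecular-frame observables are designed
around the in-plane S/O momenta.

What the generator does *not* emulate: anharmonic large-amplitude
vibrations, in-plane thermal motion, initial-velocity distributions,
conformational heterogeneity, and the geometry diversity of real
surface-hopping trajectory ensembles.  Passing tests therefore show that
the *pipeline* recovers staged deplanarization under controlled
conditions; they do not validate excited-state dynamics itself.

## Coulomb explosion integrator

Internal units are Hartree atomic units (1 Å = 1.8897261255 bohr,
1 amu = 1822.888486 mₑ); masses are most-abundant-isotope values.
The equations of motion are integrated with an embedded Dormand–Prince
RK5(4) scheme with per-step error control (default rtol 1e-8, atol
1e-10).  Many near-identical geometries are integrated as one batch under
a shared adaptive step; the pair forces use a precomputed pair list and a
signed incidence matrix, so a 2000-member thermal ensemble explodes in
seconds.

Termination: the run ends when the residual potential energy of every
batch member is below `pe_tolerance` (default 1e-5) times its total
energy; momenta are reported without extrapolation, so asymptotic momenta
agree with closed forms at the pe_tolerance/2 level and tighter contracts
(the two-body 1e-6 sweep, 1e-9 rotational equivariance) are tested with
correspondingly tighter configurations.  Non-convergence within
`max_time`/`max_steps` raises a diagnostic error; nothing is silently
truncated.

The instantaneous point-charge model converts the *entire* initial
Coulomb energy (≈ 14.8 Hartree ≈ 402 eV for all-+1 2-thiouracil) into
kinetic energy release — a known overestimate of real experiments, which
largely cancels in the normalized-momentum representations.  Initial
velocities default to zero; a per-atom velocity option exists for
sensitivity studies.

## Frames and binning

Frame A (recoil): ẑ = p̂_S; ŷ = normalized component of p_O ⊥ ẑ (so O has
y ≥ 0, x = 0); x̂ = ŷ × ẑ; all momenta divided by |p_S|.  Frame B
(sum/difference): ẑ′ = unit(p_S + p_O); x̂′ = normalized component of
(p_S − p_O) ⊥ ẑ′; ŷ′ = ẑ′ × x̂′; protons reported as (Θ, Φ) with
Φ ∈ (−180°, 180°], ±180° identified.  The polar-axis assignment (sum, not
difference) is the one validated against the simulated planar layout:
it puts H10 at the north pole (+0.98), H12 at the south pole, H9 at
Φ ≈ 0° (cos Θ ≈ −0.35) and H11 at Φ ≈ ±180° (cos Θ ≈ −0.58).  A config
flag (`polar_axis`) retains the alternative.

Binning defaults: Newton plots 100 × 100 over [−1.5, 1.5]²; angular maps
72 (Φ) × 40 (cos Θ).  "Separated features" is made deterministic as:
threshold at 20 % of the histogram maximum, count 4-connected components.

## Delay-scan Monte Carlo

`simulate_delay_scan` explodes a finite pool of structures —
`n_trajectories` (default 100, a typical excited-state ensemble size)
excited members per delay plus `n_thermal` (default 1000) unpumped
thermal geometries — and then draws `n_events` (default 20 000)
coincidence events per delay with replacement: excited with probability
`excited_fraction` (default 0.2, a plausible UV-excitation fraction given
focal-volume averaging; configurable), thermal otherwise.  This mirrors
how a finite theoretical trajectory set is sampled by many detection
shots.  Event counts set the Poisson errors; pool sizes set how finely
the geometry distribution is resolved (pool-resampling correlations make
the quoted errors slightly optimistic, which is acceptable for the
ordering statistics computed here).

The detector model smears every momentum component with Gaussian noise
σ_p (default 2 a.u., a few percent of a proton momentum) and reduces each
record to a threefold S⁺/O⁺/H⁺ coincidence, the proton chosen uniformly
among the four (labels can be stripped for "measured mode").

Angular maps are normalized to the integrated number of ions per delay
step.  Difference distributions normalize each input per its total ions
and combine errors in quadrature.  Smoothing uses a Gaussian kernel
(width in axis units; Φ treated as periodic); the output is rescaled to
the input total, so the integral is preserved exactly; errors are
smoothed with the same kernel — a conservative, correlation-ignoring
estimate.

## Analysis regions

Defaults, frozen after validation on the simulated planar layout and the
G2/G3 presets (all configurable):

| region   | Φ (deg)        | cos Θ            |
|----------|----------------|------------------|
| H9       | [−25, 25]      | [−0.50, −0.20]   |
| H11      | \|Φ\| ≥ 150    | [−0.80, −0.26]   |
| filament | all            | (−0.1, 0.6) minus the other boxes |

The H9 box brackets its validated unpumped peak (cos Θ ≈ −0.35) tightly,
so the earliest pucker-driven displacement (to ≈ −0.61) empties it at the
first delay.  The H11 box is deliberately wide above its peak (≈ −0.58):
the pucker alone tilts the frame and moves H11 to ≈ −0.36, which must
*not* register, while the later sulfur-driven migration of H11 through
the map (to cos Θ ≈ 0, with Φ drifting below 150°) must.  The box
geometry thus encodes the physical attribution: H9 times the pucker, H11
and the filament time the sulfur motion.  The filament band keeps the
characteristic −0.1 < cos Θ < 0.6 range.

Onset detection: earliest delay with |value − unpumped baseline| >
k·(combined standard deviation), default k = 2 — early enough to honour
"first decrease" semantics while controlling false onsets on flat
series; ties are reported as ties, never-departing series as "no onset".

`scale_to_reference` provides the closed-form single-factor least-squares
scaling (factor = Σ r·s / Σ s²) used when overlaying differently
normalized series.

## Problem sizes and determinism

Default study sizes — 2000-member ground-state ensembles for the static
benchmarks and 100 trajectories + 1000 thermal structures + 20 000
events/delay for scans, with 20 seed replicates for the onset-recovery
property — resolve all tested contrasts at many combined standard
deviations while keeping a full replicate set to a few minutes of compute.
Every stochastic stage takes an explicit seed (numpy `default_rng` /
`SeedSequence`); identical configurations reproduce bitwise-identical
outputs, and scan artifacts carry their configuration hash and seeds.

## Known limitations

* Instantaneous, purely Coulombic, point-charge fragmentation: no finite
  charge-up time, charge transfer, sequential ionization or non-Coulombic
  forces.  Absolute kinetic energies are overestimated by construction;
  simulated angular features are sharper than measured ones.
* The generator imitates two specific deformation modes with fixed
  amplitudes and monotone onsets; real dynamics are a broad distribution
  over many coordinates.
* Detector acceptance is reduced to isotropic Gaussian momentum noise and
  an idealized threefold-coincidence filter; no flight-time
  reconstruction, dead-time or acceptance anisotropy.
* Carbon-ion observables are deliberately out of scope: in experiments
  they are smeared by charge-up dynamics that this model does not cover.
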