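# tucei — Coulomb-explosion imaging of ultrafast deplanarization in 2-thiouracil

`tucei` simulates how time-resolved X-ray-induced Coulomb-explosion imaging
(CEI) reveals the out-of-plane symmetry breaking of photoexcited
2-thiouracil.  It is aimed at gas-phase molecular-physics groups who want a
tested, end-to-end reference pipeline for CEI observables: from molecular
geometries, through the N-body Coulomb fragmentation, to the
molecular-frame momentum representations and delay-scan statistics used to
time the deformation.

## The physics

Planar heterocycles such as 2-thiouracil (2-tUra, C₄H₄N₂OS) relax after UV
excitation through an internal conversion (¹ππ\* → ¹nπ\*) that is symmetry
forbidden at planar geometry: the molecule must deplanarize.  Theory
predicts a staged motion — first a local pyramidalization at the C₂ atom
(with the N₁–C₂–N₃ triangle and its protons folding out of the ring
plane), then the sulfur atom swinging strongly out of plane with a C–S
elongation, closing the C–S/C–O bond-vector angle from its ground-state
116° towards 104°.

CEI probes this by rapidly stripping the molecule into atomic cations
(modelled here as instantaneous: every atom becomes a point charge +1) and
measuring all fragment momenta in coincidence.  The package computes the
standard observables:

* **cos α** — cosine of the relative emission angle between the S⁺ and O⁺
  ions, `cos α = p̂_S · p̂_O`.  For the planar ground state it peaks near
  −0.4, i.e. arccos(−0.4) ≈ 114°, strikingly close to the 116° bond angle.
* **Recoil frame** — z ∥ **p**_S, the O⁺ momentum spanning the y–z plane
  (y ≥ 0), all momenta scaled by |**p**_S|; Newton plots in this frame
  separate the four protons cleanly.
* **Sum/difference frame** — polar axis along **p**_S + **p**_O, azimuth
  reference along **p**_S − **p**_O; proton emission is histogrammed in
  (Φ, cos Θ).  In the planar molecule H10/H12 sit at the poles, H9 at
  Φ = 0° and H11 at Φ = ±180°.  Deplanarization smears these peaks and
  populates a "filament" band −0.1 < cos Θ < 0.6.
* **Region series and onsets** — per-delay box integrals of the angular
  map with Poisson errors; an onset is the earliest pump–probe delay
  departing from the unpumped baseline by more than k (default 2)
  combined standard deviations.

A synthetic generator supplies the study conditions: a planar S0 fixture,
thermal out-of-plane smearing, and staged-onset excited-state trajectories
(pucker fully developed at τ_pucker = 65 fs, sulfur motion at
τ_s = 130 fs) sampled at the measured delays 65, 130, 260 and 1000 fs.

## Worked example

```python
import numpy as np
from tucei import build_s0, thermal_ensemble, explode_ensemble
from tucei.frames import CoincidenceEvent, cos_alpha_histogram, newton_plot, count_features

ensemble = thermal_ensemble(build_s0(), n=2000, seed=1)   # sigma_oop = 0.05 A
events = [CoincidenceEvent.from_result(r) for r in explode_ensemble(ensemble)]

hist = cos_alpha_histogram(events, bin_width=0.05)
print("cos(alpha) peak bin center:", round(hist.peak_center(), 3))
print("implied S-O emission angle:", round(np.degrees(np.arccos(hist.peak_center())), 1), "deg")
print("proton features in the y-z Newton plot:",
      count_features(newton_plot(events, plane="y-z", species="H")))
```

prints

```
cos(alpha) peak bin center: -0.425
implied S-O emission angle: 115.2 deg
proton features in the y-z Newton plot: 4
```

— the momentum-space S⁺/O⁺ angle of the exploded planar molecule maps the
116° ground-state bond angle to within ~1°, and the four protons form four
separated features.

A full time-resolved scan (explosion of excited-state geometry ensembles
at each delay, detector model, normalized angular maps, region integrals,
onset detection):

```python
from tucei.scan import DelayScanConfig, run_scan
report = run_scan(cfg=DelayScanConfig(seed=0))
print(report.onsets)
```

```
onset threshold: 2.0 combined standard deviations
  H9: 65 fs
  H11: 130 fs
  filament: 130 fs
order: H9 < H11=filament
```

The H9 depletion is instantaneous on the delay grid (the C₂ pucker), the
H11 depletion and the filament growth follow at the sulfur onset — the
staged deplanarization read directly off the proton angular maps.

The same pipeline is available from the shell:

```
tucei synth --outdir out            # S0 + staged trajectory as XYZ
tucei explode out/s0.xyz --outdir out   # per-ion momentum table (CSV)
tucei scan --outdir out             # maps, difference plots, onset report
```

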