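# corpusim

Vibration sensing in vertebrates relies on lamellated mechanoreceptors —
the Pacinian corpuscle (PC) of mammals, reptiles and amphibians and the
Herbst corpuscle of birds: an ovoid capsule of concentric collagenous
lamellae separated by fluid, wrapped around a single sensory neurite.
Across species these receptors differ enormously in size and layering
(outer radii from ~5 µm in the star-nosed mole to ~320 µm in the elephant),
which raises a comparative question: how do a corpuscle's structural
parameters set the frequencies it hears best?

`corpusim` is a scientific Python package for that question, aimed at
computational neuroscientists and sensory biomechanicists.  It provides

* a **three-stage mechanotransduction simulator**: (1) a frequency-domain
  model of the lamellated outer core — thin spherical shells with membrane
  stiffness `k = 2Eh/((1−ν²)r²)` coupled by squeeze films with damping
  `c = κµr²/g³`, assembled into a tridiagonal harmonic balance whose
  solution `T(ω) = U_core/A` is a mechanical high-pass; (2) an analytic
  inner-core surrogate converting core displacement into half-wave
  rectified neurite strain and then saturating channel current
  `I = I_max·ε/(ε+ε_sat)`; (3) a conductance-based (sodium–potassium–leak)
  point neuron producing spike trains;
* a **tuning-curve engine** that finds, per stimulus frequency in
  2–1000 Hz, the minimal surface displacement producing 1:1 spike
  entrainment (bisection over amplitude), and extracts the peak frequency
  (tuning-curve minimum, `A_min`) and the bandwidth (range where the
  threshold stays below `3.5·A_min`);
* a packaged **19-animal morphometry table** (common name, body mass,
  corpuscle outer radius, lamella count, mean lamellar thickness, with
  pixel-unit flags for micrographs lacking scale bars) and the
  **cross-species regression battery** over it;
* a **synthetic-population generator** reproducing the table's statistical
  structure, for testing every stage without external data.

The model's single fitted constant — the squeeze-film shape factor κ — is
calibrated once so the cat corpuscle's simulated peak frequency matches its
reported 48 Hz optimum, then frozen for all species, mirroring the
tune-once-to-the-cat practice of this receptor's modelling literature.

## Worked example

```python
import numpy as np
import corpusim as cs

records = cs.load_species_table()            # packaged 19-animal table
cat = next(r for r in records if r.common_name == "cat")
geometry = cs.build_geometry(cat)            # 30 shells spanning 51.1-255.6 um
materials = cs.MaterialParams()              # E=1.4 kPa, mu=3.5 mPa s, calibrated kappa

# Stage-1 transmission is a mechanical high-pass
for f in (2.0, 48.0, 1000.0):
    T = cs.transfer_ratio(geometry, materials, f).transfer
    print(f"|T({f:6.0f} Hz)| = {abs(T):.2e}")

# threshold for 1:1 spike entrainment at the cat's best frequency
pipe = cs.Pipeline(geometry, materials)
cfg = cs.TuningConfig(freq_grid=np.array([48.0]))
print(f"threshold at 48 Hz = {cs.threshold_at_frequency(pipe, 48.0, cfg):.3f} um")

# cross-species structure: lamellar organisation follows corpuscle size...
battery = {(r.x_name, r.y_name): r for r in cs.structural_regressions(records)}
lam = battery[("outer_radius_um", "n_lamellae")]
print(f"n_lamellae ~ radius: r2 = {lam.r_squared:.2f}, p = {lam.p_two_tailed:.4f}, n = {lam.n}")
# ...but nothing follows body mass
mass_p = min(r.p_two_tailed for (x, y), r in battery.items()
             if x == "mass_kg" and "mammal" not in y)
print(f"mass regressions: smallest p = {mass_p:.2f}")
```

prints

```
|T(     2 Hz)| = 5.18e-10
|T(    48 Hz)| = 6.60e-03
|T(  1000 Hz)| = 4.34e-01
threshold at 48 Hz = 0.687 um
n_lamellae ~ radius: r2 = 0.43, p = 0.0083, n = 15
mass regressions: smallest p = 0.38
```

Reading the numbers: the cat's capsule passes essentially nothing at 2 Hz
and ~43% of the surface displacement at 1 kHz (the high-pass that protects
the ending from static pressure); a 0.7 µm vibration at 48 Hz is enough to
fire one spike per cycle; across species the lamella count is strongly
predicted by corpuscle radius (r² = 0.43) while no structural parameter
follows body mass (all p ≥ 0.38) — corpuscle organisation is set by
corpuscle size, not by the animal carrying it.

A command-line interface wraps the same machinery:

```bash
corpusim tune --species cat --out out/       # curve CSV + features JSON
corpusim tune --all --out out/               # 19-species summary
corpusim stats species.csv --out regressions.csv
corpusim synth --n 200 --seed 1 --out synthetic.csv
corpusim calibrate --species cat --target 48
```

Every run writes a `*.provenance.json` sidecar echoing its effective
parameters.  `src/corpusim/data/defaults.yaml` is the fully specified
default configuration.

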