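# Methods

`corpusim` models how a lamellated mechanoreceptor — the Pacinian corpuscle
(PC) of mammals and other tetrapods, and its avian homologue the Herbst
corpuscle — converts a sinusoidal indentation of its surface into a spike
train, and asks how the receptor's best frequency and bandwidth depend on
the three structural parameters that comparative histology provides: outer
radius `R`, number of outer-core lamellae `N`, and average lamellar
thickness `h`.  A companion statistics module analyses those same three
parameters across a 19-animal morphometry table.

## The three-stage transduction model

**Stage 1 — lamellated outer core (`corpusim.mechanics`).**  The outer core
is a sphere of alternating solid and fluid layers.  Each lamella is a thin
spherical shell with membrane restoring stiffness per unit area

    k_i = 2 E h_i / ((1 − ν²) r_i²),

and each interlamellar fluid film a squeeze-film damping per unit area

    c_i = κ µ r_i² / g_i³,

the lubrication scaling for fluid squeezed laterally over a length ~`r` out
of a gap `g`.  A single dimensionless constant `κ` absorbs the mode-2
deformation shape factors of both elements.  Layer inertia is neglected:
at micrometre scale and below 1 kHz the dynamics are stiffness/viscosity
dominated, and the quasi-static harmonic balance

    k_i U_i + iω [ c_{i−1}(U_i − U_{i−1}) + c_i (U_i − U_{i+1}) ] = 0

is a tridiagonal complex system solved directly (banded LU; the residual is
checked against 1e−10 on every call).  The outermost surface is driven at a
prescribed mode-2 displacement amplitude — tuning thresholds are defined in
surface displacement — and the core surface is backed by a nearly rigid
spring (10× the stiffest lamella, exposed as a parameter).  The resulting
transfer ratio `T(ω) = U_core / A` is a monotone high-pass: slow
indentations leak through the films, fast ones are transmitted inward.
Because `k` and `c` both scale as 1/length, `T` depends on the geometry
only through the dimensionless ratios `h/R`, `g/R`, `r/R` — the simulator
is scale-invariant, which is what lets records measured in pixels be
simulated through their thickness/radius ratio at a nominal 100 µm radius.

**Stage 2 — inner core and neurite strain (`corpusim.transduction`).**  The
finite-element inner core of the original modelling lineage is replaced by
an analytic surrogate: the core-surface displacement is converted to a
neurite membrane strain `ε = G·max(u, 0)/r_core` (half-wave rectified —
compression-only gating keeps one spike per stimulus cycle the natural
entrainment mode; a full-wave option exists), then to a cation current
through a two-parameter hyperbolic saturation
`I = I_max · ε/(ε + ε_sat)`.  The saturation matters qualitatively: at high
stimulus frequencies the per-cycle charge is capped at `I_max × half-period`
no matter how large the displacement, which is what ends the receptor's
following range.

**Stage 3 — afferent terminal (`corpusim.neurite`).**  A classic
sodium–potassium–leak excitable membrane (squid-axon parameter set, single
compartment, identical for every species) driven by the channel current,
integrated with a fixed-step fourth-order Runge–Kutta scheme at
dt = 0.01 ms (gating variables clipped to [0, 1]; a non-finite state raises
with advice to reduce dt).  All gating rates are multiplied by
`φ = 3^((T − 6.3)/10)`.

## Layered geometry construction

Per-lamella radial positions are not measurable from the available
morphometry, so lamella mid radii are spaced uniformly on `[r_core, R]`
with `r_core = 0.2 R` by default (a fixed geometric fraction, so that
cross-species comparisons reflect only the three measured parameters), and
the fluid gaps are the residual spacing.  A record whose lamellae are
thicker than the uniform spacing is rejected unless the layout's
minimum-gap fallback is enabled, which packs the lamellae inward from the
surface with films of `0.1 h` and lets the core shrink.

## Choice of operating point (the single end-to-end calibration)

The published account of this receptor family tuned its neurite model once
to the functional response of the cat PC and froze it for all species; this
package does the same, in two prescribed steps.

First, the neuron/transduction operating point.  The squid-axon equations
lose excitability when their kinetics are accelerated too far: we measured
1:1 entrainment ceilings of ~150 Hz at φ = 1, 500–700 Hz at φ = 4–6, and
complete heat block (no spikes at any drive) for φ ≳ 8, so a mammalian
temperature with Q10 = 3 scaling is not usable with this parameter set.
The defaults — T = 5.3 °C (φ ≈ 0.9), `I_max` = 10 nA over an effective
membrane area of 1e−5 cm² (saturation density 1000 µA/cm²), `G` = 0.3,
`ε_sat` = 0.01 — were chosen together so that the isolated afferent's
threshold-versus-frequency valley bottoms near 40 Hz, stays finite from
2 to 1000 Hz, and the calibrated cat pipeline (below) entrains at 48 Hz
with thresholds inside the 0.01–100 µm decade.

Second, the film constant.  `calibrate_kappa` bisects `log κ` until the
full pipeline's peak frequency for the cat geometry (R = 255.6 µm, N = 30,
h = 0.24 µm) equals the cat's reported 48 Hz optimum within 2%; the peak is
verified to be monotone non-increasing in κ over the bracket (stronger
films transmit lower frequencies).  The fitted value, κ = 0.0438, is the
package's single fitted constant, shipped as the `MaterialParams` default
and frozen for every species.

## Tuning curves and features

The tuning threshold at frequency `f` is the smallest surface amplitude for
which the steady-state firing rate equals `f` within 10% (25 stimulus
cycles, the first 5 discarded; the tolerance and window are this package's
choices, since only the rate-equality definition is prescribed).  A
13-point log-spaced amplitude scan over 1e−4–1e3 µm brackets the lowest
crossing of `0.9 f`; bisection shrinks the bracket to 1% relative width.
Amplitudes below the accepted crossing may climb through sub-harmonic
locking plateaus (one spike per 2, 3, … cycles) without invalidating the
search; a rate *above* the entrainment band below the crossing would, and
raises an error.  Where nothing inside the bracket entrains the threshold
is a NaN sentinel.

Features: `A_min` is the curve minimum; the peak frequency is the grid
argmin refined by golden-section search between its two grid neighbours to
0.5 Hz; the bandwidth is the frequency range over which the threshold stays
below `3.5 A_min`, located by log–log interpolation between grid points,
with the lower limit reported as 0 Hz when the lowest tested frequency is
already below the cut-off and the upper limit as the highest tested
frequency when no crossing exists.  Both the limits and their difference
are reported, since a single printed "bandwidth" number is ambiguous
between the two conventions.

Default problem sizes: the library default frequency grid is 40 log-spaced
points over 2–1000 Hz; the shipped analyses (acceptance script and
acceptance tests) use a 15-point grid per species and 4-point parameter
sweeps, which resolve the features these analyses compare while keeping a
full 19-species panel with calibration to a few minutes of CPU.

## Synthetic data

`corpusim.synth` draws populations with the statistical structure the
regression analysis assumes: radii log-uniform over 4–320 µm (the observed
two-decade span), lamella counts `N = round(15 + 0.05·R + Normal(0, 6))`
clipped at 5 (scatter chosen to put the population lamellae-radius r² near
the observed 0.43), thickness `h = 0.02·R·Lognormal(0, 0.8)` (weak
radius correlation, near the observed 0.23), and mass log-uniform over
10⁻²–10⁴·⁶ kg independent of everything (no mass–structure relation).
These are targets of emulation, not claims about nature.  The generator
does not emulate measurement error structure, phylogenetic relatedness, or
within-species variability — population-level statistics only — so tests
passing on synthetic tables certify the statistical machinery, not
biological inference.  `single_layer_fixture` builds an N = 1 geometry with
a free-riding core whose transfer has the closed form
`|T| = ωc/√(k² + ω²c²)`, the analytic oracle for the ladder solver.

## Statistics

Ordinary least squares with r² and a two-tailed slope t-test
(df = n − 2), via the standard library routine and cross-checked against a
normal-equations + t-distribution oracle to 1e−10 in tests.  Exclusion
policy: pixel-unit records are excluded from any regression involving an
absolute length; the dimensionless thickness/radius ratio and the lamella
count use all 19 records; the mammal sub-analyses drop the two aquatic
mammals (and the pixel-unit mammals, which have no absolute radius).
Animal mass enters untransformed by default: the linear regressor is the
one that reproduces the published sub-analysis p-values (0.71 for all
mammals, 0.16 for terrestrial mammals, and minimum 0.38 across the four
mass regressions), while a log10 regressor (also provided) does not.  No
multiple-testing correction is applied; raw p-values are reported.

## Known limitations

The quasi-static surrogate reproduces the central comparative phenomenon —
structurally very different corpuscles compressing into a similar
sensitivity band — and the cat anchor, but not every reported per-species
contrast.  Three limitations are worth stating precisely.

1. **Ordering of outliers.**  With a monotone high-pass Stage 1 and one
   shared neuron, every species' peak frequency is bounded below by the
   neural threshold valley's argmin; a species can only sit *below* the
   common cluster if Stage 1 attenuates its high frequencies, which a
   quasi-static shell/film ladder cannot do.  Reported low outliers
   (ostrich, dog) therefore come out inside the cluster here, and the
   cross-species corner spectrum implied by `(h/R, g/R, N)` alone does not
   push the goose above the human or above every cluster species.

2. **Curve shape at extreme geometries.**  Species whose films are wide and
   shells soft relative to the band (several pixel-ratio records, whale,
   mole) transmit so little below 1 kHz that their thresholds fall
   monotonically to the top of the tested band or exceed the amplitude
   bracket entirely; their curves lack an interior minimum.

3. **Scaling exponents.**  The threshold landscape has two wells — the
   afferent's intrinsic valley near 40 Hz and a mechanical pass-edge well
   that slides with `E·h·g³/r⁴` — so log–log slopes of peak frequency
   against `E`, `h` or `N` are well-defined only within one well and come
   out shallow (≈0.6 for `E`, ≈0.1 for `h`) or slightly negative (for `N`)
   across the prescribed sweep ranges, rather than the linear and
   superlinear laws reported for the original finite-element stage.  For
   `N` there is also a geometric effect with the opposite sign: at fixed
   outer radius, added lamellae thin the residual films (`g ∝ 1/N`),
   strengthening viscous coupling and lowering the pass edge, whereas a
   superlinear increase presupposes film widths that do not shrink as
   lamellae are added.  The acceptance script reports the measured slopes.

Also excluded by design: skin and surrounding-tissue filtering between the
stimulus and the corpuscle surface, corpuscle–corpuscle interactions,
species-specific neurite electrophysiology, and any spatially resolved
inner-core mechanics.
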