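# Fully specified default configuration for the corpusim CLI.
# Every value below equals the library default; pass this file (or an edited
# copy) to `corpusim tune/calibrate --config`.

materials:
  youngs_modulus: 1400.0      # Pa; lamellar Young's modulus (1.4 kPa)
  viscosity: 0.0035           # Pa s; interlamellar fluid (~5x water at 37 C)
  poisson_ratio: 0.49         # nearly incompressible soft tissue
  kappa: 0.0438               # squeeze-film constant, calibrated on the cat

layout:
  core_fraction: 0.2          # inner-core radius as a fraction of outer radius
  nominal_radius_um: 100.0    # stand-in radius for pixel-unit records
  min_gap_fallback: false     # pack inward with thin films when lamellae exceed spacing
  min_gap_fraction: 0.1       # fallback film width as a fraction of lamellar thickness

channel:
  i_max_na: 10.0              # saturating mechanosensitive current, nA
  eps_sat: 0.01               # strain at half saturation
  gain: 0.3                   # strain per unit relative core compression
  rectification: half         # compression-only gating (one spike per cycle)

neuron:
  c_m: 1.0                    # uF/cm^2
  g_na: 120.0                 # mS/cm^2
  g_k: 36.0
  g_leak: 0.3
  e_na: 50.0                  # mV
  e_k: -77.0
  e_leak: -54.387
  temperature_c: 5.3          # sets phi = 3^((T-6.3)/10) ~ 0.9
  membrane_area_cm2: 1.0e-05

tuning:
  freq_points: 40             # log-spaced grid over 2-1000 Hz
  bandwidth_cutoff: 3.5       # bandwidth limits at 3.5 x A_min
  entrainment_tol: 0.1        # rate within 10% of the stimulus frequency
  amplitude_bracket_um: [1.0e-04, 1.0e+03]
  bisection_rel_tol: 0.01
  refine_resolution_hz: 0.5
  n_cycles: 25                # stimulus cycles per simulation
  skip_cycles: 5              # discarded onset transient
  scan_points: 13             # coarse amplitude pre-scan
  dt: 1.0e-05                 # s; fourth-order fixed step
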