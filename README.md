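# osteotherm

Simulation and closed-loop control of focused-ultrasound (HIFU) mild
hyperthermia inside the medullar cavity of an osteolytic bone lesion.

The package reproduces, without hardware, the computational chain of an
MR-guided HIFU hyperthermia setup that exploits the natural acoustic
window of a cortical breakthrough:

* **`geometry`** — voxelized phantom: cortical cylinder (bone axis = +x)
  pierced by a 72° conical breakthrough (opening toward the transducer,
  beam axis = +z), cavity filled with tumour-mimicking gel; extraction of
  the inner cortical facet exposed to the beam.
* **`acoustics`** — Rayleigh–Sommerfeld field of the spherical-cap
  emitter (f = 130 mm, d = 120 mm, 1 MHz), with an axisymmetric cached
  surface integration, linear soft-tissue attenuation, focal metrics and
  sqrt(power) scaling; the focal offset H translates the transducer
  rigidly along the beam axis.
* **`sources`** — the dual heat source: direct soft-tissue absorption
  `q = 2·beta·I`, and the "acoustic oven" term: beam power crossing the
  inner cortical facet, averaged and re-deposited uniformly in the
  cortical shell (by default around the full inner perimeter of the
  sonicated segment — the wave-guide redistribution behind the
  circumferential isotherms).
* **`thermal`** — heat diffusion by iterative convolution with the exact
  Gaussian heat-kernel; impulse responses, the time lag ε between the
  end of sonication and the focal temperature maximum, the ε(R, H) table
  and its six-term quadratic surface fit; ring-uniformity metrics.
* **`control`** — the predictive duty-cycle controller: mono-exponential
  asymptote projection over a 32 s sliding window and the multiplicative
  update `delta ← clamp(min(delta·T_target/T_inf, 1), [0.1, 0.9])`,
  dwell time 64 s, activation at +1.5 °C.
* **`thermometry`** — synthetic single-slice PRFS maps (1×1×4 mm,
  1.6 s, σ = 0.2 °C, background drift, no signal in cortical bone and
  fatty medulla), drift correction from an unheated ROI, the 13-pixel
  disc ROI, a virtual intracortical fluoroptic sensor (0.1 °C) and
  PRFS-vs-sensor cross-correlation.
* **`session`** — the closed loop (plant → thermometry → controller),
  session metrics (settling by the |offset| < 0.2 °C criterion,
  steady-state mean/std, overshoot, converged duty cycle and power,
  delivered energy), and the focal-offset comparison study.
* **`experiments`** — packaged record of the 14 ex vivo procedures
  (cavity long axis, steady-state elevation, precision, energy) and its
  aggregation.

At the default configuration the simulated closed loop converges to a
duty cycle of ≈ 0.14–0.15 (≈ 8–9 W average acoustic power), settles in
≈ 200–260 s and holds +6 °C with < 0.2 °C ripple and < 0.7 °C overshoot.

## Calibration constants

Two semi-empirical constants are calibrated rather than derived:

* `TransducerSpec.efficiency = 0.228` — ratio of the measured free-field
  focal intensity (432 W/cm² at 60 W nominal) to the ideal lossless
  bowl prediction (1891 W/cm²); folds electro-acoustic conversion and
  apodization of the physical phased array into one constant.
* `SourceParams` — cortical absorption fraction 0.9 (cortical bone
  absorbs nearly all incident acoustic power), soft-tissue absorption
  0.35 × attenuation (the silica-loaded gel attenuates largely by
  scattering, which does not heat).

## CLI

```bash
osteotherm field --config cfg.yaml --out field.nii.gz   # pressure field
osteotherm run --seed 7 --out results/                  # closed-loop session
osteotherm lag-surface --out lag.csv                    # eps(R, H) + quadratic fit
osteotherm offset-study --h -7,0,7 --out offsets.csv    # focal-offset comparison
osteotherm table1                                       # ex vivo record summary
```

Configuration is YAML/JSON with one section per component
(`geometry`, `transducer`, `medium`, `source`, `thermal`, `controller`,
`thermometry`) plus `duration_s`, `seed`, `element_size_mm`; omitted
keys keep their defaults (see `osteotherm/config.py`).

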