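# Methods

This note documents the models behind `phycowatch`: the optical forward
model of the virtual reactor, the culture dynamics, the measurement
protocol, the analytics, and the numerical and design choices made where
the behavior was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The virtual instrument

### Detector

The virtual spectrometer samples 225–1000 nm at a 1.5 nm step (517
samples) with a 16-bit full scale of 65 535 counts. Counts scale linearly
with exposure time; values at or above full scale are clipped and flagged
saturated. Samples above 0.98 × full scale are treated as saturated for
quantitation (the instrument shows saturation but no published cutoff
exists; 0.98 leaves a guard band below the hard clip). Wavelength
calibration, dark current and stray light are deliberately not modeled.

### Excitation bank

Six LEDs with measured peaks 657, 615, 586, 520, 451 and 373 nm and
radiant powers 450, 334, 242, 270, 600 and 930 mW. Each line is modeled as
a Gaussian with 20 nm FWHM whose integral over wavelength equals the
radiant power. Gaussians are a pragmatic parameterization of the measured
lineshapes — the published spectra are shown but not parameterized — and
the FWHM is configurable per channel.

### Forward model

For culture state with biomass `B`, contaminant density `C` (cells/µL),
per-cell pigment contents `p_f`, yield modifier `y` and exposure `t`, the
expected counts at wavelength λ are

```
μ(λ) = t · [ s · (B + C + m) · L(λ)
           + Σ_f  β_f · p_f · B · y · η_f · G_f(λ) ]
```

* `L(λ)` — active LED profile (mW/nm as above);
* `s` — scattering coefficient (default 3.0 counts·nm·µL per mW·s·cell),
  wavelength-independent within an LED band and linear in particle
  density: the simplest model reproducing the observed monotone growth of
  the collected excitation line with scatterer concentration;
* `m` — medium/vial scattering floor (default 5 000 cell-equivalents/µL).
  Medium and vial walls scatter even in a blank vial; the floor keeps the
  excitation-line reference finite at zero biomass, which the calibration
  procedure requires. With the floor, the noise-free index grows
  monotonically (not proportionally) with biomass;
* `η_f` — excitation efficiency: the closed-form overlap of the unit-area
  LED Gaussian with a unit-peak Gaussian excitation band,
  `(σ_ex/√(σ_led²+σ_ex²))·exp(−Δ²/(2(σ_led²+σ_ex²)))`, summed over
  excitation maxima with weight 1.0 for the primary and 0.5 for
  secondaries; it lies in [0, 1] and decays monotonically with detuning Δ;
* `G_f(λ)` — unit-area Gaussian emission band (phycocyanin: 650 nm center,
  25 nm FWHM; chlorophyll a: 673 nm, 30 nm);
* `β_f` — relative brightness (phycocyanin 250, chlorophyll a 120,
  bright dyes 500–600), chosen once so that a dense culture (500 cells/µL)
  produces a mid-scale unsaturated excitation line at 0.1 s and a clearly
  resolved, unsaturated fluorescence band at 5 s, while the excitation line
  saturates in the 5 s capture — the regime the dual-exposure protocol is
  designed for.

Noise: Poisson shot noise on the expected counts plus Gaussian read noise
(σ = 4 counts, both configurable). Where the expectation exceeds 10× full
scale the Poisson draw is replaced by its normal approximation; those
samples clip to full scale regardless.

### Culture dynamics

Forward-Euler updates with a default step of 0.1 h (error O(dt); the step
is small against every default rate). Scenarios:

* **growth** — logistic biomass, `dB = r·B·(1−B/K)·dt`, r = 0.04 /h
  (≈17 h doubling, a realistic exponential-phase rate for cyanobacteria),
  K = 2 000 cells/µL; pigments constant, yield 1.
* **photoinhibition** (irradiance above a critical level; defaults
  150 vs 120 µmol photons m⁻² s⁻¹, inside the 20–150 range relevant for
  cyanobacterial cultivation) — three coupled effects:
  1. *transient yield pulse* `y(t) = 1 + A·(kt)·e^(1−kt)` (A = 0.6,
     k = 0.5 /h): energy that damaged photosystems can no longer channel
     into photochemistry is briefly re-emitted as fluorescence, producing
     a rise during the first hours. The pulse starts at 1, peaks at
     `1 + A` at `t = 1/k` and relaxes back. (A multiplicative factor of
     the form `1 + A·e^(−kt)` cannot produce this transient rise — it is
     maximal at t = 0 and strictly decreasing — so the pulse form above is
     used instead.)
  2. *pigment photo-degradation*: per-cell pigment decays exponentially at
     0.15 /h.
  3. *die-off*: once phycocyanin falls below 30 % of its healthy level,
     biomass decays at 0.1 /h (cell death/lysis), so OD declines late in
     the run.
  The product of pulse and decay peaks near t ≈ 1–2 h and falls below 10 %
  of its initial value well before 24 h, reproducing the qualitative
  "peak is lost" endpoint.
* **contamination** — target biomass static with pigment loss at 0.15 /h
  (a stressed, declining target population); a non-fluorescent contaminant
  grows logistically at 0.12 /h from 20 cells/µL. The contaminant
  contributes to scattering (and OD) only: OD rises while the fluorescence
  index falls.
* **calibration** — no dynamics.

The OD reading is linear in total particle density (10⁻³ OD units per
cell/µL) with Gaussian noise (σ = 0.005), logged at a 5 s cadence during
normal operation. OD cannot distinguish target cells from contaminants —
that blindness is the premise of the contamination detector.

## 2. The measurement protocol

A round: snapshot job state → photoperiod lights off, OD job paused → for
each requested LED, switch it on (the backend enforces that no two
excitation LEDs, nor an LED and the photoperiod lights, are ever on
together), capture 0.1 s and 5 s, switch it off → restore lights and OD
job. Restoration runs in a `finally` block, so any injected failure leaves
the reactor exactly as found; a failed capture aborts the round, keeping
completed pairs (round atomicity is per-LED, not all-or-nothing — partial
rounds carry usable data).

The monitor loop runs on the backend's simulated clock (a 24 h run
completes in well under a second); rounds start at t = 0 and repeat at the
configured interval (default 60 min), which must exceed the round
duration. Each pair is persisted as two CSVs with JSON sidecars, and the
fluorescence index is appended to `fluorescence_index.csv` after every
round. A sink write is retried once; a second failure aborts the run with
partial data intact. Floats serialize at 9 significant digits, which
round-trips the quantities of interest and makes equal-seed runs
byte-identical.

## 3. Spectral processing

* **Band integration** — trapezoidal over the native grid, with saturated
  samples removed first (the trapezoid then spans the surviving,
  non-uniform grid). Robust after masking; at the 1.5 nm grid it matches a
  0.01 nm reference integral of a Gaussian band to within 2 %. Fewer than
  two usable samples yield 0 by convention.
* **Exposure normalization** — linear rescaling; saturated samples keep
  their clipped value and a flag rather than being rescaled into fabricated
  counts.
* **Peak finding** — argmax over usable samples, refined by a three-point
  parabola when the maximum is interior; ties break toward the shorter
  wavelength; degenerate (convex) fits fall back to the raw sample. On a
  noiseless Gaussian at the default grid the center is recovered to a
  small fraction of the grid step.
* **Fluorescence index** — band areas per second by default
  (`(long fluor area / t_long) / (short excitation area / t_short)`);
  area is noise-robust, but interpolated peak *heights* are selectable
  (`mode="height"`) since the normalization convention (height vs area)
  is not fixed by the underlying method description. Default windows:
  excitation = LED peak ± 10 nm; phycocyanin emission = 640–680 nm,
  centered near the observed ~657 nm peak and clear of the 615 nm
  excitation window. The index is exactly invariant under a common
  multiplicative gain as long as the saturation mask is unchanged;
  amplifying gains can push shoulder samples across the saturation cutoff
  and thereby change the excluded set — a property of real clipped
  detectors, not an artifact.

## 4. Analytics

* **Normalization** — series are scaled to their first value (the
  published traces are "normalized" without a stated method; initial-value
  scaling makes run-to-run comparisons read as fold changes). A
  non-positive first value falls back to max-normalization with a warning.
* **Trend classification** — Theil–Sen slopes of initial-value-normalized
  OD and fluorescence, reduced to signs with a ±0.01 /h flat band, then the
  sign table: OD↑ & F↑ → healthy_growth; OD↑ & F↓ → contamination;
  OD↓ & F↓ → degradation; anything else indeterminate. Slopes are taken
  over the **full series span by default**: a trailing-window slope was
  evaluated and rejected as the default because a fluorescence trace that
  has already collapsed to the blank floor has near-zero trailing slope
  (floor effect), which turns clear contamination/degradation runs into
  indeterminate; the window remains a parameter for change-point-style use.
  `onset_h` is the earliest time from which the final verdict's sign
  pattern holds persistently through the end of the series; confidence is
  a bounded ratio of the weaker slope to twice the flat band (a reporting
  heuristic, not a calibrated probability).
* **LED selection** — the channel minimizing |LED peak − primary
  excitation maximum|, ties toward the shorter wavelength. Only the
  primary (first-listed) maximum is used: chlorophyll a is paired with the
  451 nm LED by its 429 nm primary maximum even though the 657 nm LED lies
  nearer its 661 nm secondary maximum — matching how the physical panel
  was driven.
* **LoD** — ordinary least squares on (concentration, index), then
  `LoD = 3.3·sd(blanks)/slope` (the ICH-style convention; 3.0 is
  selectable). A brute-force empirical check is provided
  (`empirical_lod`): the smallest tested concentration whose index
  exceeds the 99th percentile of blanks in ≥ 95 % of replicates; the two
  routes agree within a factor of 2 on the default synthetic calibration.

## 5. What the simulator does and does not establish

The generator emulates the *structure* of real measurements — scattering
proportional to particle density, weak Stokes-shifted emission, detector
saturation and noise, OD blind to scatterer identity — with intentionally
simple parametric forms: Gaussian lineshapes, wavelength-flat scattering
within a band, first-order kinetics with invented (config-exposed, not
biologically claimed) photoinhibition parameters. Passing tests therefore
demonstrate that the *pipeline* is correct and that the decision rules
recover the scenario classes under realistic noise; they do not calibrate
any physical instrument. In particular the LoD computed on synthetic
calibrations (~1 cell/µL under default noise) characterizes the virtual
detector's noise floor, not an achievable limit for any real device, which
is dominated by optical alignment, fiber coupling and biological
variability that are outside this model. Radiative-transfer/Mie
scattering, photobleaching, temperature and nutrient dynamics, and
multi-species spectral unmixing are out of scope.

## 6. Problem sizes used in the test suite

The package's own verification uses desk-scale runs chosen to exercise
every code path with comfortable statistics: 24 h simulated runs at 60 min
rounds on the phycocyanin channel; 100 seeded runs per scenario for the
recovery rates; 1 000 randomized spectra for the linearity/invariance
sweeps; an 11-point 0–500 cells/µL calibration with 20 blanks, and
150–400 replicates per concentration for the empirical-LoD cross-check.
OD is sampled at 5 s cadence in live runs and more coarsely in batch
experiments, where the analysis only consumes OD interpolated at round
times.
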