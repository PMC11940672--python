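# phycowatch

Fluorescence monitoring of cyanobacterial cultures in a stirred
mini-photobioreactor, as software: a virtual instrument, the dual-exposure
acquisition protocol with excitation-peak scattering normalization, and
analytics that turn fluorescence/turbidity time series into culture-state
decisions.

## The problem

Cyanobacteria are the main drivers of harmful algal blooms in reservoirs.
Their dominant autofluorescence comes from phycocyanin, the phycobilisome
pigment that absorbs around 620–630 nm and emits near 650–657 nm, so the
phycocyanin emission band is the natural optical handle for monitoring a
culture. The standard in-vessel observable, near-infrared optical density
(OD), is blind to *what* is scattering: a contaminated culture and a healthy
one can produce the same rising OD trace. Watching phycocyanin fluorescence
alongside OD resolves the ambiguity — and also reveals physiological damage
such as photoinhibition, where excess light degrades the phycobilisomes and
the emission peak is progressively lost.

Measuring weak fluorescence in a dense, stirred colloid has a confound of
its own: the 90° collection fiber also receives directly scattered
excitation light, and that contribution grows with particle density. The
protocol implemented here tackles it with **two exposures per excitation
LED** in every measurement round:

* a **short capture** (0.1 s) in which the scattered excitation line stays
  below detector full scale and can be quantified;
* a **long capture** (5 s) in which the excitation line saturates but the
  pigment emission band is well resolved.

Exploiting detector linearity in exposure time, the two are combined into a
scattering-corrected **fluorescence index**

```
index = (∫ fluorescence band, counts·nm / s, long capture)
        ─────────────────────────────────────────────────
        (∫ excitation band,   counts·nm / s, short capture)
```

which cancels the density-dependent scattering (and any common detector
gain), leaving a quantity proportional to emitted fluorescence per unit
scattered excitation.

## What the package contains

| module | contents |
|---|---|
| `phycowatch.spectra` | `Spectrum`/`Band` containers; saturation masking, band integration, exposure normalization, parabolic peak refinement, the fluorescence index |
| `phycowatch.simulate` | optical forward model (LED lines, excitation/emission overlap, linear scattering, shot + read noise, saturation) and culture dynamics for growth, photoinhibition and contamination scenarios |
| `phycowatch.reactor` | the simulated instrument backend (simulated clock, job state, optical mutual exclusion) |
| `phycowatch.acquisition` | measurement rounds with guaranteed job-state restoration, and the scheduled monitor loop |
| `phycowatch.analytics` | series normalization, Theil–Sen trend classification (healthy / degradation / contamination), excitation-LED selection, limit-of-detection estimation |
| `phycowatch.config`, `phycowatch.persist`, `phycowatch.cli` | validated YAML run configuration, CSV/JSON run artifacts, command-line verbs |

Only the simulated backend is shipped; a physical reactor would implement
the same `InstrumentBackend` protocol on top of real drivers.

## Worked example

Monitor a simulated culture that becomes contaminated by a non-fluorescent
invader, then classify the trend:

```bash
$ phycowatch monitor --scenario contamination --hours 24 --interval-min 60 \
                     --seed 7 --out demo
completed 24 rounds, 24 pairs -> demo

$ phycowatch analyze trend --run demo --no-plot
{
 "confidence": 0.9211898634600861,
 "fluor_slope_per_h": -0.028298143826963072,
 "fluor_slope_sign": -1,
 "label": "contamination",
 "od_slope_per_h": 0.018423797269201722,
 "od_slope_sign": 1,
 "onset_h": 12.0
}
```

OD rose (+1.8 %/h of its initial value) while the phycocyanin index fell
(−2.8 %/h of its initial value): the growth seen by turbidity is not the
target organism — the contamination signature. `demo/` holds every spectrum
(`spectra/round000_615nm_short.csv`, …), `fluorescence_index.csv`,
`od_readings.csv` and the run log.

Pick the excitation channel for a fluorophore (nearest LED to its primary
excitation maximum):

```bash
$ phycowatch select-led --fluorophore chlorophyll_a
chlorophyll_a: LED 451nm (peak 451 nm)
```

Estimate the detection limit from a simulated dilution series:

```bash
$ phycowatch calibrate --out demo-cal --seed 1
$ phycowatch analyze lod --calibration demo-cal/cal.csv --blanks demo-cal/blanks.csv
{
 "blank_sd": 1.2870545020674244e-05,
 "factor": 3.3,
 "intercept": 0.0022032425418181817,
 "lod_cells_per_ul": 1.120198666042706,
 "n_blanks": 20,
 "n_points": 11,
 "r_squared": 0.9994191098122318,
 "slope": 3.791541612727273e-05
}
```

`lod_cells_per_ul` is 3.3 × blank standard deviation / calibration slope —
the lowest cell density distinguishable from blank vials under the virtual
instrument's noise model (see `docs/methods.md` for why this number is a
property of the simulator, not of any physical device).

## Documentation

The model, its assumptions, parameter defaults and known limitations are
described in [`docs/methods.md`](docs/methods.md).
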