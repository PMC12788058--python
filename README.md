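# wspri

Simulation and signal-processing toolkit for **wavelength-modulated surface
plasmon resonance imaging (SPRi)** with a discrete multi-LED light source.

Label-free SPR biosensors read out binding events as a shift of the
resonance wavelength (RW) — the wavelength of minimum p-polarized
reflectance of a prism / metal-film / analyte multilayer in the Kretschmann
configuration. Imaging variants replace the spectrometer with a camera and a
handful of monochromatic LEDs: five channels at 730, 740, 756, 777 and
805 nm cover a 75 nm window, and an **adaptive second-order fitting (ASF)**
tracker reconstructs the RW from only three intensity samples per cycle,
switching between three overlapping LED triples as the resonance drifts.
This package implements the full computational chain for that instrument
class, end to end, with no hardware required:

* `wspri.dispersion` / `wspri.optics` — dispersive multilayer permittivity
  models and the transfer-matrix p-reflectance `R_p(λ)`, plus dense-grid RW
  extraction and the surface-plasmon phase-matching diagnostic
  `|Re k_SP − k_x|`, where

  `k_SP = (2π/λ) √(ε_m ε_d / (ε_m + ε_d))`  and  `k_x = (2π/λ) n_p sin θ`;

* `wspri.acquisition` — the five-LED bank, the three fitting bands
  (730–756, 740–777, 756–805 nm) with trigger-band overlaps and switching
  thresholds at 740/756 nm, discrete (optionally noisy, optionally
  finite-linewidth) sampling, and the scan-cycle timing model
  `n × (t_LED + t_exposure)`;

* `wspri.asf` — the tracker: exact five-point quartic initialization, exact
  three-point parabola fits with clamping at the band edges, band-switching
  with blue-shift mirrors, convergence in ≤ 3 fits, and per-ROI time-series
  tracking into tidy sensorgram DataFrames;

* `wspri.metrics` — calibration analytics: OLS sensitivity `S` (nm/RIU),
  baseline noise RMS, refractive-index resolution `σ_RI = RMS / S`, limit of
  detection `LOD = 3 δ_N / S`, dynamic range, net shift, and the NaCl
  concentration→RI conversion (13 % w/v ↔ 0.0241 RIU);

* `wspri.synth` — a synthetic six-channel flow-cell imaging generator
  (16-bit multi-page TIFF stacks) driven by staircase or 1:1 Langmuir
  binding RI time courses, for closed-loop testing of the whole pipeline;

* `wspri` CLI — `simulate`, `synth`, `track`, `report`.

## Worked example

Sweep the analyte refractive index in 0.002-RIU steps across the LED window
and compare the dense-grid ("true") RW with the sparse ASF reconstruction:

```sh
$ wspri simulate -o out/sim
true slope 4828.95 nm/RIU, ASF slope 5183.14 nm/RIU, relative error 7.33%
```

`out/sim/rw_table.tsv` holds one row per RI with columns
`ri, true_rw_nm, asf_rw_nm, band_id, clamped`, and `out/sim/spectra/`
the reflectance spectra. The two slopes are the wavelength sensitivities of
the sensor (≈ 4.8–5.2 × 10³ nm/RIU for a 48 nm gold film in this window);
their 7 % gap is the band-dependent fit bias discussed in the methods note.

Render a synthetic two-channel staircase experiment, track it, and compute
the calibration report:

```sh
$ wspri synth --scenario examples/scenario_staircase.yaml -o out/frames
wrote 39 frames x 5 LEDs to out/frames
$ wspri track --frames out/frames -o out/sensorgram.tsv
wrote sensorgram (78 rows) to out/sensorgram.tsv
$ wspri report --sensorgram out/sensorgram.tsv \
      --calibration examples/calibration.yaml -o out/report
roi: ch1
x_unit: RIU
slope: 6256.9301486501
intercept: 0.4964260520127928
r_squared: 0.9814654189683322
baseline_rms_nm: 1.1368683772161603e-13
rir_riu: 1.8169746987848886e-17
blank_sd_nm: 0.0
lod: 0.0
```

This demo scenario is noise-free, so the baseline RMS and the derived
refractive-index resolution collapse to numerical zero; the slope is the
local sensitivity recovered from the three staircase levels, and the
non-zero intercept and r² < 1 reflect the tracker's deterministic fit bias
rather than noise. With the default noise model
(`noise_sd: 0.00067`, calibrated to a 0.014 nm tracked baseline RMS) the
report returns a finite RIR of order 10⁻⁵–10⁻⁶ RIU.

Every command writes a `run_log.txt` with the package version, config
digests and seed, so a run can be reproduced from its log alone.

## Configuration formats

Layer stacks, LED banks, scenarios and ROI maps are YAML (see `examples/`);
optical-constant tables are 3-column text (`wavelength_nm  n  k`, packaged
defaults: `au_nk` for evaporated gold, `cr_nk_synthetic` for the chromium
adhesion layer); sensorgrams and sweep tables are TSV with header rows.
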