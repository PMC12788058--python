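# Methods

## Forward model

The sensor is a planar multilayer in the Kretschmann geometry: a coupling
prism (default constant index 1.785, optionally SF11 Sellmeier dispersion),
a 2 nm chromium adhesion layer, a 48 nm gold film, and a semi-infinite
aqueous analyte. p-polarized reflectance is computed with the standard 2×2
characteristic-matrix method using the TM admittance `q_j = k_z,j /(k_0 ε_j)`
per layer. Conventions: time dependence `exp(−iωt)`, so passive media have
`Im ε ≥ 0`; the normal wavevector takes the decaying branch `Im k_z ≥ 0`;
angles are degrees at the API surface and radians internally; wavelengths
are nanometres throughout. An independently coded recursive Fresnel cascade
(Parratt recursion, in the test suite) agrees with the matrix method to
≤ 10⁻¹⁰ absolute over thousands of randomized stacks; for a lossless
incidence medium the reflectance obeys `0 ≤ R_p ≤ 1`, and only rounding
overshoot ≤ 10⁻⁹ above 1 is clamped (a lossy incidence medium may
legitimately reflect more than unity and is left untouched).

Gold optical constants default to a packaged evaporated-gold `(λ, n, k)`
table (Johnson–Christy-style values, linear interpolation, no
extrapolation); a smooth Drude fit (`ε_∞ = 9.84`, `ħω_p = 9.01 eV`,
`ħγ = 0.072 eV`) is available as an analytic alternative. The chromium
table is a synthetic fixture of representative evaporated-Cr magnitudes —
through a 2 nm layer it perturbs the resonance by well under a nanometre,
so only its order of magnitude matters. Every simulated result is traceable
to the dispersion models named in the stack config.

The **resonance wavelength (RW)** is the wavelength of minimum reflectance
at fixed angle, located by a dense-grid argmin (default 0.01 nm step)
refined by three-point parabolic interpolation; ties resolve to the smaller
wavelength, and a minimum on the search boundary raises an error (the dip
is outside the window). On the default stack at 51.2° the water dip sits
near 784 nm and red-shifts by ≈ 4.8 × 10³ nm/RIU; note that the
phase-matching wavelength (zero of `|Re k_SP − k_x|`) sits ~15 nm blue of
the reflectance minimum — the familiar offset of a lossy coupled resonator
— so the residual is a diagnostic, not a substitute for the dip search.

## Acquisition model

Five LEDs at 730/740/756/777/805 nm (an instrument convention for this
window; the slightly uneven spacing widens the red bands where sensitivity
is higher). Sampling is a delta function at the center wavelength by
default — the tracker's own idealization — with an optional Gaussian line
profile (profile-weighted mean reflectance via Gauss–Legendre quadrature
over ±3σ) for realism studies. Noise is injected at sampling as additive
zero-mean Gaussian intensity noise, seeded, with a floor at zero counts.
Cycle timing is `n × (t_LED + t_exposure)` with defaults 2 ms + 33 ms:
105 ms for a three-wavelength tracking cycle, 175 ms for a five-wavelength
full scan.

Three overlapping bands partition the window: Band 1 = LEDs 1–3 (fit range
730–756 nm), Band 2 = LEDs 2–4 (740–777 nm), Band 3 = LEDs 3–5
(756–805 nm). Band selection uses half-open intervals [730, 740), [740,
756), [756, 805] so every RW maps to exactly one active band; the overlaps
740–756 and 756–777 nm are trigger bands in which two triples can both
resolve the RW, which is what makes hand-over stable.

## The adaptive second-order fitting tracker

All fits are exact interpolations — three points determine the parabola,
five the quartic — because point counts equal parameter counts; solves are
done in centered coordinates for conditioning (vertex recovery of a
generating parabola is exact to ≤ 10⁻⁹ nm).

1. **Initialization**: one five-LED scan; the exact quartic through the
   five samples is minimized over [730, 805] (interior derivative roots
   with positive curvature compete with the endpoints; lowest fitted value
   wins, ties to the smaller wavelength; an endpoint winner is flagged
   clamped).
2. **Tracking**: each cycle fits the active triple. An upward parabola
   with its vertex inside the band's fit range yields the RW; otherwise the
   estimate clamps to the fit-range endpoint with the lower fitted
   intensity (the downhill direction) and is flagged. Collinear samples are
   flagged degenerate and clamp the same way rather than erroring
   mid-experiment.
3. **Switching**: the estimate re-selects the band (≥ 756 → Band 3,
   ≥ 740 → Band 2, else Band 1; mirrored for blue-shifts so rinse phases
   track). A clamp at the *lower* edge of the active band's fit range
   forces a step down one band — without this rule a Band-3 tracker whose
   dip moved below 756 nm would read exactly 756 nm and re-select Band 3
   forever. Convergence stops when a step leaves the band unchanged, capped
   at three fits; with three totally ordered bands at most two switches
   occur per convergence call, and further switches in a cycle are
   suppressed.
4. **Time series**: per-ROI tracker states are carried forward;
   initialization runs once per ROI and again after more than three
   consecutive clamped estimates (the dip may have jumped). All-zero
   frames are flagged missing, never fabricated. Sensorgrams are tidy
   DataFrames (`time_s, roi_id, rw_nm, band_id, clamped, missing`) written
   as TSV.

### Measured accuracy, and the gap to the idealized figures

On an ideal parabolic dip the tracker is exact. On the physical Fresnel
dip it is not: the dip of a 48 nm gold film is deep (near-critical
coupling) and skewed, and over a 26–49 nm LED triple the cubic content of
`R_p(λ)` biases the exact three-point vertex. Measured noise-free against
the dense-grid truth on the default stack, the bias is ±1–4 nm for
interior estimates and up to ~8 nm where dips near the window edges clamp
to a band boundary; the envelope asserted in the unit suite is 9 nm with a
mean of ~3 nm. The bias is band-dependent (its sign flips across switch
thresholds), which puts the ASF-vs-true sensitivity slopes ~7 % apart over
a full-window sweep and caps closed-loop staircase linearity near
r² ≈ 0.99. The idealized figures often quoted for this instrument class —
0.5 nm recovery in the band-switching worked example, 0.2–0.5 % slope
agreement, r² > 0.999 — are reproduced only by a near-symmetric idealized
dip model, not by the full multilayer realization; the acceptance suite
asserts them at face value and the corresponding tests fail by design,
documenting the gap. No standard gold model closes it: a
Johnson–Christy-style table, Drude fits with bulk or film-grade damping
(ħγ = 0.072–0.30 eV), dropping the Cr layer, SF11 prism dispersion, and
finite LED linewidths (FWHM up to 35 nm, which worsens the bias by
red-shifting the effective minimum) were all evaluated. Because the bias is
deterministic and slowly varying, it calibrates out of relative
measurements — which is how such instruments are used in practice.

## Sensitivity sweep

The sensitivity simulation steps the analyte index on the 0.002-RIU grid
anchored at n = 1.333 and keeps the grid points whose dense-grid dip lies
inside the LED window (seven points, n = 1.323…1.335, for the default
stack — where on the grid the window falls depends on the gold model,
which shifts the RI intercept but not the slope). OLS regressions of true
and ASF RW on RI give the two sensitivities; the default stack yields
≈ 4.83 × 10³ (true) and ≈ 5.18 × 10³ (ASF) nm/RIU.

## Calibration metrics

Sensitivity `S` is the OLS slope of RW response against RI or
concentration (r² is the squared Pearson correlation). The
refractive-index resolution is `σ_RI = RMS / S`, with the RMS taken about
the window mean of a quiet baseline segment (no detrending beyond mean
removal; ≥ 10 samples required). The limit of detection is `3 δ_N / S`
with `δ_N` the blank-channel standard deviation. Net shift is the
difference of window means before and after a reaction. Both `σ_RI` and
LOD are exactly homogeneous: doubling the noise doubles them, doubling the
slope halves them. NaCl concentration converts to RI linearly at
0.0241/13 ≈ 1.854 × 10⁻³ RIU per % w/v, anchored at the 13 % ↔ 0.0241 RIU
endpoint (standard refractometry agrees to ~2 significant figures).

The **dynamic range** estimator scans the analyte RI (default 5 × 10⁻⁴
steps), runs the noise-free tracker at each point, and reports the widest
contiguous RI interval over which `|ASF − true| ≤ tolerance`. The
signature's default tolerance of 0.5 nm expresses the idealized accuracy
and yields a near-empty interval on the Fresnel model; at the package's
measured 9 nm envelope the default configuration gives 0.015 RIU, and the
identity (range × sensitivity ≈ usable wavelength span: 0.015 × 4830 ≈
72 nm ≈ the 75 nm LED span) holds. The CLI report uses the 9 nm envelope.

## Synthetic imaging generator

The generator renders per-LED 16-bit frames of a six-channel flow cell
(defaults mimic 1 mm-wide parallel channels on a ~10 × 7.5 mm field):
each ROI pixel carries the forward-model reflectance of the stack with
that channel's instantaneous analyte index, background pixels a fixed
non-resonant level (0.85 full scale), full scale = reflectance 1.0,
round-half-even quantization, per-pixel additive Gaussian noise, all
deterministic under the scenario seed (bit-identical stacks on re-render).
RI time courses are piecewise-constant staircases or a 1:1 Langmuir model

`Δn(t) = R_max · C/(C+K_D) · (1 − e^{−(k_on C + k_off)(t−t_on)})`,

with exponential `k_off` decay after the rinse, continuous at the switch
(`K_D = k_off/k_on`; parameters chosen so association plateaus within a
few hundred seconds, like a typical antibody–antigen run). The default
pixel noise (6.7 × 10⁻⁴ of full scale) is calibrated so that tracking a
quiet water baseline in Band 1 with a ~160-pixel channel ROI gives a
0.014 nm RW RMS — the noise floor of a well-behaved bench system; Band-3
baselines track ~4× quieter because the wider LED spacing stiffens the
parabola vertex against intensity noise.

What the generator does *not* emulate: optical blur and fixed-pattern
noise, prism image distortion, unequal LED powers (frames are rendered at
equal power, so flat-field normalization is available but unnecessary by
default), mass-transport-limited kinetics, temperature drift, and surface
chemistry variability. Closed-loop tests therefore demonstrate the
correctness of the tracking and analytics chain, not the performance of
any physical instrument.

## Problem sizes

Default test and acceptance runs use dense grids of 0.01 nm over the 75 nm
window, sweeps of ~7 RI points, 10³ randomized oracle comparisons, and
synthetic stacks of ≤ 100 frames at 48 × 64 pixels — sizes chosen so the
full suite runs in seconds while every code path is exercised end to end.

## Known limitations

* The tracker's skew bias (above) is intrinsic to exact three-point
  parabola fits on realistic dips; a least-squares fit over more samples or
  an asymmetric dip model would reduce it but is outside this package's
  scope.
* Tabulated dispersion uses linear interpolation between rows; with the
  packaged gold table (~50–65 nm row spacing in the NIR) this leaves small
  curvature kinks at row boundaries.
* The NaCl→RI conversion is a linear anchor, adequate to ~2 significant
  figures over 0–13 % w/v.
* s-polarization, angular interrogation, phase modulation, rough or graded
  interfaces and near-field effects are out of scope.
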