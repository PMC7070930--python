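# Methods

## The measurement this package models

Micromechanical thermal analysis (MTA) deposits pico- to nanogram amounts of
sample on resonating silicon-rich nitride microstrings and tracks each mode's
resonance frequency f and quality factor Q during a slow heating ramp in a
medium vacuum. The resonance follows temperature through tensile-stress
relaxation (here linearized as c_T, default −30 Hz/°C); a sample passing its
glass transition redistributes effective mass through viscous flow, detuning
the resonance, and damps the string, dipping Q before the liquefied sample
lets Q rise sharply above its baseline.

The temperature-modulated variant superimposes a small sinusoid
(±`amp_T` = 0.2 °C, period `P` = 20 s) on the linear ramp
(`rate` = 1.6 °C/min from `T0` = 30 °C), in direct analogy to modulated DSC.
At the heater the program is a PWM duty cycle
`DC(t) = k_s + k_l·t + A_mod·sin(2πt/P)`; the duty→temperature map is treated
as linear over the narrow working range, so the simulator works directly in
temperature space with the realized settings above. Sampling is `dt` = 0.2 s,
matching the ~200 ms acquisition of a single vibrometer spectrum.

## Deconvolution

Given a raw modulated trace x(t):

1. **Underlying signal (UFS)** — first-order Savitzky–Golay filter whose
   window is the odd sample count nearest one period (101 samples at
   P/dt = 100). An order-1 fit reproduces constants and ramps exactly and
   attenuates the period-P sinusoid to ≈1/window (≈1%); endpoints are handled
   by polynomial edge fitting so the output keeps the input length and the
   identity `raw = ufs + periodic` holds exactly.
2. **Periodic part** — `raw − ufs`.
3. **Upper envelope** — magnitude of the FFT-constructed analytic signal,
   smoothed with the same one-period filter. The same operator applied to the
   temperature trace yields the temperature-modulation envelope TS_ue.
4. **Reversing signal** — `RS = P_ue / (TS_ue · P / 2π)`. For a purely linear
   response f = c·T this is the constant |c|·2π/P (9.42 s⁻¹-units at
   |c| = 30 Hz/°C, P = 20 s); any process that changes the response per degree
   of modulation — the glass transition — appears as a local RS maximum,
   independent of slow drifts. RS units are left as the ratio defines them;
   only peak locations are interpreted.

The first and last filter window of every derived series carries edge
artifacts and is flagged (`edge_samples`); detectors skip it.

**Modulation-transfer check.** `dominant_period` verifies that the applied
period appears in a trace: linear detrend, unit-variance normalization, Hann
taper, FFT magnitude, and the maximum over components completing at least 10
cycles in the record. The cycle floor matters: the glass-transition detuning
step contributes more low-frequency energy than the few-Hz modulation line,
but a component that does not repeat is drift, not periodicity.

## Transition detection

* **Tg_F** — local maxima of RS with prominence ≥ `prominence_frac` (default
  0.2) × (max − median), and at least one modulation period wide at half
  prominence (the RS cannot resolve anything faster; narrower bumps are
  envelope noise). The first maximum is Tg_F; more than one sets the
  `multiple-maxima` flag — later maxima can mark the dynamic transition, a
  strong effective-mass change, or a prominent-mode switch, and the package
  flags rather than interprets.
* **Tg_Q** — on the one-period-smoothed Q trace: the most prominent local
  minimum, when one exists; otherwise (the dip is not always pronounced, the
  upward shift always is) the intersection of the pre-rise baseline tangent
  with the maximum-slope tangent of the rise (`rise-onset`).
* **UFS onset and Δf** — classical tangent construction: a baseline line is
  fit to the first quarter of the samples and intersected with the tangent at
  the point of strongest slope deviation; Δf is the maximum deviation of the
  UFS from the extrapolated baseline. The onset is reported absent when the
  strongest local slope deviates from the baseline slope by less than
  `slope_change_frac` (default 0.5) of its magnitude — the faint-detuning
  regime in which only the reversing signal localizes the transition. A
  two-segment least-squares breakpoint was evaluated for this detector and
  rejected: on a completed step (line–ramp–line) its SSE-optimal breakpoint
  falls mid-to-post transition rather than at the onset.
* Note on semantics: the simulator's `tg_static` is the *midpoint* of the
  logistic detuning step, which is where RS peaks; an onset estimator
  necessarily reports ≈2 step widths earlier. Tg_F, not the UFS onset, is the
  calibrated locator.

## The signal simulator

Per tracked mode (`ModeSpec`: id, harmonic n, responsivity, baseline offset):

    f(t) = f_n(load) + c_T·(T(t) − T0) + r·D(T(t)) + ε,   ε ~ N(0, noise_f²)

with T(t) the modulated ramp — evaluating the full response on the modulated
temperature is what transfers the modulation into the frequency trace — and
D(T) a logistic detuning step of depth `detune_total` (default 300 Hz,
clearly visible over noise_f = 0.5 Hz) centred at `tg_static` = 45 °C with
width `step_width` = 1 °C; `two_step` adds an equal second step at
`tg_dynamic` = 50 °C, emulating the two-fold frequency change seen when mass
redistribution continues through liquefaction. Mode responsivity scales the
step: local mass responsivity goes as the squared local amplitude
(sin²(nπx)), and mixed (torsion-involved) modes respond more strongly than
pure flexural ones for the same deposit.

The quality factor is `q0 − dip + rise + ε`: a Gaussian dip (depth
`q_dip` = 400, width = step_width) centred at `tg_dynamic` and a logistic
rise (`q_rise` = 600) set two step widths later, so the minimum stays
pronounced, lies within one step width of `tg_dynamic`, and is followed by
the sharp shift to higher values. With these shapes the detected
Tg_Q − Tg_F offset across replicates recovers the embedded 5 °C split.

**Load model and mass estimate.** The unloaded ladder is exact, f_n = n·f1.
A deposit of effective (mode-weighted) load m scales the resonance by the
exact inverse of the distributed-load mass approximation

    m_sample = π·m0·(f0² − f_res²) / ((π+2)·f_res²),

so `estimate_sample_mass(loaded_mode_frequency(...))` round-trips to machine
precision; each particle contributes mass·sin²(nπx) to the mode-n load
(full weight at an antinode — the reference distribution of the estimate —
none at a node).

## Image simulation and contour tracking

The frame simulator renders particles as anti-aliased bright disks
(512×128 px at 1.5 px/µm, i.e. a 50 µm string ≈ 75 px wide) whose projected
area follows shrink-then-spread through the transition: a 5% area loss
(densification) completing ~6 °C before a 60% overshoot (liquefaction
wetting), each particle lagged by 0.2 °C per µm of diameter — bigger
particles heat through later. Radii scale as the square root of the area
factor; only the 2D projection is modeled (no PSF, no contact-angle physics).

Analysis segments frames at a fixed threshold — background (median gray) plus
half the distance to the median foreground, both from the first frame — and
bins connected components by equivalent diameter 2√(area/π)/scale into the
three contour levels [0, 5), [5, 10), [10, ∞) µm. Level membership is
anchored to the first frame: later components inherit the class of the
first-frame component they overlap, because a spreading particle that crosses
a class edge mid-transition would otherwise abandon its series (components
with no first-frame counterpart are binned by their own diameter). Per-level
pixel counts are smoothed with the one-period filter; each level's area
minimum (in the central window, absent for monotone series) marks its
shrink-to-spread crossover, and the minima order by particle size — smaller
particles track the instantaneous Q response most closely.

## Mode-shape analysis

Grid-overlay measurements (default 23×3 = 69 points; a 7×3 = 21-point
low-resolution variant) sample the complex amplitude over the string. The
shape is rotated to the real axis (global-phase and scale invariant);
harmonic order is 1 + the sign changes of the width-averaged profile along
the string (samples below 5% of peak ignored); torsional involvement —
"mixed" modes — is flagged when the amplitude spread across width rows
exceeds 0.3× the peak (indeterminate for single-row grids). The prominent
mode is the registered mode nearest the largest spectral magnitude in a
band; switches are label changes persisting ≥ `debounce_n` = 3 samples.

## Synthetic scenarios

Registered, seed-deterministic bundles drive every stage end to end:
`indomethacin_default` (full dual signature), `two_step`, `low_mass` /
`low_mass_494` (single antinode particles back-solved to 433/494 pg, 15 Hz
detuning — below the 50 Hz "pronounced" threshold, yet RS still peaks at
45 °C), `large_mass` (900 Hz, two steps), `mode_switch` (crossing spectral
magnitudes with an injected persistent switch), and `four_mode` (flexural
1.1/3 at 163/489 kHz plus mixed 1.2/2 with markedly larger detuning).
Default problem sizes — 1500 s traces at 0.2 s (7 501 samples), 81-frame
movies at 0.5 °C steps, 12 replicates for the offset statistic — run the
full pipeline in about a second per scenario.

## What the generator does and does not emulate

Passing tests show the pipeline recovers what the generator embeds:
modulation transfer, envelope calibration, a logistic detuning at 45 °C, a
Q dip/rise at 50 °C, lagged shrink-spread particle areas, idealized string
mode shapes. Real measurements differ in ways the generator does not model:
1/f drift and temperature-calibration error, non-logistic relaxation
kinetics (the real transition shape depends on thermal history), optical
blur and uneven illumination, particle overlap and irregular shapes,
spectrum-tracking dropouts near mode crossings, and the heater's actual
duty→temperature dynamics. Absolute Tg values from real samples therefore
cannot be validated here — only the signal-processing chain and its
calibration are.

## Numerical choices

SG windows are forced odd (nearest odd to P/dt, ties up); envelope values
are clipped non-negative after smoothing; RS samples with non-positive
temperature envelope are NaN-masked and logged; detector ties break toward
lower temperature (onset semantics); rendered gray values are clipped to
[0, 255] after rounding; all noise comes from a single seeded
`numpy.random.default_rng` stream per simulation, so identical
(seed, config) give bit-identical output.
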