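# mta-kit

Temperature-modulated **micromechanical thermal analysis** (MTA) in Python:
simulation, signal deconvolution, dual glass-transition detection, particle
image tracking, and resonator mode-shape analysis — no instrument required.

MTA heats pico–nanogram samples deposited on resonating microstrings and
tracks resonance frequency *f* and quality factor *Q* through a thermal ramp.
This package implements the temperature-modulated variant: a sinusoidal
modulation (±0.2 °C, period *P* = 20 s) superimposed on a 1.6 °C/min ramp is
deconvolved — in direct analogy to modulated DSC — into

* the **underlying frequency signal** (UFS): first-order Savitzky–Golay
  filter, window = one modulation period;
* the **periodic part** and its Hilbert-transform **upper envelope** P_ue;
* the **reversing signal** RS = P_ue / (TS_ue · P / 2π), where TS_ue is the
  temperature-modulation envelope.

The glass transition then shows two distinct signatures: **Tg_F**, the first
prominent RS maximum (the quasi-static onset), and **Tg_Q**, the
quality-factor minimum or rise onset (the dynamic, liquefaction signature),
with Tg_Q consistently above Tg_F. Supporting analyses track per-size-class
particle pixel areas through their shrink-then-spread minima, classify
flexural vs. mixed (torsion-involved) mode shapes from grid-overlay
amplitude measurements, and estimate sample mass from the resonance shift of
a loaded string, m = π·m0·(f0² − f²)/((π+2)·f²).

A seeded simulator generates complete synthetic measurements — modulated
temperature, per-mode frequency and Q traces, microscope frame stacks, mode
grids — with known embedded ground truth, so the whole pipeline is testable
end to end. See `docs/methods.md` for the model details.

## Worked example

```sh
mta simulate --scenario indomethacin_default --seed 1 --out sim --frames
mta deconvolve --input sim/trace.csv --period 20 --out deconv.csv
mta detect --deconv deconv.csv --trace sim/trace.csv --period 20 --out report.json
mta image-track --frames sim/frames --index sim/frames/index.csv --scale 1.5 --out areas.csv
```

`report.json` from this exact run contains (abridged):

```json
{
  "tg_f_C": 45.10,
  "rs_maxima": [{"temp_C": 45.10, "prominence": 23.4}],
  "tg_q_C": 50.06,
  "tg_q_method": "minimum",
  "ufs_onset_C": 43.00,
  "delta_qf_C": 4.96,
  "detuning_Hz": 304.1,
  "flags": []
}
```

The reversing signal locates the static onset at 45.1 °C (the scenario
embeds it at 45 °C), the quality factor puts the dynamic transition at
50.1 °C (embedded at 50 °C), and their difference, ≈5 °C, is the
static/dynamic split of the glass transition. The maximum frequency
detuning recovered from the UFS is ≈304 Hz against an embedded 300 Hz step,
with the UFS slope-change onset at 43.0 °C. `image-track` prints the
per-level area minima (here level 2 at 46.8 °C, level 3 at 48.7 °C),
ordered by particle size — smaller particles respond closer to the
instantaneous Q signature.

The same works in Python:

```python
from mta import make_scenario, deconvolve, build_report

m = make_scenario("indomethacin_default", seed=1).simulate()
d = deconvolve(m, "1", P=20.0)
report = build_report(d, m.quality["1"])
print(report.tg_f, report.tg_q, report.delta_qf)
# 45.13 50.06 4.92
```

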