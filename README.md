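# mrbscan

Simulation and quantitation toolkit for **electrophoresis titration (ET)
sensing with a scanning contactless-conductivity detector**.

In ET sensing, an analyte (e.g. glucose) is enzymatically converted into a
charged species (the crystal-violet cation, CV⁺) that migrates into an
electrophoresis channel and is neutralized by counter-migrating hydroxide.
The *moving reaction boundary* (MRB) formed where they meet advances at a
velocity V_MRB that grows linearly with the logarithm of the analyte
concentration — the boundary's speed **is** the analytical signal.  A pair of
capacitively coupled contactless-conductivity (C⁴D) electrodes translated
along the channel converts the spatial conductivity profile σ_E(x) into a
time-domain trace

σ_D(t) = Σₖ f(k) · σ_E(x_start + v_scan·t + offsetₖ),

where f is the sliding-window response of the electrode pair.  The boundary
appears as a trough in each scan; tracking the trough across timed scans
gives V_MRB, and the calibration V_MRB = a·log₁₀C + b inverts to a
concentration.

The package provides, for people developing or validating such instruments
without hardware in the loop:

- **forward model** — analytic diffuse-boundary conductivity profiles
  σ(x,t) = σ₁ + (σ₂−σ₁)/2·(1 + erf((x−Ut)/(2√(Dt)))) with optional
  leading-edge depletion/accumulation structure, the sliding-window detector
  response (trapezoidal, differential or delta), and a conservative 1-D
  Nernst–Planck finite-difference solver with the CV⁺ + OH⁻ neutralization
  reaction;
- **signal processing** — baseline-scan subtraction, moving-average
  filtering, and boundary localization by the derivative-interval (gradient)
  method, the trough position, or the trailing-edge (t₂) convention;
- **quantitation** — V_MRB from position-vs-time OLS, log-linear
  calibration with r², inverse prediction, LOD (k·SD convention), RSD and
  spike recovery;
- **synthetic experiments** — seeded generator reproducing the bench
  protocol (first scan at 7 min, 2-min interval, 4 scans, 1.0 mm/s over a
  24 mm channel) with a parameterized noise model, plus negative controls.

## Worked example

`examples/locate_boundary.py` generates a four-scan experiment for a 10 mM
sample and runs the full signal chain:

```
scan clock (min)   boundary fix (mm)   true position (mm)
          7.11              9.93               9.75
          9.14             11.59              11.40
         11.17             13.31              13.04
         13.20             14.98              14.69

fitted V_MRB = 0.8318 mm/min (r2 = 0.99996); true U = 0.8220 mm/min
```

Each fix sits ~0.2 mm ahead of the true boundary center — a constant
geometric offset from the window response and the depletion dip — but the
offset cancels in the slope, so the fitted velocity matches the configured
one to ~1% even with noise on every sample.  `examples/calibrate_and_quantify.py`
continues to the seven-point calibration (r² = 0.9999, per-concentration
velocity RSD ≤ 0.6%) and inverse-predicts an unknown; `examples/simulate_and_scan.py`
and `examples/nernst_planck_front.py` show the raw detector physics and the
first-principles reaction-front simulation.

A thin CLI wraps the same library for shell use:

```
mrbscan simulate --out sim/ --seed 1
mrbscan detect   --traces sim/ --baseline sim/baseline.csv --method trough --out fixes/
mrbscan calibrate --points calibration.csv --out cal/
mrbscan quantify --traces sim/ --baseline sim/baseline.csv --model cal/model.yaml --out report/
mrbscan recover  --spiked 100 --found 89.1
```

Every CLI run writes a JSON manifest (config hash, seed, package version) so
runs are reproducible bit-for-bit.

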