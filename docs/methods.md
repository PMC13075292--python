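# Methods

This note documents the models behind `mrbscan`, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions.

## Physical picture and units

An electrophoresis channel (24 mm long, 200 µm × 100 µm cross-section,
x = 0 at the anode-side entrance) carries a moving reaction boundary (MRB):
behind it lies the titrated CV⁺ zone with conductivity σ₁, ahead of it the
background electrolyte with σ₂ > σ₁.  The boundary center migrates toward
the cathode at U mm/min; U is log-linear in the analyte concentration.
Interface units are bench units — positions in mm, electrophoresis time in
min, boundary velocities in mm/min, scan speed in mm/s — while all physics
(mobilities, diffusion coefficients, conductivities) is SI internally.

## Conductivity models

**Kohlrausch law.** σ = F·Σᵢ μᵢcᵢ over all ionic species, with unit charge
magnitudes assumed for every species in this chemistry (K⁺, Na⁺, Cl⁻,
acetate, OH⁻, CV⁺).

**Diffuse boundary (analytic).** The concentration front of the titrant is
the advected–diffused step c(x,t) = c₀(1 − erf((x−Ut)/(2√(Dt)))).  The
conductivity step is implemented in the asymptote-consistent form

σ(x,t) = σ₁ + (σ₂−σ₁)/2 · (1 + erf((x − x_c(t))/(2√(Dt)))),  x_c(t) = x₀ + U·t,

which tends to σ₁ far behind and σ₂ far ahead of the boundary with midpoint
(σ₁+σ₂)/2 at x_c.  (A common shorthand writes the step as
σ₁ + (σ₂−σ₁)/2·erf(·); its asymptotes σ₁ ± (σ₂−σ₁)/2 contradict the zone
definitions, so the consistent form is used and noted here.)  The
boundary-formation offset x₀ accounts for the boundary forming at the
solution–gel interface rather than at x = 0 at clock zero.

**Leading-edge structure.** Real titration fronts develop a localized
low-conductivity depletion zone just ahead of the boundary (slow ion
replenishment plus OH⁻ depletion), optionally followed by an
anion-accumulation bump.  These are modeled as parameterized Gaussian
perturbations centered ahead of x_c — a deliberate phenomenological choice,
since only their qualitative shape is known.  The depletion dip is what
makes the scanned signature a *trough* rather than a monotone ramp, and the
trough is what both localization algorithms key on.

**Nernst–Planck solver.** A conservative explicit finite-difference scheme
advects each species at its signed electromigration velocity (upwind fluxes)
and diffuses it with its own coefficient; the CV⁺ + OH⁻ neutralization is
applied per cell and per step, either instantaneously (limiting reagent) or
at a capped rate k·[CV⁺][OH⁻]·dt.  Flux-form updates make no-flux runs
conserve mass to round-off; stability bounds (advection number ≤ 1,
diffusion number ≤ 0.5) are checked up front and violations name the bound.
Default ion parameters are literature limiting mobilities/diffusivities
shipped in `data/ion_defaults.yaml` (the CV⁺ values are order-of-magnitude
estimates for a bulky triarylmethane cation); all are overridable.

## Detector response

The electrode pair (2.5 mm actuator, 1.5 mm gap, 2.5 mm pick-up) is modeled
as a discretized sliding-window function:

- `unipolar_trapezoid` (default): non-negative, unit-sum weights ramping up
  across the actuator, flat over the gap, down across the pick-up.  This
  reproduces the single-trough boundary signature.
- `bipolar_differential`: ±rectangles over the two electrode footprints
  (antiparallel pick-up wiring); integrates to zero.
- `delta`: single-point sampling; the trace is exactly the profile resampled
  along the scan path (used as an identity check).

Whether a real detector is better described as unipolar or differential is
not derivable from geometry alone, so both are provided; the default is the
one that matches the observed single-trough signature.  During one scan the
generator lets the boundary keep migrating (each sample is evaluated at its
own electrophoresis clock); `freeze_boundary_during_scan=True` restores the
stationary-boundary idealization, which is accurate to ~0.25 mm per scan at
the default velocities but biases the fitted velocity by ~0.8% because
detection times then no longer correspond to boundary positions.

## Boundary localization

All methods operate on baseline-subtracted (pre-run background scan,
linearly resampled onto the trace grid — no warping) and moving-average
filtered traces:

- **gradient** (default): forward-difference time derivative; global maximum
  (earliest on ties); the maximal contiguous run with derivative ≥ −tol
  (tol = 0 by default) containing that maximum; the run's first sample is
  the detection time.  For a trough signature this is the trough bottom,
  where the signal turns back up.
- **trough**: global minimum of the filtered signal (earliest on ties).
- **t₂**: trough time mapped to the trailing window edge (boundary position
  when the pick-up has fully cleared it), i.e. trough position minus half
  the window support.

All three differ by near-constant geometric offsets, which cancel in the
velocity fit; gradient is the default, and the choice is exposed because the
conventions genuinely coexist in practice.  A configurable quality floor
(derivative peak height / trough depth) marks weak fixes invalid; the series
pipeline keeps at most the first four valid fixes and requires at least
three.

The moving-average filter is edge-truncated (symmetrically shrinking
window), keeping output length equal to input length without fabricating
data.  The 5-point default matches the bench convention, but a point count
only has meaning relative to an acquisition rate: at the generator's 100 Hz
it spans 0.05 mm of scan path, which barely suppresses noise.  The
calibration workflows therefore smooth over 2.5 mm of scan path (251 samples
at 100 Hz / 1 mm/s) — roughly half the ~6 mm trough width, i.e. a
near-matched filter for the feature being localized.  With the 5-point
filter the trough argmin wanders ~0.1 mm under 2% noise; with matched-scale
smoothing ~0.02 mm, which is what brings replicate velocity RSDs into the
~1% regime that bench instruments report.

## Quantitation

V_MRB is the OLS slope of fix position (mm) against electrophoresis clock
(min), n ≤ 4 by the first-four-valid-peaks rule, n ≥ 3 required.  The
calibration is unweighted OLS of V_MRB on log₁₀(C/mM); base 10 is chosen
(standard in analytical calibration), so the slope has units mm·min⁻¹ per
decade.  Replicate velocities are averaged per concentration before the
calibration fit; RSD is reported on the raw replicates with the n−1 sample
SD.  Inverse prediction is C = 10^((v−b)/a), flagged when outside the fitted
range.  LOD uses the inverse prediction of v_blank + k·SD(blank) with k = 3
by default — the convention is parameterized because conventions differ.
Spike recovery is 100·found/spiked reported to one decimal; of the published
reference rows, 100·89.1/100 = 89.1% and 100·376.8/350 = 107.7% reproduce
exactly, while the middle row's printed 98.6% disagrees with its own printed
inputs (100·147.8/150 = 98.5% at one decimal), so it is excluded from exact
checks.

## Synthetic experiments: what they emulate, and what not

The generator reproduces the bench protocol: an independent background scan
of the boundary-free channel, then unidirectional scans at 1.0 mm/s starting
at 7 min on the electrophoresis clock, every 2 min, four scans (all within
the 16 min run), detector window always inside the channel.  Velocities
follow U = a·log₁₀C + b and the generator rejects configs whose boundary the
detector could not catch (|U| ≥ scan speed).  Scan return time is idealized
to instantaneous.

Defaults (chosen once, at design time): σ₁/σ₂ = 0.08/0.10 S/m (a 20%
conductivity step on a ~10 mM acetate background), D = 1×10⁻⁹ m²/s,
depletion dip 0.08 S/m deep × 1.0 mm wide centered 0.5 mm ahead of the
boundary (the dip dominates the signature, as observed signals do), DAQ rate
100 Hz (lock-in C⁴D outputs are kHz-class; 100 Hz keeps files small at
0.01 mm per sample), white noise SD 4×10⁻⁴ S/m = 2% of the conductivity
step.  The velocity law keeps the measured slope a = 0.272 mm/min/decade;
the intercept b = 0.55 mm/min and offset x₀ = 4 mm are chosen so that all
seven calibration concentrations (0.2–50 mM) give boundaries that advance
and stay inside the scannable window for the whole schedule.  (Taking the
published intercept of −0.011 literally would imply a stationary or
retreating boundary below ~1.1 mM, for which a replicate velocity RSD of ~1%
is arithmetically impossible — so the intercept is treated as
dataset-specific rather than physical.)

The noise model (white + optional low-order polynomial drift + rare spikes;
drift and spikes off by default, magnitudes placeholders) exercises
robustness but does not emulate real C⁴D noise spectra, channel-to-channel
variability, gel inhomogeneity, scan-speed jitter, or the enzymatic
incubation chemistry (concentration enters only through the effective U).
Passing tests therefore demonstrate correctness of the algorithms and
self-consistency of the pipeline under the stated noise model — not
instrument-level performance on real hardware.

## Numerical conventions and edge cases

- Ties in argmax/argmin resolve to the earliest index.
- Forward differences define the derivative so a run's "starting point" is
  well defined at the run's first index.
- Flat traces raise a no-boundary error; fixes below the quality floor are
  flagged, not silently dropped from the schedule (they simply don't count
  toward the four).
- Profiles validate uniform, strictly increasing grids; traces validate
  uniform sampling and positive scan speed.
- Seeded streams are spawned per trace via `SeedSequence`; negative controls
  use a distinct spawn domain so they never share noise with the experiment
  generated from the same seed.
- The scaled-down problem sizes used throughout (2401-point spatial grids,
  ~1750-sample scans, 3 replicates, 101-cell solver grids) were chosen so a
  complete workflow runs in seconds on one core.

## Known limitations

- The depletion/accumulation zones are phenomenological Gaussians, not
  solutions of the coupled electromigration problem; the Nernst–Planck
  module produces the step but not the full measured leading-edge shape
  (that would require electroneutrality coupling and field feedback, out of
  scope here).
- The detector window is a 1-D weighting function; no capacitive circuit or
  2-D field modeling.
- The gradient locator degrades gracefully but noticeably under heavy noise
  (its derivative statistics are noise-amplifying); the trough locator is
  the robust choice for quantitation, and is what the calibration workflow
  uses.
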