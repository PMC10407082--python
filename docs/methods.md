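# Methods

`suctionsim` is an in-silico test bench for ventricular suction under
continuous-flow left ventricular assist device (LVAD) support.  It couples a
closed-loop lumped-parameter circulation to an HVAD-like rotary pump through a
collapsible apex segment, generates device telemetry the way a clinical
controller reports it, and scores a beat-level suction detector against the
simulator's own ground truth.  This note records the model, its assumptions,
the calibration strategy, and the known limitations.

## Circulation model

The circulation has eight volume compartments: four time-varying-elastance
chambers (LV, LA, RV, RA), systemic arterial and venous beds, and pulmonary
arterial and venous beds.  Valves are diode resistances; vascular beds are
resistance-compliance elements with explicit unstressed volumes.  Every flow
moves volume between two compartments, and the pump path withdraws from the
LV apex and returns to the systemic arterial node, so total blood volume is
conserved to machine precision by construction.

Ventricular pressure blends two curves with a periodic double-Hill activation
`a(t)` (normalized to peak at exactly 1; systolic fraction ≈ 0.3 of the
cycle, 0.37 for the dilated phenotype whose longer ejection this calibration
required):

* end-systolic: `P_es = Ees · (V − V0) · V/(V + V_sat)`.  The factor
  `V/(V + V_sat)` (V_sat = 8 mL) is a low-volume saturation making the ESPVR
  curvilinear: the local slope at operating volumes still equals the
  configured `Ees`, but an emptying ventricle loses its pressure-generating
  capacity.  This term is essential: the restrictive phenotype's printed
  end-systolic point (13 mL at ~100 mmHg) forces a negative linear-ESPVR
  volume intercept, and without saturation an *empty* chamber would still
  generate full systolic pressure — depleted-state pulsatility would never
  collapse, contradicting the Frank-Starling behaviour the bench must show.
* end-diastolic: `P_ed = S · (exp(k (V − V0_ed)) − 1)`, with `k` fixed in
  closed form by the anchor `P_ed(V30) = 30 mmHg`.  The EDPVR volume
  intercept `V0_ed` may differ from the ESPVR intercept (standard in PV-loop
  modelling); for the restrictive profile it is the mechanism that lets
  diastolic pressure cross below zero when the chamber is overdrained.

Chamber pressures are floored at −20 mmHg for solver robustness; the floor is
only approached in deeply drained states after the collapse dynamics have
engaged.

Two phenotype profiles ship with the package.  Published quantities (heart
rate 78 bpm; LV `Ees` 0.4 / 3.3 mmHg/mL; `V30` 210 / 95 mL; the baseline
target hemodynamics) are fixed; every other parameter (vascular resistances
and compliances, unstressed volumes, right-heart and atrial elastances,
total blood volume, ESPVR/EDPVR intercepts and scales) is a free calibration
constant fit so the closed loop supported at 2,800 rpm reproduces the target
hemodynamics: DCM — CO 4.7 L/min, mean arterial pressure 84 mmHg, wedge
12 mmHg, EDV/ESV 183/154 mL; RCM — CO 5.0 L/min, wedge 7 mmHg, EDV/ESV
67/13 mL.  The shipped defaults land all of these inside the bench's
acceptance bands (±0.25 L/min, ±2 mmHg, ±5 mmHg on mean pressure, ±10 mL on
DCM volumes, ±7/±5 mL on RCM volumes).

## Pump, motor and telemetry

Hydraulics use the standard quadratic head map
`ΔP = a0 ω² + a1 ω q + a2 q²` (ω in rpm, q in L/min), fit to be flat over
the operating range as centrifugal pumps are, with the head at (2,800 rpm,
DCM operating flow) matching that profile's aortic-minus-ventricular
gradient plus cannula losses.  Flow through the inflow/outflow cannulae is a
state with inertance; the impeller obeys
`J dω/dt = k_t I − c_q q ω − b ω`, with a PI speed controller (anti-windup
clamped) holding the setpoint.  The beat-mean speed stays within ±5 rpm of
the setpoint, while the intra-beat excursion is the dynamic signature the
detector features use: a biphasic dip-then-rise of several tens of rpm in
filled states, and a transient rise of order +100 rpm when a collapse event
unloads the impeller.  Inertia and gains were tuned jointly to those two
signatures.

The device does not measure flow; it *estimates* it.  The reported flow
channel inverts the motor torque balance from current and speed, then passes
through a causal 4th-order low-pass (0.55 Hz) and an asymmetric slew-rate
limiter (−1.25 / +1.2 (L/min)/s), mimicking how controller firmware smooths
and rate-limits the displayed estimate.  These reporting dynamics are not
cosmetic: they set the scale of the flow-slope feature and are the main
calibration lever for the detector's published feature dispersion.  Beat
means of the reported flow track true flow within 1 % in steady non-suction
states (after a ~2-beat filter warm-up).  Hemodynamic channels are recorded
at 1,000 Hz; pump channels are decimated to 50 Hz with a 20-sample
block-average anti-alias filter.

## Suction module

The apex segment is a transmural-pressure-dependent inflow restriction.  Its
collapse fraction `c ∈ [0, 1]` relaxes (engage τ = 20 ms; release 6× slower)
toward a steep sigmoid of ventricular pressure centred at the 0-mmHg
collapse threshold, and the inflow resistance blends linearly from
`r_open` = 0.06 to `r_collapsed` = 3.0 mmHg·s/mL.  On top of the sigmoid sits
a hysteretic latch (a Schmitt trigger): a crossing below the threshold
drives the tube fully shut, and it releases only once chamber pressure
recovers above threshold + 0.1 mmHg.  The latch reflects the actuated
character of a physical squeeze chamber; without it, the sigmoid's own
negative feedback settles into a partial-collapse equilibrium with chamber
pressure regulated at ~0 mmHg and no discrete suction events ever occur.
With it, the bench produces the reported event morphology: an end-systolic
apex-pressure spike far below chamber pressure, a flow notch with recovery,
and the +100 rpm speed transient.

The ground-truth label for a beat is TRUE iff the collapse fraction exceeded
0.5 (the open/collapsed midpoint, configurable) at any sample in the beat
window.  The two phenotypes collapse for different reasons, matching their
reported flow patterns: the dilated ventricle empties completely and crosses
the threshold at end-systole (flow spike followed by a plateau), while the
restrictive ventricle keeps ejecting — its stiff diastolic chamber is sucked
below the EDPVR intercept between beats (a preserved systolic flow pulse
above the collapsed baseline).

## Protocols

`run_steady` integrates to a periodic steady state (beat CO and EDV changing
< 0.5 % over three consecutive beats; convergence error after 200 beats) and
then records.  `hypovolemia_ramp` withdraws 2 % of the baseline blood volume
per stage from the stressed venous compartments (systemic and pulmonary, in
proportion to their stressed volume), records 15 beats per stage after a
5-beat settle, and stops at the first stage with at least one ground-truth
suction beat AND a 50-Hz reported-flow peak below 2 L/min.  `full_protocol`
runs both profiles over the speed grid [2,500, 2,800, 3,000] rpm and pools
the segmented, labelled beats, trimming to per-profile quotas (183/19 and
168/21 suction/non-suction) round-robin across speeds in ramp order.  The
grid stays inside the 2,500–3,200 rpm study range; the 3,200-rpm endpoint
was excluded from the default grid because at that speed the baselines are
so unloaded that their telemetry pulsatility overlaps the suction class and
no threshold set can separate them (the package will happily run it if
configured).  With the default protocol the dataset holds roughly 170
suction and exactly 40 non-suction beats.

Everything is integrated with a fixed-step RK4 scheme at dt = 0.5 ms,
recorded on an exact 1-kHz grid.  A fixed step (rather than an adaptive one)
buys bit-exact determinism — identical config and seed reproduce identical
records — and keeps the stiffest time constants (valve resistance against
peak elastance, ≈ 1.5 ms) comfortably inside the stability region.  Optional
zero-mean telemetry noise (off by default, seeded) is available for detector
robustness studies.

## Detection pipeline

Beats are segmented from the 50-Hz reported flow at the minima of a lightly
smoothed copy (7-sample moving average, 0.3-s refractory, prominence gate);
windows are contiguous and half-open, and a flat signal yields zero beats
with a warning.  The beginning of diastole is marked at the smoothed-flow
crest (the onset of the post-systolic decline).  Three features per beat:

* `dqdt_min` — minimum two-point slope of the raw reported flow [L/min/s];
* `d_omega_min` — minimum of speed minus beat-median speed [rpm];
* `t_dqdt_max` — timing of the maximum positive flow slope, normalized to
  the cycle from the diastole-start landmark, wrapped into [0, 1).

The classifier is a fixed-order 3-split tree (flow slope, then speed
pulsatility, then timing); equality at a threshold classifies as suction —
the conservative choice for a safety-relevant detector.
`calibrate_thresholds` grid-searches quantile candidates maximizing balanced
accuracy.  The shipped default thresholds (−0.925 L/min/s, −35 rpm, 0.93)
were chosen inside the class gaps of the full-protocol calibration dataset
to represent the clinically-determined character of a deployed detector; on
that dataset they score 88.7 % sensitivity, 95.0 % specificity, and 81.2 %
of detected suction beats exiting at the first split.  (The balanced-accuracy
optimum itself over-calls suction, at 96.4 % sensitivity / 100 %
specificity.)

## What the synthetic data do and do not show

The generator reproduces the *mechanism* structure of bench data: two
phenotype archetypes, a controlled hypovolemia exposure, clean telemetry
with device-like reporting dynamics, and a ground-truth flag that is exact
by construction.  It does not emulate clinical variability: no arrhythmia or
heart-rate drift, no cannula malposition (suction occurs only on complete
ventricular emptying), no Lavare-style speed modulation, no sensor drift,
and class distributions far tighter than clinical recordings.  Passing
detector statistics here therefore demonstrates internal consistency of the
bench, not clinical performance.

Known quantitative limitation: the pooled suction-beat timing median
computes to ≈ 0.71 rather than the reported ≈ 0.97.  At 50 Hz, a flow notch
sharp enough to pin the max-positive-slope sample against the diastole-start
landmark implies a slope magnitude of roughly 25× its depth, which is
incompatible with the gentle suction slope scale (≈ −0.4 L/min/s) unless the
reported flow is smoothed so heavily that the notch detaches from the beat
landmark altogether.  The class *ordering* of the timing feature (suction
later than non-suction) is preserved, and the other four per-class medians
land on the reported values.

## Numerical and design choices

* Units: mmHg, mL, s internally; rpm for speed (rad/s inside torque math).
* EDPVR stiffness from its anchor in closed form:
  `k = ln(1 + 30/S) / (V30 − V0_ed)`.
* Steady-state detection operates on whole beats; summaries (CO, pressures,
  EDV/ESV, wedge as beat-mean left-atrial pressure) use whole beats only.
* Collapse fraction is clamped to [0, 1] after each step; the latch updates
  once per time step from current chamber pressure.
* Beat quotas select round-robin across pump speeds in ramp order, so every
  speed contributes and baseline beats fill the non-suction quota first.
* Degenerate inputs: flat telemetry → zero beats (warning, not an error);
  zero-variance samples in the normality gate → Mann-Whitney fallback with a
  warning; absent classes → explicit undefined-metric errors.
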