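# Methods

## Circuit model

Each patient is a single-compartment linear lung obeying the equation of
motion `P_aw = R·Q + V/C + PEEP`, with compliance `C` (mL/cmH₂O) and
resistance `R` (cmH₂O/L/s). Two branches share one source in a 1 + 1 split:
the *standard* branch is unrestricted; the *variable* branch carries a
needle-valve flow restrictor on its inspiratory limb only (one-way check
valves route expiration around it), so the variable branch's inspiratory
resistance is `R_lung + R_valve(turns)` and both branches exhale through
`R_lung` alone.

**Valve map.** Handle turns-from-closed map to resistance by exponential
interpolation, `R(t) = r_min · (r_closed/r_min)^(x^shape)` with `x` the
fractional closure: exactly `r_min` at full open, exactly `r_closed` at full
closure, strictly decreasing in between. `shape = 2` (default) concentrates
the change near closure, matching the steeply nonlinear near-closed
behaviour of needle valves. `r_closed` is finite by design: a fully "closed"
restrictor still passes air so the restricted patient is never completely
occluded. Defaults: 6 turns full travel, `r_min = 1`, `r_closed = 200`
cmH₂O/L/s.

**Pressure control.** The source pressurises from PEEP toward the set PIP
with a first-order rise (`rise_time`, default 0.15 s — the pressurization
ramp that is a front-panel setting on ICU ventilators) and each branch
responds independently; expiration is passive decay to PEEP. With
`rise_time = 0` the drive is an ideal square wave and the branch flow is the
textbook exponential `Q(t) = ΔP/R · e^(−t/RC)`, which the unit tests check
against the closed form. The default is non-zero because an ideal step
produces a flow *discontinuity* that no physical ventilator produces, and
whose interaction with a 0.25 s median filter is pathological: the median
replaces the leading half-window of a jump-then-decay pulse with its
end-of-window value, discarding up to a third of the pulse area when
`RC ≪` window. A finite rise restores a continuous flow onset, which the
median filter passes essentially unchanged.

**Volume control.** The source delivers the set total volume as a constant
total inspiratory flow, divided between branches at every time step in
inverse proportion to instantaneous branch impedance (inspiratory resistance
plus elastic back-pressure `V/C`); check valves clamp branch flow at zero.
This reproduces the defining mode contrast: a pressure source isolates the
patients (valve sweeps leave the standard patient's tidal volume unchanged
to numerical precision), while a volume source couples them (volume removed
from the variable patient appears at the standard patient, the per-breath
total being conserved exactly by construction).

**Integration.** Fixed-step explicit Euler at the configured sample rate
(default 2000 Hz, the acquisition rate of the transducers the chain is
designed for). Per-segment the affine recurrence is evaluated in closed form
(vectorised; `scipy.signal.lfilter` for the time-varying drive), so the
cost is linear and the 2 kHz step error is negligible against the ≥0.2 s
time constants involved. Ground truth per breath — onset, end-inspiration,
delivered volume (volume at end-inspiration minus at onset), instantaneous
rate, spontaneous label — is recorded in a sidecar table.

## Artifact model

Two artifact classes are superimposed after the physics, both seeded
(`numpy.random.default_rng`; identical config + seed ⇒ bit-identical
output):

- **Transducer noise**: zero-mean Gaussian, default SD 0.02 L/s, for which
  ≳99% of samples fall below the 0.08 L/s floor the analysis chain removes.
- **Spontaneous breaths**: half-sine flow pulses (200 mL over 0.4 s)
  inserted late in randomly chosen expiratory phases (at 80% of the breath
  period). The placement is deliberate: with instantaneous rate defined as
  60 / (gap to next onset), an effort at phase 0.8 has a rate of 5× the set
  rate (far beyond the 30% exclusion band) while the preceding mechanical
  breath's rate rises only to 1.25× (within the band), so the ground-truth
  labels coincide exactly with what the rate rule can recover.

## Analysis chain

Order is fixed: noise-floor zeroing → median smoothing → segmentation /
integration. Choices where the chain's description left room:

- **Noise floor** (default 0.08 L/s) is two-sided on |flow| (expiratory flow
  is negative on the same transducer) and strict: samples exactly at the
  floor are retained.
- **Median window** (default 0.25 s) is `round(window · fs)` samples forced
  odd (501 at 2 kHz) so the centre is unambiguous; at the series ends the
  window shrinks symmetrically rather than padding — the filter never
  invents data. Interior samples use pandas' rolling median; edge samples
  are computed directly.
- **Integration** is trapezoidal (second-order accurate); tidal volume is
  the integral over one breath interval, in mL.
- **Segmentation**: a breath is a run of positive flow following a run of
  non-positive flow, with a 25 ms hysteresis (configurable) so sub-floor
  chatter at the crossings neither splits nor spawns breaths.
- **Instantaneous rate** is the first difference of breath-onset times,
  `60/Δonset`, assigned to the earlier breath; a patient's final breath has
  no defined rate and is never flagged spontaneous.
- **Exclusions** (volume < 90 mL; rate more than 30% from the set point) are
  strict inequalities, and are *flags*, not deletions, so summaries can
  report how many breaths each rule removed.
- **Record alignment** uses half-open windows `[t_k, t_{k+1})` on entry
  timestamps (last entry extends to the end of the recording); breaths are
  assigned by onset. Summaries use the sample (n−1) SD, reported missing
  below two breaths. Dynamic compliance is `TV/(PIP − PEEP)` with the
  entry's pressures. Tidal-volume ratios are ratios of per-entry means (the
  two patients' breaths are not synchronised, so per-breath pairing is not
  defined).
- **Calibration** supports both turn conventions seen in practice
  (turns-from-open on the bench, turns-from-closed at the machine) with an
  explicit tag and conversion. Normalisation divides each quantity by its
  own fully-open value (not the sweep maximum — the unrestricted patient can
  legitimately sit above 100%), and is idempotent. The control range runs
  from the first handle position where delivery departs from the open value
  (default 1% band) to full closure.

## Default study conditions

The generator's defaults are the conditions the rest of the package is
validated under: compliances 20 (standard) and 50 (variable) mL/cmH₂O;
lung resistance 10 cmH₂O/L/s for both (the canonical intubated-adult value —
endotracheal tube plus airways); PIP 25 / PEEP 5 cmH₂O in pressure control;
1200 mL total per breath in volume control (a lossless 50/50 open split of
600 mL per patient); 12 breaths/min with inspiratory fraction 0.33 (I:E
1:2); 2 kHz sampling; noise SD 0.02 L/s. Recovery figures quoted by the
acceptance script use 20-breath (100 s) runs; mode-contrast sweeps use 15 s
runs at 7 valve positions — sizes at which every quantity is already stable
to well inside its tolerance.

## What the generator does and does not emulate

It emulates: quasi-periodic ventilator-driven flow for two patients of
differing compliance, the mode-dependent branch coupling, a monotone
turns→resistance restrictor with finite closed-state leak, low-amplitude
transducer noise, and off-schedule spontaneous efforts. It does **not**
emulate: nonlinear (flow-dependent) resistance, inertance, heterogeneous or
time-varying lung mechanics, gas exchange, circuit compliance or leaks,
ventilator trigger/cycling logic, or more than two branches (the interfaces
permit n branches but only 1 + 1 is exercised). Passing recovery tests on
this generator therefore demonstrates the chain's correctness on idealised
single-compartment waveforms, not its robustness to every pathology of real
spirometry.

## Known limitations

- A flow pulse that decays below the 0.08 L/s floor before inspiration ends
  loses `τ·(0.08 − Q_end)` of volume to the floor — a property of the
  analysis chain itself, visible in pressure-control runs with short time
  constants. The volume-control waveforms the chain is primarily validated
  on keep branch flow above the floor for the whole inspiration, where the
  deterministic bias is under 1%.
- Dynamic compliance recovered through the chain (`≈48.6` for a true 50
  mL/cmH₂O lung at Ti = 6.6·RC) carries that same small floor bias plus the
  `1 − e^(−Ti/RC)` truncation of the delivered volume.
- Breath assignment to record entries is by onset; breaths spanning an entry
  boundary contribute wholly to the entry containing their onset.
- The two exclusion rules act on integrated volume and onset-interval rate
  only; flow-shape-based effort detection is out of scope.
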