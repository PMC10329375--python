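# Methods

## The physical model

The simulator treats the respiratory system as one passive compartment
behind a resistive airway, ventilated through a circuit with compressible
volume. Symbols and units: pressures cmH2O, volumes mL, flows L/s,
resistance `Rrs` cmH2O/(L/s), compliances mL/cmH2O.

State variables are the Y-piece pressure `Paw` (the circuit node) and the
alveolar volume `V`. The static recoil relation `P_alv = P(V)` is either
linear (`V = Crs·P`) or bilinear with a lower inflection point (`C_below`
up to the LIP, `C_above` beyond it — the poorly-recruited-lung shape).
Flows obey

```
Ccirc · dPaw/dt = 1000·(Q_vent − Q_lung),     Q_lung = (Paw − P_alv)/Rrs,
dV/dt           = 1000·Q_lung,
```

with `Q_vent` the delivered flow (constant during insufflation, zero during
the occlusion) and, during expiration, an exhalation valve path of
resistance `Rexp` toward set PEEP (default `Rexp = Rrs`).

**Airway closure** is a single opening-pressure threshold `AOP`: while
closed, `Q_lung = 0` and all delivered gas charges `Ccirc`, so `Paw` climbs
linearly at `Q_vent/Ccirc` — the steep first slope both methods rely on.
The airway opens the instant `Paw` reaches `AOP` (opening is modeled as
instantaneous; the threshold is sharp) and re-closes during expiration when
`P_alv` decays to `AOP`, trapping gas at that pressure. That trapping is
what makes the maneuver repeatable: every insufflation re-opens the airway
at the same pressure. An `AOP` at or below PEEP never closes and is treated
identically to a closure-free system.

### Integration

A fixed-step scheme (1 kHz, decimated to the 100 Hz output rate that a
ventilator data stream realistically provides) advances `Paw` with an
exponential update toward its instantaneous asymptote (alveolar pressure
frozen within the step), and takes the lung-volume increment as the residual
of the volume balance. Two consequences: gas volume is conserved to machine
precision at every step, and the scheme remains stable for arbitrarily small
`Ccirc`, so the stiff limit can be compared directly against the closed-form
constant-flow solution `Paw(t) = PEEP + Rrs·Q + Q·t·1000/Crs` (agreement
< 0.05 cmH2O; tested). The phase-A→B transition is located exactly within a
step rather than on the grid. Sensor noise is additive Gaussian on the
sampled pressure only (flow is left clean), seeded.

The waveform's volume column is defined as the cumulative trapezoid of the
*sampled* flow — what a bedside logger would compute — so it is
self-consistent at any sampling rate; the conservation property is asserted
on the integrator's internal states instead, where it is exact.

### Bench scenarios and ventilator settings

Three shipped scenarios: `aop10` (closure at 10 cmH2O), `control1` (linear,
no closure), `control2` (bilinear, LIP 10, compliances 20/40), all with
`Rrs` 10 and `Ccirc` 2 mL/cmH2O (a typical adult circuit; the value is
configurable). Constant-flow breaths default to 60 L/min, tidal volume
420 mL, occlusion 0.4 s, rate 12/min — the rate is chosen low enough that
expiratory flow reaches zero across the whole mechanics range the cohort
draws from, mirroring the clinical rule of lowering the rate until no
intrinsic PEEP is visible. The low-flow maneuver uses 5 L/min at 5
breaths/min.

## The detectors

Both methods replace a clinician's visual reading with deterministic
exhaustive least-squares fits; all constants live in `DetectionConfig`.

**Onset and occlusion.** Insufflation onset is the first sample with flow
above 2 L/min sustained for 3 samples; the occlusion is the span with
|flow| < 0.5 L/min after insufflation and must last ≥ 0.3 s for a valid
plateau. Residual flow above 2 L/min at the last pre-insufflation sample
flags intrinsic PEEP, which marks the result unreliable (the AOP formula
assumes total PEEP = set PEEP) without changing the computation.

**Peak and plateau.** The plateau is the mean pressure over the final
0.1 s of the occlusion. The peak is obtained by fitting a line to the last
~80 ms of insufflation and evaluating it at the end of the last flow-on
sampling interval: the pressure ramps to the very last insufflation
instant, so a raw sample maximum both undershoots the true peak (up to one
sample of ramp) and, under noise, rides the upper order statistic.

**Low-flow (standard) method.** A continuous two-segment piecewise-linear
fit over the whole insufflation, breakpoint searched exhaustively on the
sample grid (ties take the earlier index). A break qualifies as closure
when (i) its local one-vs-two-segment SSE ratio is ≥ 5 — evaluated over a
window around the break, because residuals summed over the long featureless
remainder of a 5-s maneuver would dilute the evidence; (ii) the first/second
slope ratio is ≥ 5 — the first slope of genuine closure is the circuit
charging slope, an order of magnitude above any lung slope, whereas a
bilinear PV curve can only produce ratios near `C_above/C_below`; and
(iii) the break pressure exceeds PEEP by more than 1 cmH2O. The AOP is the
break pressure itself (and so includes the small resistive offset
`Rrs·Q ≈ 0.8 cmH2O` at 5 L/min — the bench closure model reads 11 for a
true opening pressure of 10, as expected).

**Constant-flow (conductive-pressure) method.** After the break, the
pressure does not bend into the elastic ramp instantly: it approaches it
exponentially with the circuit–lung time constant `τ = Rrs·Ceq`
(`Ceq = Ccirc·Crs/(Ccirc+Crs)`, ~20 ms here). A plain second line fitted
through that transient drags the break pressure down by an amount growing
with `τ` (up to several cmH2O for stiff, resistive lungs), so the
post-break segment is modeled as `A + B·(t−tb) + C·e^{−(t−tb)/τ}` with
`C ≤ 0`. The time constant is not fitted freely — that is badly
conditioned on noisy 100 Hz data — but anchored on the breath's own
physics, `τ ≈ P_res / (charging slope)`, with two candidate forms (one
exact when a closed phase exists, one inverting the first-interval rise
when it does not) arbitrated by residual. The fit window is short (0.15 s)
to keep mid-insufflation features such as a compliance inflection out of
the fit, and is extended (up to 0.3 s) only when the added samples remain
statistically consistent with the same line-plus-exponential — a
mid-insufflation bend fails that check and keeps the window short.

The reported break pressure is the asymptote evaluated at the corner
(the intersection of the charging line with the asymptote shifted down by
`P_res`). This choice makes the method exactly self-consistent: in this
model the asymptote at the corner sits above the corner point by
`Rrs·Q·(Crs/(Crs+Ccirc))²` — and the occlusion plateau, equilibrated with
the circuit, makes measured peak−plateau equal *the same quantity*. The
circuit factors cancel identically, so `P_cond − P_res` estimates
`AOP − PEEP` with no correction factors, for any circuit compliance.
Detection and the AOP value then follow the clinical rule verbatim; raw
values are kept and the reported AOP is rounded to 1 cmH2O (half-up),
matching clinical reporting.

## The synthetic cohort

Real validation recordings are not public, so `aopkit.cohort` emulates a
passive ARDS cohort: closure prevalence 0.26; opening pressures lognormal
(`μ = ln 9.85`, `σ = 0.30`), truncated to > PEEP + 1 (an AOP at or barely
above PEEP is undetectable by the rule itself), giving median ≈ 10.1 and
IQR ≈ 8.7–12.6 cmH2O after truncation — a two-parameter lognormal cannot
reproduce an asymmetric 9–13 IQR with median 10 exactly, so the parameters
are a quantile-matching compromise; mechanics uniform over `Rrs` 5–20
cmH2O/(L/s) and `Crs` 20–60 mL/cmH2O; pressure noise 0.3 cmH2O; both
maneuvers simulated per case at PEEP 5. Per-case seeds are spawned from the
cohort seed, so the whole pipeline is bit-reproducible.

What the cohort does *not* emulate: spontaneous effort, flow-dependent or
time-varying resistance, viscoelasticity, multi-compartment heterogeneity,
ventilator rise-time and flow overshoot, cardiogenic oscillations, or
secretions. Passing cohort-level tests therefore demonstrates correctness
of the method under its own assumptions, not bedside performance.

## Numerical and statistical conventions

- Percentage metrics are displayed rounded half-up to integers, ratios and
  the Youden index to two decimals; raw fractions are always retained.
  Undefined metrics (zero denominators) are NaN, never exceptions.
- Bland–Altman limits use the n−1 standard deviation; the differencing
  convention is carried in the report (`standard − pcond` for the method
  comparison). Spearman correlation uses average ranks for ties.
- Confusion-matrix reconstruction enumerates all integer tables with the
  stated margins and keeps those whose displayed metrics match every
  reported value; for the validation cohort's margins (213 total, 55
  positive) the printed table pins a unique matrix, (51, 4, 15, 143).
- Waveform CSV: `#`-prefixed `key=value` metadata, 6-significant-digit
  values (lossless round-trip at that precision), LF or CRLF accepted;
  timestamp rounding jitter is snapped back to the uniform grid on read
  and genuinely irregular grids are rejected with the offending row.

## Known limitations

- **Detection at `AOP = PEEP + 1` sits on the decision boundary.** The
  clinical rule is strict (`> 1 cmH2O`), so an opening pressure exactly
  1 cmH2O above PEEP yields an expected excess of exactly the threshold;
  with noise, such cases are missed in a substantial fraction of runs.
  This is a property of the rule, not of the implementation.
- **Single-breath precision.** At 100 Hz and 0.2–0.3 cmH2O noise the
  spread of the AOP estimate is ≈ 0.3–0.5 cmH2O (worst for stiff,
  resistive lungs where the knee transient is longest), so a small
  fraction of runs falls just outside ±1 cmH2O, and roughly 2–6% of
  noisy no-closure breaths cross the 1 cmH2O threshold — comparable to,
  and somewhat better than, the 91% specificity human readers achieved on
  clinical recordings. Averaging several breaths would reduce both; the
  package scores single breaths by design.
- **Bilinear lungs at low PEEP** put an inflection bend close to the fit
  region of the constant-flow method, inflating its variance (the bench
  bilinear control accounts for most of the false-positive tail above).
- The optional actual-flow correction (`flow_correction`) rescales
  `P_res` by the measured flow ratio between break time and
  end-insufflation; with the ideal constant-flow sources simulated here it
  is a no-op and ships disabled.
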