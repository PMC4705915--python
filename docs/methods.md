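# Methods

## The measurement and the model

A modified (Duffin-type) rebreathing test probes cerebrovascular CO2
reactivity: after a room-air resting baseline, the subject hyperventilates
for 3 min to hold end-tidal CO2 (PETCO2) near 18 mmHg, then rebreathes
from a bag so PETCO2 rises steadily until it reaches ~50 mmHg, all in
background hyperoxia (PETO2 > 250 mmHg) so oxygen-driven vascular tone is
constant.  Middle cerebral artery velocity (MCAv, transcranial Doppler) is
used as the cerebral blood flow index and expressed as percent change from
its resting value.

The MCAv response to PETCO2 is modelled as a logistic (sigmoid):

    MCAv% = minimum + amplitude / (1 + exp(-(PETCO2 - midpoint)/range))

* `minimum` (%) — the hypocapnic constriction floor.  It is **not fitted**:
  it is fixed to the mean MCAv% over the final 60 s of the hyperventilation
  segment, on the assumption that hyperventilation produces full
  hypocapnia-induced vasoconstriction.  `--fit-minimum` frees it for
  sensitivity analysis.
* `amplitude` (%) — total span from constriction floor to dilation ceiling.
* `midpoint` (mmHg) — the PETCO2 at the curve's center, the optimal
  operating point between the constriction and dilation reserves.
* `range` (mmHg) — the logistic width; the central quasi-linear zone spans
  roughly `midpoint ± 2·range`.

Cerebrovascular CO2 reactivity — "the slope of the linear portion" — is
reported as the analytic maximal slope of the logistic,
`amplitude/(4·range)` (%/mmHg).  The analytic identity is exact for this
model; a secondary estimator (`linear_reactivity`) regresses MCAv% on
PETCO2 over points within one `range` of the midpoint, for users who
prefer an empirical chord slope.  The two differ by a few percent on
clean data because the chord of a sigmoid is shallower than its tangent.

### Blood-pressure censoring (T_ABP)

Beyond some PETCO2, mean arterial pressure (ABP) starts rising and MCAv
becomes partly pressure-driven.  T_ABP is defined as the PETCO2 from which
mean ABP rises faster than 0.5 mmHg per mmHg CO2, found by a two-segment
linear fit of ABP on PETCO2 over the rebreathing data: every observed
PETCO2 value with at least 4 points on each side is a candidate breakpoint;
the lower segment is fitted with its slope clipped just below the 0.5
criterion, the upper segment unconstrained, and the candidate minimizing
the total SSE wins.  Ties break toward the lowest PETCO2 (conservative
censoring: when in doubt, censor more).  The threshold counts as detected
only if the upper slope exceeds the criterion; only data at or below a
detected T_ABP enter the sigmoid fit.  The two segments are fitted
independently — no continuity constraint at the breakpoint; imposing
continuity would change the estimator but not the definition, and the
unconstrained version is the simpler reading of "two straight lines above
and below".  The search is an exhaustive O(n²) grid, trivial at 1 Hz.

### Acid-base re-expression

Arterial pH converts to hydrogen-ion concentration by [H+] = 10^(9−pH)
nEq/L (the standard pH relation; the full acid-base nomogram with base
excess is not needed for any quantity computed here).  Per trial, [H+] is
regressed on PaCO2 by OLS over the protocol's arterial samples (room air,
40-mmHg clamp, hyperventilation, end-rebreathing), and that line maps the
sigmoid parameters into [H+] units: midpoint → intercept + slope·midpoint,
range → slope·range, reactivity → amplitude/(4·range_H).  Because the map
is affine in the abscissa, fitting directly against [H+] and transforming
the mmHg-domain fit are mathematically equivalent — that equivalence is
tested at 1e-6 relative.  It is also the computational content of the
acclimatization story: a leftward PETCO2 shift generated purely by a
changed [H+]–PaCO2 line vanishes in [H+] coordinates.  PETCO2 is treated
as a proxy for PaCO2 when applying the arterial line to end-tidal-domain
parameters, as the measurement convention implies; `transform_fit` exposes
an optional linear PETCO2→PaCO2 calibration hook for users with paired
measurements.

### Vascular reserves

With S the fitted sigmoid: constriction reserve = S(resting PETCO2) −
minimum; dilation reserve = S(T_ABP) − S(resting PETCO2), or
(minimum + amplitude) − S(resting PETCO2) when no threshold was reached.
Their sum never exceeds the amplitude.

### Group statistics

Per condition: mean, SD, and t-based 95% CI.  Effect size: Cohen's
d = (M1 − M2)/SD with SD of the **concatenated** data (not the
bias-corrected pooled-variance formula), labelled negligible / small /
moderate / large / very large at |d| = 0.2/0.5/0.8/1.3.  Pairwise
contrasts: Welch two-sample t-tests with Holm–Šidák step-down adjustment
(sorted ascending, p_adj(i) = 1 − (1 − p(i))^(m−i+1), monotonized) at
α = 0.05.  Conditions are treated as independent groups.  A repeated-
measures mixed model over the partially overlapping subjects would be the
more powerful analysis, but its covariance structure is a free design
choice we deliberately avoid; the simpler Welch + Holm–Šidák procedure is
conservative and fully specified.  Its family-wise error under the null is
verified by simulation (1000 replicates, 3 conditions).

## Preprocessing choices

* 1-s reduction uses left-closed bins [t, t+1); each output value is the
  arithmetic mean of the raw samples in the bin, stamped at the bin
  center; bin segment labels are decided by majority; a partial trailing
  bin is dropped.  Input already at 1 Hz passes through unchanged.
* The resting reference is the mean over the final 60 s of the room-air
  rest segment (at least 30 s required).  The averaging window length is
  a package choice — a minute of quiet baseline is the conventional
  compromise between stationarity and noise.

## The synthetic-trial generator

The generator is first-class, tested code: it is the ground-truth oracle
for every downstream stage.  Defaults describe one trial of the protocol:

| parameter | default | why |
|---|---|---|
| resting PETCO2 | 40 mmHg (SL); 28 / 23 at altitude day 1 / day 16 | normocapnia; hyperventilation-induced hypocapnia of ~12 / ~17 mmHg at altitude |
| hypocapnic plateau | 18 mmHg | protocol target |
| ramp | linear, 1 mmHg per 3 s, 18 → 50 mmHg | the protocol fixes only the endpoints; linear is the simplest monotone choice and the fit is trajectory-agnostic |
| rest / hyperventilation duration | 120 s / 180 s | enough baseline for the 60-s reference window; 3-min hyperventilation per protocol |
| resting MCAv | 60 cm/s | typical adult value; all analysis is in % units so it is immaterial |
| MCAv noise | Gaussian, SD 5 % of resting, independent per 1-s epoch | plausible beat-to-beat variability after 1-s averaging |
| ABP baseline / noise | 90 mmHg / SD 2 mmHg per 1-s epoch | typical mean pressure and variability |
| ABP upper slope | 2.0 mmHg per mmHg CO2 | CO2 breathing raises mean pressure steeply once the threshold is crossed, especially at altitude; 2–3 mmHg/mmHg is the observed order of magnitude |
| T_ABP | absent by default; 42 mmHg in the canonical threshold scenario | a few mmHg above resting PETCO2 |
| [H+]–PaCO2 lines | per-condition (intercept, slope) such that the mmHg-domain group parameters map onto the published [H+]-domain ones | internal consistency of the two reporting domains |
| sample rate | 10 Hz (any rate ≥ 1 Hz supported, incl. 200 Hz) | economy; the 1-s reduction makes the analysis rate-invariant |

Noise is drawn once per integer second and held within the second, so the
post-reduction noise level is the nominal SD regardless of raw sampling
rate — "5 % MCAv noise" means 5 % on the 1-Hz series the fit actually sees.

Two conventions make the generator the exact inverse of the analysis on
noiseless data, and both are physiological assumptions of the method
itself: the rest segment sits at the resting reference (0 % change, by the
definition of percent change), and the hyperventilation segment sits at
the full-constriction floor `minimum_pct` (the method's assumption that
hyperventilation achieves full vasoconstriction).  Consequently the
rebreathing curve does not pass through 0 % at resting PETCO2 — the
rebreathing response at a given CO2 exceeds the resting value, which is
exactly why the midpoint, not the resting point, is the curve's center.

What the generator does **not** emulate: breath-by-breath gas dynamics and
end-tidal detection, MCAv pulsatility and probe artifacts, cerebral
autoregulation dynamics, drift in the resting baseline, or subject-level
parameter heterogeneity beyond what a scenario encodes.  Passing recovery
tests therefore show that the estimators invert the assumed data-generating
process at realistic noise levels — not that the model is correct for any
particular subject.

## Numerical choices

* Sigmoid fitting: trust-region reflective bounded least squares
  (`scipy.optimize.least_squares`), bounds amplitude ∈ (0, 500] %,
  midpoint ∈ [10, 60] mmHg, range ∈ (0.1, 20] mmHg.  Bounds require the
  TRF method; for this smooth 3-parameter problem it finds the same
  minimum classical Levenberg–Marquardt would.  Initialization: amplitude
  from the observed span, midpoint at the half-span crossing, range
  4 mmHg; up to 5 restarts from jittered starts (fixed restart seed) on
  non-convergence, after which parameters are returned flagged
  `converged=False`.  An amplitude collapsed below 0.001 % is flagged as
  no-response.  r² is computed on the censored (fitted) points only.
* Breakpoint fit: lower-segment slope clipped at 0.5 − 1e-9; SSE ties
  broken toward the lowest candidate.
* Degenerate inputs raise typed validation errors: < 8 points or < 8 mmHg
  span for the sigmoid, < 10 points or < 5 mmHg span for the breakpoint,
  identical PaCO2 for the [H+] line, n = 1 groups get no CI.
* Trial CSVs are written with `%.17g` and read with round-trip float
  parsing, so read(write(x)) is bit-exact.

## Problem sizes

Recovery studies use 1-Hz trials (~400 samples; 97 rebreathing points) and
100 seeds per condition; the null simulation for the family-wise error
uses 1000 replicates of 3×7 values.  These sizes give stable Monte-Carlo
estimates (binomial SE ~0.007 on the error rate) while the full suite runs
in well under a minute.

## Known limitations

* Reactivity as `amplitude/(4·range)` is one of two defensible readings of
  "slope of the linear portion"; published group-mean reactivities are not
  exactly `amplitude/(4·range)` of the group-mean parameters (consistent
  with subject-level averaging).  Both estimators are provided.
* The Welch + Holm–Šidák group procedure ignores the repeated-measures
  structure; printed P-values from mixed-model analyses are not
  reproducible and are not a target.
* The breakpoint estimator's precision is signal-limited: with 1-s
  samples, ABP noise of 2 mmHg and an upper slope of ~2 mmHg/mmHg its
  median error is about 1 mmHg; shallower slopes widen it regardless of
  estimator.
* PETCO2 is taken as PaCO2 when applying the arterial [H+] line; the
  calibration hook exists but defaults to identity.
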