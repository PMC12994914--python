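# Methods

## Scope and design

`insom` turns a time series of melanopic irradiance at the eye
(`E_e,mel`, W m⁻²) plus a sleep schedule into simulated physiological
outcomes — subjective sleepiness (KSS), mean reaction time (vPVTRT),
plasma melatonin and circadian phase — and aggregates them into seasonal,
time-of-day metrics. It deliberately works on *scalar* melanopic
quantities: full α-opic spectral weighting from spectral power
distributions, raytraced daylight simulation and space geometry are
upstream concerns. The scenario generator exists so the entire pipeline is
exercisable and testable with no external dataset.

## The combined photobiological model

One state vector `[V_v, V_m, H, x, y, n, P, M]` — six core differential
equations plus two melatonin compartments — integrated with fixed-step
classical RK4 at `dt = 20 s` (time unit hours internally).

### Sleep–wake switch and homeostat

Mean-field voltages of the sleep-active (ventrolateral preoptic, `V_v`)
and wake-active (monoaminergic, `V_m`) populations inhibit each other
through sigmoidal firing rates `Q(V) = Q_max/(1+exp(−(V−θ)/σ))`
(`Q_max = 100 s⁻¹`, `θ = 10 mV`, `σ = 3 mV`, couplings
`ν_vm = −2.1`, `ν_mv = −1.8 mV s`). The somnogen `H` (nM) follows
`χ dH/dt = μ Q_m − H` (`χ = 45 h`, `μ = 4.4 nM s`): it rises during wake
(the wake-active population fires) and clears during sleep. Drives:
`D_v = A_v + ν_vh H + ν_vc C` (`A_v = −10.2 mV`, `ν_vh = 1 mV nM⁻¹`,
`ν_vc = −2.9 mV`) and `D_m = A_m = 1.3 mV`. In the packaged working
regime the switch is bistable; natural sleep onset occurs when rising
`D_v` annihilates the wake branch, natural wake when falling `D_v`
annihilates the sleep branch.

Two non-standard numerical choices, made deliberately:

* **Population relaxation times are 150 s**, not the ~10 s sometimes
  quoted for mean-field switch models. With the mandated 20-s RK4 step,
  10-s constants put the switch transitions at or beyond the linear
  stability limit (the effective eigenvalue during a transition includes
  the sigmoid slope times the couplings) and the integration blows up.
  150 s keeps transitions on a minutes scale — physiologically
  indistinguishable at the 20-s output resolution — and holds the
  step-refinement error (20 s vs 10 s over a week) below 2×10⁻⁴ of each
  component's amplitude.
* **Forced wake is adaptive "wake effort"**: during scheduled wake the
  monoaminergic drive is `max(A_m, V_hold − ν_mv Q_v)` with
  `V_hold = 0.5 mV`, holding the wake-active population at a waking
  voltage however high sleep pressure gets. A constant bias either fails
  under high `H` or destabilises the switch.

**Forced sleep is permissive, not imposed.** Scheduled sleep adds a
moderate sleep-permissive VLPO drive (0.8 mV — darkness, recumbency). If
the circadian wake drive is high, the switch does not reach deep sleep:
a mid-afternoon nap, falling in the circadian wake-maintenance zone, is
neuronally shallow and restores little sleep pressure, while nocturnal
sleep is deep. This is what makes the disrupted sleeper (delayed onset,
fragmented night, afternoon nap) carry visibly more homeostatic pressure
than the regular sleeper at every hour, despite similar nominal time in
bed. The behavioural `awake` flag always follows the schedule exactly —
it controls light gating (eyes closed) and output masking.

### Circadian pacemaker and photic drive

Van der Pol-type limit cycle:

    dx/dt = (π/12) [ y + γ(x/3 + 4x³/3 − 256x⁷/105) + B + N_s ]
    dy/dt = (π/12) [ B y/3 − x ((24/(f τ_c))² + k B) ]

with `τ_c = 24.2 h`, `γ = 0.13`, `k = 0.55`, `f = 0.99669`. The photic
drive is `B = G α (1−n)(1−b_x x)(1−b_y y)` with `G = 37`,
`b_x = b_y = 0.4`, photoreceptor kinetics
`dn/dt = 60[α(1−n) − β n]` (`β = 0.007 min⁻¹`) and melanopic
dose-response `α = α₀ (E/E₀)^p` (`α₀ = 0.05 min⁻¹`, `E₀ = 5.7 W m⁻²`,
`p = 0.5`). The nonphotic drive
`N_s = ρ (1/3 − Ŝ)(1 − tanh(10x))` (`Ŝ = 1` asleep, 0 awake,
`ρ = 0.032`) nudges the oscillator with the rest–activity cycle; it keeps
a schedule-entrained subject's dark-reference run from drifting freely
(important for stable suppression denominators) at the cost of pulling
the measured dark free-run to ≈4 min/day below τ_c — inside the package's
own ±5 min/day free-run check. The circadian wake drive is
`C = (1 + x)/2`; with the packaged phase, `C` peaks in the late afternoon
(wake-maintenance zone) and troughs near 04:30.

Retinal input is zero during sleep. In forced mode this gating is applied
to the exposure series at its own grid *and* at every RK4 stage time, so
a run with arbitrary light inside sleep intervals is bit-identical to one
with that light zeroed — interpolation cannot bleed light across the
boundary.

### Melatonin

Two compartments: pineal synthesis drive
`dP/dt = (R·g(x,y)·w(E) − P)/τ_syn` and plasma
`dM/dt = (P − M)/τ_clear` (`R = 100` pmol L⁻¹ equivalent,
`τ_syn = 0.4 h`, `τ_clear = 0.75 h`, matching a ~30–45 min plasma
half-life). The secretion gate `g` is a smooth sigmoid on the pacemaker
phase (direction and threshold set for a ~10-h biological night; with the
packaged entrained phase, onset ≈22:00, plasma peak ≈04:30, near-zero
plasma through the afternoon). The instantaneous light inhibition is
`w(E) = 1/(1 + (E/E₅₀)^h)` with `E₅₀ = 0.1 W m⁻²` and `h = 2`, calibrated
so that sustained 1 W m⁻² during waking hours produces ≈95–97 % evening
suppression of the melatonin AUC against the matched dark reference —
the dose anchor stated for this model class. (With `h = 1.5` the
measured week-long figure was 89–91 %, short of the anchor, because the
dark reference drifts slightly; the exponent, not the anchor, was the
free parameter.)

### Alertness outputs

`KSS = clamp(0.5 + 0.27·H − 1.4·C − 1.3·(1 − exp(−E/0.018)), 1, 9)`:
the instantaneous alerting term spans 1.3 KSS units and is >98 %
saturated at 0.075 W m⁻², so KSS discriminates mainly among *dim*
conditions. `vPVTRT = max(100 + 14·H + 90·(1 − C), 50) ms` is a function
of `H` and `C` only — deliberately no instantaneous light term. Both are
NaN during sleep and flagged invalid for 2 h after the end of any sleep
bout longer than 3 h (naps do not trigger the mask). The regression
coefficients are packaged defaults chosen for plausible ranges (KSS ≈ 2–4
daytime, vPVTRT ≈ 250–400 ms) and correct signs; they are config-visible
(`ModelParams`) for substitution, and one known qualitative divergence is
documented: under strong evening light the packaged regression does not
make evening the fastest reaction-time period.

### Entrainment and initial conditions

The packaged initial state is an asleep, approximately-entrained midnight
state. `entrain(schedule, params, days=7, exposure=...)` runs seven
repeats of the exposure's first day under the schedule and returns the
state at the end of day 7, which seeds the assessed run. Determinism is
exact: identical inputs give bit-identical trajectories.

## Derived metrics

* **Melatonin peak / phase shift.** The peak for day *d* is the argmax of
  plasma melatonin in the 24-h window from 15:00 of day *d−1* to 15:00 of
  day *d* (a civil-day argmax splits peaks that straddle midnight), with
  parabolic sub-grid refinement. Daily phase shift is the wrapped
  (−12 h, +12 h] clock-time difference, advance negative; seasonal shift
  is the sum over consecutive day pairs inside the season, which
  telescopes exactly.
* **Suppression.** `100·(AUC_dark − AUC_day)/AUC_dark` by trapezoid over
  the morning (08–12) or evening (18–24) window. The dark reference
  shares the entrained initial state and the sleep schedule and zeroes
  only light. The afternoon window is not computed: an entrained
  night-sleeper has almost no circulating melatonin then. Seasonal values
  are means of daily values (days with zero dark AUC are skipped as
  missing, never as 0). Because the dark reference is only
  nonphotically entrained, mild drift can make individual daily values
  exceed 100 % impossible — but slightly negative values are possible for
  weak-light scenarios; they are reported as computed.
* **Period statistics.** Arithmetic means of KSS / vPVTRT over awake,
  valid samples per period (morning 08–12, afternoon 12–18, evening
  18–24) within each meteorological season (spring Mar 1–May 31, summer
  Jun 1–Aug 31, fall Sep 1–Nov 30, winter Dec 1–Feb 28/29; Feb 29 counts
  as winter). Empty cells are missing, not zero.

All derived metrics are descriptive; the package deliberately attaches no
pass/fail thresholds to them.

## Legacy metrics

* **N-VE / CP**: clamped linear probability `100·E_D55/750 − 28` (0 % at
  ≤210 lx, 100 % at ≥960 lx); CP is its mean over the resetting
  (06–10), alerting (10–18) and avoidance (18–06) periods across the
  series. D55 equivalent illuminance is approximated from melanopic
  irradiance by `1/K_mel` (D55 and D65 are close on the melanopic band);
  unit tests feed `E_D55` directly so the formula itself is exact.
* **nvRD**: the published interior constants of the original cumulative
  model were not available; the package uses a saturating Hill dose
  accumulator (half-response 300 lx, exponent 2) on the 6-min grid whose
  scale factor is computed *from the anchor* so that 824 lx × 5 h scores
  exactly 4.2. The fallback is flagged in the output metadata.
* **WELL**: daytime tiers require the EML threshold (>150 / >250 lx) for
  ≥4 consecutive hours beginning at or before noon; the residential rule
  caps evening EML (<50 lx after 20:00). Both a per-day-pass evaluation
  (the rule as written) and a timestep-fraction mode are provided; the
  correlation path uses the fraction mode. The electric-light-only
  stipulation is out of scope by design.
* **Consensus (Brown) thresholds**: fractions of daytime samples with
  melanopic EDI ≥ 250 lx, pre-bed (3 h before bedtime) samples ≤ 10 lx,
  and sleep samples ≤ 1 lx; thresholds are inclusive. "Daytime" is
  defined schedule-relative (waking hours outside the pre-bed window).
* **Comparison**: Pearson r (two-sided p) between per-unit seasonal
  metric columns, separately per sleep type, with effect-size labels at
  |r| cut-points 0.2 / 0.5 / 0.8 (half-open at the left, since the quoted
  intervals leave the boundaries undefined). Zero-variance columns yield
  missing r, flagged.

## Scenario generator

The generator emulates the *statistical and temporal structure* of an
east-facing daylit space, not any particular building:

* Daylight is a raised-cosine diffuse component between sunrise and
  sunset (day length 12 ± 2 h sinusoidally over the year, longest near
  June 21) plus a morning direct-sun lobe. Dynamic shades engage whenever
  the unshaded photopic vertical illuminance (melanopic EDI ≈ photopic
  for daylight) would exceed 3000 lx, multiplying transmission by 0.12,
  and re-raise as soon as the trigger clears — producing the documented
  morning spike, shaded late morning, early-afternoon peak and decline.
  `view_depth ∈ [0, 1]` attenuates linearly to 15 % at the back of the
  space.
* Electric/screen sources are scalar melanopic presets (6500 K electric
  0.35, 2800 K electric 0.10, 6500 K screen 0.12, 1900 K screen
  0.02 W m⁻²) on the documented clock schedules. These presets are
  synthetic fixtures calibrated only for plausible magnitudes; real
  spectra live upstream.
* The generator is fully deterministic, so worked examples and
  regression tests are exact. What it does *not* reproduce: weather,
  cloud stochasticity, inter-reflection, seasonal sun-path geometry
  beyond day length, or occupant shade misuse. Passing tests therefore
  demonstrate correct *mechanics* of the pipeline and model, not fidelity
  to any measured building.

Sleep schedules: `scheduled` = 00:00–06:00 nightly; `disrupted` = onset
00:24, main bout spanning 5.6 h (ending 06:00) with three 12-min
awakenings at the bout's quartile points, plus a nap 15:00–16:20. The
source description of the disrupted night is ambiguous about whether
5.6 h includes the interruptions; the bout-span reading is packaged
because it preserves the common 06:00 wake time and yields the documented
homeostatic ordering between sleep types. (The stated nap length "1.2 h"
and the stated clock times 15:00–16:20 disagree by 8 min; the clock times
win.)

## Numerical choices and degenerate inputs

Fixed-step RK4 at 20 s (refinement-tested); exposure held by linear
interpolation between its 60-s grid points, sampled at the proper RK4
stage times. Integration failure (non-finite state) raises an error
naming the step, time and offending component. Flat melatonin days, empty
statistic cells and zero dark AUCs raise or propagate as *missing*
values, never silently as 0. Peak detection uses parabolic refinement;
ties resolve to the first maximum. Natural-mode sleep transitions use a
0.5 mV hysteresis band on the wake-active voltage to prevent chattering
at the threshold.

Problem sizes used by the packaged verification runs: a 7-day entrained
week for the suppression dose check, 32 days for the dark free-run
period, 3–7 days for refinement and stability checks, and 3–4-day
multi-unit runs for the pipeline tests; the full annual horizon
(1.58 M RK4 steps) integrates in about a minute per trajectory.

## Known limitations

* The exact coefficient values of the source model lineage's supplemental
  material were not available; the packaged defaults are structurally
  faithful and calibrated to the stated behavioural anchors, but
  individual state values (e.g. H in nM) are not comparable against that
  lineage's published trajectories number-for-number.
* Rod/cone mediation of ipRGC firing, age-dependent corneal transmission
  and chronotype are not modelled.
* The alertness regressions are packaged defaults with correct signs and
  plausible ranges, not refits against study data.
* Legacy-metric approximations (D55 weighting, nvRD interior dynamics,
  WELL workplane semantics collapsed onto the eye-level series) are
  documented above and in the code.
* Shift-work schedules are not packaged (the schedule object supports
  arbitrary interval lists, but no presets or validation beyond
  non-overlap are provided for them).
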