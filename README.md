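# insom

Annualized simulation of non-visual (ipRGC-influenced) physiological
responses to light for lighting design analysis.

Architectural lighting metrics for "circadian" design have mostly been
threshold- or saturation-based: a space passes if enough (or little enough)
melanopically weighted light reaches the eye at given hours. But the
biology they stand in for — subjective sleepiness, vigilance, melatonin
secretion, circadian phase — responds to the *timing, history and dose* of
light, not to instantaneous thresholds. `insom` simulates those responses
explicitly. It drives a combined photobiological model with an annual
melanopic-irradiance time series and a sleep schedule, and derives seasonal
and time-of-day metrics a designer can compare across lighting scenarios,
occupant positions and sleep quality — alongside the legacy metrics
(N-VE/CP, nvRD, WELL EML tiers, consensus melanopic-EDI thresholds) and a
Pearson-correlation harness relating the two families.

## The model

State vector `[V_v, V_m, H, x, y, n, P, M]`, integrated with fixed-step
RK4 at 20 s:

- **Sleep–wake switch.** Mean-field voltages of mutually inhibitory
  sleep-active (VLPO, `V_v`) and wake-active (monoaminergic, `V_m`)
  populations, with firing rates `Q_i = Q_max / (1 + exp(−(V_i − θ)/σ))`.
  The homeostatic somnogen `H` obeys `χ dH/dt = μ Q_m − H`: sleep pressure
  rises during wake and clears during sleep. The VLPO drive is
  `D_v = A_v + ν_vh H + ν_vc C`.
- **Circadian pacemaker.** A van der Pol-type limit cycle `(x, y)` with
  intrinsic period τ_c = 24.2 h, driven photically through a photoreceptor
  activation state `n` with drive `B = G α(E) (1−n)(1−b_x x)(1−b_y y)`,
  where `α ∝ (E_e,mel / E₀)^p`, plus a weak nonphotic (sleep/wake) drive.
  The circadian wake drive is `C = (1 + x)/2`. Retinal input is gated to
  zero during sleep (eyes closed).
- **Melatonin.** Pineal synthesis `P` switches on during the biological
  night (a smooth gate on the pacemaker phase), is inhibited
  instantaneously by light via `1 / (1 + (E/E₅₀)^h)`, and feeds plasma
  concentration `M` (pmol L⁻¹) with first-order clearance.
- **Outputs.** KSS (1–9) regresses on `H` and `C` with a rapidly
  saturating instantaneous light alerting term (saturated above
  ≈0.075 W m⁻²); vPVTRT (ms) regresses on `H` and `C` only. Both are
  masked during sleep and for 2 h after each main wake.

Derived metrics: daily/seasonal circadian phase shift from the
plasma-melatonin peak (advance negative); melatonin suppression
`100·(AUC_dark − AUC_day)/AUC_dark` against a matched dark-reference run
(morning 08–12 and evening 18–24 windows); per-period KSS/vPVTRT means
over meteorological seasons (boundaries Mar 1 / Jun 1 / Sep 1 / Dec 1).

A deterministic scenario generator synthesizes annual exposure series for
three operational conditions in a daylit space — `daylight` (dynamic
shades triggered at 3000 lx vertical illuminance), `electric` (constant
6500 K light 06–24 h plus a cool evening screen) and `dimming` (warm
2800 K evenings, half power 22–24 h, blue-depleted evening screen) — and
two sleep types, `scheduled` (00:00–06:00) and `disrupted` (delayed onset,
three nocturnal awakenings, midday nap).

## Worked example

Two weeks of the `electric` scenario starting September 15, window-front
view, scheduled sleep, after a 7-day entrainment pre-run:

```python
import datetime as dt
import numpy as np
from insom import (ScenarioConfig, build_sleep_schedule, compose_scenario,
                   ModelParams, entrain, integrate, seasonal_metrics,
                   legacy_metrics)
from insom.units import MelanopicIrradianceSeries

cfg = ScenarioConfig("electric", start_date=dt.date(2021, 9, 15))
exposure = compose_scenario(cfg, year_days=14, view_depth=0.0)
sleep = build_sleep_schedule("scheduled")
params = ModelParams()

state0 = entrain(sleep, params, days=7, exposure=exposure)
lit = integrate(exposure, sleep, params, initial_state=state0)
lit.start_date = cfg.start_date
dark = integrate(MelanopicIrradianceSeries(
    exposure.t, np.zeros_like(exposure.values), start_date=cfg.start_date),
    sleep, params, initial_state=state0)
dark.start_date = cfg.start_date

m = seasonal_metrics(lit, dark)
lg = legacy_metrics(exposure, sleep)
```

This prints (via the obvious `print` calls):

```text
fall KSS means:         {'morning': 2.0, 'afternoon': 1.71, 'evening': 2.52}
fall vPVTRT means (ms): {'morning': 323.9, 'afternoon': 302.9, 'evening': 353.6}
fall suppression (%):   {'morning': 89.5, 'evening': 86.8}
fall phase shift (min): 1.6
mean nvRD:              8.58
CP (%):                 {'resetting': 86.5, 'alerting': 78.9, 'avoidance': 9.6}
Brown compliance (%):   {'daytime': 100.0, 'nighttime': 0.0, 'sleep': 100.0}
```

Reading: constant bright 6500 K light keeps the occupant alert (KSS ≈ 2,
"alert") but suppresses ~87 % of evening melatonin and violates the
consensus pre-bed recommendation outright (nighttime compliance 0 %) —
exactly the trade-off between alerting benefit and circadian cost the
simulated metrics make visible and the threshold metrics cannot.

The same pipeline runs from the shell:

```console
insom synth --scenario electric --days 14 --out exp.csv --schedule-out sched.json
insom simulate --exposure exp.csv --schedule sched.json --out traj.csv
insom legacy --exposure exp.csv --schedule sched.json --out legacy.csv
insom run --config examples/demo_config.yaml
```

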