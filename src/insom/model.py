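"""Combined photobiological model of sleep, circadian phase and melatonin.

The model couples three well-established components into one state vector
integrated with fixed-step RK4 at 20-s resolution:

1. **Sleep–wake switch** — a mean-field flip-flop between wake-active
   (monoaminergic, voltage ``Vm``) and sleep-active (ventrolateral
   preoptic, ``Vv``) neuronal populations with mutual inhibition, driven by
   a homeostatic somnogen ``H`` that accumulates during wake and clears
   during sleep, and by a circadian wake drive ``C``.

2. **Circadian pacemaker** — a van der Pol-type limit-cycle oscillator
   ``(x, y)`` with intrinsic period ``tau_c`` receiving a photic drive
   ``B`` through a photoreceptor activation state ``n`` and a weak
   nonphotic (sleep/wake state) drive.  Light input is melanopic
   irradiance in W m⁻² and is gated to zero during sleep (eyes closed).

3. **Melatonin** — a two-compartment extension (pineal synthesis →
   blood plasma, pmol L⁻¹) in which synthesis is switched on during the
   biological night by the pacemaker and inhibited instantaneously by a
   saturating function of melanopic irradiance.

Alertness outputs are regressions on the state: KSS (1–9, includes an
instantaneous, rapidly saturating light alerting term) and vPVTRT (ms,
a function of ``H`` and ``C`` only — no instantaneous light term).

State vector layout: ``[Vv, Vm, H, x, y, n, P, M]`` (six core differential
equations plus the two melatonin compartments); time unit inside the
integrator is hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .scenarios import SleepSchedule
from .units import MelanopicIrradianceSeries

__all__ = [
    "ModelParams",
    "PhysiologicalTrajectory",
    "derivatives",
    "integrate",
    "entrain",
    "kss",
    "vpvtrt",
    "IntegrationError",
]

# state indices
IV, IM, IH, IX, IY, IN, IP, IMEL = range(8)
STATE_NAMES = ("Vv", "Vm", "H", "x", "y", "n", "P", "M")


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass
class ModelParams:
    """Coefficient set of the combined model.

    Neuronal and homeostatic constants follow the Phillips–Robinson
    mean-field sleep–wake lineage; the pacemaker and photic processing
    follow the Kronauer/St Hilaire lineage with light in melanopic
    irradiance; melatonin and the alertness regressions are packaged
    defaults in the same lineage, calibrated so that the documented
    qualitative behaviour (nocturnal secretion, evening suppression
    saturating near 1 W m⁻², KSS light term saturating near
    0.075 W m⁻²) holds.  Every constant is overridable.
    """

    # --- neuronal mean-field flip-flop (mV, s⁻¹, nM) ---
    q_max: float = 100.0          # maximum firing rate, s⁻¹
    theta: float = 10.0           # sigmoid midpoint, mV
    sigma: float = 3.0            # sigmoid width, mV
    tau_v: float = 150.0 / 3600.0  # VLPO relaxation time, h
    tau_m: float = 150.0 / 3600.0  # MA relaxation time, h
    nu_vm: float = -2.1           # MA→VLPO coupling, mV s
    nu_mv: float = -1.8           # VLPO→MA coupling, mV s
    a_m: float = 1.3              # constant wake-promoting drive, mV
    a_v: float = -10.2            # constant VLPO drive offset, mV

    # --- homeostat ---
    chi: float = 45.0             # somnogen clearance time, h
    mu: float = 4.4               # somnogen production, nM s
    nu_vh: float = 1.0            # H→VLPO drive, mV nM⁻¹
    nu_vc: float = -2.9           # C→VLPO drive, mV

    # --- circadian drive from the pacemaker ---
    c_ax: float = 1.0             # C = 0.5·(1 + c_ax·x + c_ay·y)
    c_ay: float = 0.0

    # --- pacemaker (dimensionless, h) ---
    tau_c: float = 24.2           # intrinsic period, h
    gamma: float = 0.13           # van der Pol stiffness
    k_b: float = 0.55             # light effect on period
    f_c: float = 0.99669          # period correction factor
    g_photic: float = 37.0        # photic drive gain
    alpha0: float = 0.05          # photoreceptor activation rate, min⁻¹
    e_half_photic: float = 5.7    # irradiance normalisation, W m⁻²
    p_photic: float = 0.5         # dose-response exponent
    beta_n: float = 0.007         # photoreceptor recovery rate, min⁻¹
    b_x: float = 0.4              # pacemaker sensitivity modulation by x
    b_y: float = 0.4              # and by y
    rho_nonphotic: float = 0.032  # nonphotic drive strength
    r_nonphotic: float = 10.0     # nonphotic tanh gain on x

    # --- melatonin (pmol L⁻¹, h) ---
    mel_rate: float = 100.0       # maximal plasma-equivalent synthesis drive
    mel_gate_cos: float = -0.924  # secretion-gate direction (x component)
    mel_gate_sin: float = -0.382  # secretion-gate direction (y component)
    mel_gate_threshold: float = 0.27
    mel_gate_width: float = 0.08
    tau_syn: float = 0.4          # pineal compartment time constant, h
    tau_clear: float = 0.75       # plasma clearance time constant, h
    e50_mel: float = 0.10         # half-inhibition irradiance, W m⁻²
    hill_mel: float = 2.0         # inhibition Hill exponent

    # --- alertness regressions ---
    kss_intercept: float = 0.5
    kss_h: float = 0.27           # per nM of H
    kss_c: float = -1.4           # per unit of C
    kss_light_range: float = 1.3  # depth of the instantaneous alerting term
    kss_light_sat: float = 0.018  # e-folding irradiance of that term, W m⁻²
    rt_intercept: float = 100.0   # ms
    rt_h: float = 14.0            # ms per nM of H
    rt_c: float = 90.0            # ms per unit of (1 − C)

    # --- sleep forcing / natural sleep ---
    wake_effort_target: float = 0.5  # MA voltage held during scheduled wake, mV
    forced_sleep_drive: float = 0.8  # sleep-permissive VLPO drive in scheduled sleep, mV
    vm_sleep_threshold: float = -4.0  # natural sleep onset when Vm falls below, mV
    vm_hysteresis: float = 0.5       # upward recross margin for natural wake, mV

    # --- initial condition (midnight, asleep, entrained-phase guess) ---
    initial_state: tuple = (
        4.0, -30.0, 14.0, -0.26, -0.97, 0.1, 60.0, 60.0
    )

    def __post_init__(self):
        if not (20.0 < self.tau_c < 28.0):
            raise ValueError("intrinsic circadian period must lie in (20 h, 28 h)")
        for name in ("q_max", "sigma", "tau_v", "tau_m", "chi", "mu", "alpha0",
                     "beta_n", "tau_syn", "tau_clear", "e50_mel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def _sigmoid_rate(v: float, p: ModelParams) -> float:
    """Population firing rate Q(V), s⁻¹."""
    return p.q_max / (1.0 + math.exp(-(v - p.theta) / p.sigma))


def circadian_drive(x: float, y: float, p: ModelParams) -> float:
    """Circadian wake drive C from the pacemaker state."""
    return 0.5 * (1.0 + p.c_ax * x + p.c_ay * y)


def melatonin_gate(x: float, y: float, p: ModelParams) -> float:
    """Smooth 0–1 switch enabling pineal synthesis during biological night."""
    u = p.mel_gate_cos * x + p.mel_gate_sin * y
    return 1.0 / (1.0 + math.exp(-(u - p.mel_gate_threshold) / p.mel_gate_width))


def melatonin_inhibition(light: float, p: ModelParams) -> float:
    """Fraction of synthesis surviving instantaneous light exposure."""
    if light <= 0.0:
        return 1.0
    return 1.0 / (1.0 + (light / p.e50_mel) ** p.hill_mel)


def derivatives(state, light: float, awake: bool, p: ModelParams,
                forced: bool = True) -> np.ndarray:
    """Time derivative of the full state vector (per hour).

    ``light`` is melanopic irradiance (W m⁻²) at the open eye; retinal
    input is gated to zero while asleep, so the pacemaker, melatonin
    inhibition and alerting pathways see no light during sleep.
    """
    s = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(s)):
        raise IntegrationError("non-finite state passed to derivatives")
    if light < 0:
        raise ValueError("light must be >= 0")
    vv, vm, h, x, y, n, pim, mel = s

    eff_light = light if awake else 0.0

    qv = _sigmoid_rate(vv, p)
    qm = _sigmoid_rate(vm, p)
    c = circadian_drive(x, y, p)

    d_v = p.a_v + p.nu_vh * h + p.nu_vc * c
    d_m = p.a_m
    if forced:
        if awake:
            # wake effort: hold the MA population at a waking voltage even
            # when the natural dynamics favour sleep (scheduled wake)
            d_m = max(d_m, p.wake_effort_target - p.nu_mv * qv)
        else:
            # sleep-permissive drive (darkness, recumbency) to the VLPO
            d_v += p.forced_sleep_drive

    dvv = (p.nu_vm * qm + d_v - vv) / p.tau_v
    dvm = (p.nu_mv * qv + d_m - vm) / p.tau_m
    dh = (p.mu * qm - h) / p.chi

    # photic drive
    alpha = p.alpha0 * (eff_light / p.e_half_photic) ** p.p_photic \
        if eff_light > 0.0 else 0.0
    dn = 60.0 * (alpha * (1.0 - n) - p.beta_n * n)
    b = p.g_photic * alpha * (1.0 - n) * (1.0 - p.b_x * x) * (1.0 - p.b_y * y)

    # nonphotic drive: wake pushes the oscillator one way, sleep the other
    s_hat = 0.0 if awake else 1.0
    ns = p.rho_nonphotic * (1.0 / 3.0 - s_hat) * (1.0 - math.tanh(p.r_nonphotic * x))

    omega = math.pi / 12.0
    dx = omega * (y + p.gamma * (x / 3.0 + 4.0 * x ** 3 / 3.0
                                 - 256.0 * x ** 7 / 105.0) + b + ns)
    dy = omega * (b * y / 3.0 - x * ((24.0 / (p.f_c * p.tau_c)) ** 2 + p.k_b * b))

    # melatonin: gated synthesis, instantaneous light inhibition, clearance
    synth = p.mel_rate * melatonin_gate(x, y, p) * melatonin_inhibition(eff_light, p)
    dpim = (synth - pim) / p.tau_syn
    dmel = (pim - mel) / p.tau_clear

    return np.array([dvv, dvm, dh, dx, dy, dn, dpim, dmel])


def kss(state, light: float, p: ModelParams) -> float:
    """Karolinska Sleepiness Scale prediction for an awake state.

    Regression on H and C plus an instantaneous alerting term that decays
    the score by up to ``kss_light_range`` and is effectively saturated
    above ~0.075 W m⁻² of melanopic irradiance.  Clamped to [1, 9].
    """
    s = np.asarray(state, dtype=float)
    c = circadian_drive(s[IX], s[IY], p)
    base = p.kss_intercept + p.kss_h * s[IH] + p.kss_c * c
    alerting = p.kss_light_range * (1.0 - math.exp(-max(light, 0.0) / p.kss_light_sat))
    return float(np.clip(base - alerting, 1.0, 9.0))


def vpvtrt(state, p: ModelParams) -> float:
    """Mean visual-PVT reaction time (ms): a function of H and C only."""
    s = np.asarray(state, dtype=float)
    c = circadian_drive(s[IX], s[IY], p)
    rt = p.rt_intercept + p.rt_h * s[IH] + p.rt_c * (1.0 - c)
    return float(max(rt, 50.0))


@dataclass
class PhysiologicalTrajectory:
    """Model state and outputs on a uniform grid.

    ``states`` has shape ``(n, 8)`` in the ``[Vv, Vm, H, x, y, n, P, M]``
    layout; ``kss``/``vpvtrt`` are NaN during sleep; ``alertness_valid``
    is additionally False for the first 2 h after each main wake.
    """

    t: np.ndarray                 # seconds since start
    states: np.ndarray
    awake: np.ndarray             # bool
    light: np.ndarray             # gated melanopic irradiance seen by the retina
    kss: np.ndarray
    vpvtrt: np.ndarray
    alertness_valid: np.ndarray   # bool
    start_date: object = None
    params: ModelParams | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def melatonin(self) -> np.ndarray:
        """Plasma melatonin, pmol L⁻¹."""
        return self.states[:, IMEL]

    @property
    def homeostatic(self) -> np.ndarray:
        return self.states[:, IH]

    @property
    def circadian(self) -> np.ndarray:
        p = self.params or ModelParams()
        return 0.5 * (1.0 + p.c_ax * self.states[:, IX] + p.c_ay * self.states[:, IY])

    def clock_hours(self) -> np.ndarray:
        return (self.t / 3600.0) % 24.0

    def day_index(self) -> np.ndarray:
        return (self.t // 86400.0).astype(int)


def _wake_mask_from_schedule(sleep: SleepSchedule, t_s: np.ndarray) -> np.ndarray:
    return ~sleep.is_asleep(t_s / 3600.0)


def _validity_mask(t_s: np.ndarray, awake: np.ndarray, dt: float,
                   mask_hours: float = 2.0,
                   min_main_sleep_h: float = 3.0) -> np.ndarray:
    """False while asleep and for ``mask_hours`` after each main wake.

    Only sleep bouts longer than ``min_main_sleep_h`` trigger the post-wake
    mask; naps and brief awakenings do not.
    """
    valid = awake.copy()
    n = len(awake)
    # locate sleep bouts
    edges = np.flatnonzero(np.diff(awake.astype(int)))
    starts = [0] if not awake[0] else []
    starts += [int(e) + 1 for e in edges if not awake[e + 1]]
    for s0 in starts:
        e0 = s0
        while e0 < n and not awake[e0]:
            e0 += 1
        bout_h = (e0 - s0) * dt / 3600.0
        if bout_h >= min_main_sleep_h and e0 < n:
            k = int(round(mask_hours * 3600.0 / dt))
            valid[e0:min(e0 + k, n)] = False
    return valid


def _rk4_step(s: np.ndarray, lights: tuple, awake: bool, p: ModelParams,
              dt_h: float, forced: bool) -> np.ndarray:
    """One RK4 step; ``lights`` = input at (t, t+dt/2, t+dt)."""
    l0, lh, l1 = lights
    k1 = derivatives(s, l0, awake, p, forced)
    k2 = derivatives(s + 0.5 * dt_h * k1, lh, awake, p, forced)
    k3 = derivatives(s + 0.5 * dt_h * k2, lh, awake, p, forced)
    k4 = derivatives(s + dt_h * k3, l1, awake, p, forced)
    return s + (dt_h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    exposure: MelanopicIrradianceSeries,
    sleep: SleepSchedule,
    params: ModelParams | None = None,
    dt: float = 20.0,
    mode: str = "forced",
    initial_state=None,
) -> PhysiologicalTrajectory:
    """Integrate the model over the exposure horizon with fixed-step RK4.

    ``mode='forced'`` imposes the sleep schedule exactly (with auxiliary
    wake-effort / sleep-permissive drives on the neuronal populations);
    ``mode='natural'`` lets sleep onset occur when the wake-active voltage
    ``Vm`` falls below threshold, with hysteresis on the upward recrossing.
    Light reaching the retina is zero during sleep in both modes.
    """
    if mode not in ("forced", "natural"):
        raise ValueError("mode must be 'forced' or 'natural'")
    p = params or ModelParams()
    n_steps = int(round((exposure.t[-1] + exposure.dt) / dt))
    t = np.arange(n_steps) * dt
    forced = mode == "forced"
    exp_values = exposure.values
    if forced:
        # eyes closed: zero the retinal input over scheduled sleep, both at
        # the exposure grid (so interpolation cannot bleed sleep-interval
        # light across the boundary) and at every RK4 stage time — a run
        # with arbitrary light during sleep intervals is then identical to
        # one with that light zeroed
        exp_values = exp_values * _wake_mask_from_schedule(sleep, exposure.t)
    light_in = np.interp(t, exposure.t, exp_values, left=0.0, right=0.0)
    light_mid = np.interp(t + 0.5 * dt, exposure.t, exp_values,
                          left=0.0, right=0.0)
    light_end = np.interp(t + dt, exposure.t, exp_values,
                          left=0.0, right=0.0)

    if forced:
        awake_arr = _wake_mask_from_schedule(sleep, t)
        light_in = light_in * awake_arr
        light_mid = light_mid * _wake_mask_from_schedule(sleep, t + 0.5 * dt)
        light_end = light_end * _wake_mask_from_schedule(sleep, t + dt)
    else:
        awake_arr = np.empty(n_steps, dtype=bool)

    states = np.empty((n_steps, 8))
    s = np.array(initial_state if initial_state is not None else p.initial_state,
                 dtype=float)
    dt_h = dt / 3600.0
    awake_now = bool(s[IM] > p.vm_sleep_threshold)

    for i in range(n_steps):
        if forced:
            awake_now = bool(awake_arr[i])
        else:
            if awake_now and s[IM] < p.vm_sleep_threshold:
                awake_now = False
            elif not awake_now and s[IM] > p.vm_sleep_threshold + p.vm_hysteresis:
                awake_now = True
            awake_arr[i] = awake_now
        states[i] = s
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                s = _rk4_step(
                    s, (float(light_in[i]), float(light_mid[i]),
                        float(light_end[i])),
                    awake_now, p, dt_h, forced,
                )
        except IntegrationError as exc:
            raise IntegrationError(
                f"divergence at step {i} (t={t[i] / 3600.0:.2f} h): {exc}"
            ) from exc
        if not np.all(np.isfinite(s)):
            bad = [STATE_NAMES[j] for j in range(8) if not np.isfinite(s[j])]
            raise IntegrationError(
                f"non-finite state at step {i} (t={t[i] / 3600.0:.2f} h): "
                + ", ".join(bad)
            )

    gated = np.where(awake_arr, light_in, 0.0)
    kss_arr = np.full(n_steps, np.nan)
    rt_arr = np.full(n_steps, np.nan)
    c = 0.5 * (1.0 + p.c_ax * states[:, IX] + p.c_ay * states[:, IY])
    base = p.kss_intercept + p.kss_h * states[:, IH] + p.kss_c * c
    alert = p.kss_light_range * (1.0 - np.exp(-gated / p.kss_light_sat))
    kss_all = np.clip(base - alert, 1.0, 9.0)
    rt_all = np.maximum(p.rt_intercept + p.rt_h * states[:, IH]
                        + p.rt_c * (1.0 - c), 50.0)
    kss_arr[awake_arr] = kss_all[awake_arr]
    rt_arr[awake_arr] = rt_all[awake_arr]

    valid = _validity_mask(t, awake_arr, dt)
    return PhysiologicalTrajectory(
        t=t, states=states, awake=awake_arr, light=gated,
        kss=kss_arr, vpvtrt=rt_arr, alertness_valid=valid,
        start_date=exposure.start_date, params=p,
    )


def entrain(
    sleep: SleepSchedule,
    params: ModelParams | None = None,
    days: int = 7,
    exposure: MelanopicIrradianceSeries | None = None,
    dt: float = 20.0,
    mode: str = "forced",
) -> np.ndarray:
    """Entrain the model to a sleep schedule and return the final state.

    The baseline exposure is the first day of ``exposure`` repeated
    ``days`` times (darkness when no exposure is given).  ``days=0``
    returns the packaged initial condition unchanged.
    """
    p = params or ModelParams()
    if days == 0:
        return np.array(p.initial_state, dtype=float)
    if exposure is not None:
        day_t = exposure.t[exposure.t < 86400.0]
        day_v = exposure.values[: len(day_t)]
        step = day_t[1] - day_t[0]
        t = np.arange(0.0, days * 86400.0, step)
        v = np.tile(day_v, days)[: len(t)]
    else:
        t = np.arange(0.0, days * 86400.0, 60.0)
        v = np.zeros_like(t)
    series = MelanopicIrradianceSeries(t, v)
    traj = integrate(series, sleep, p, dt=dt, mode=mode)
    # advance the last stored state by one step to land exactly on day boundary
    lv = float(v[-1])
    last = _rk4_step(traj.states[-1], (lv, lv, lv),
                     bool(traj.awake[-1]), p, dt / 3600.0, mode == "forced")
    return last
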