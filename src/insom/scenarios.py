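"""Synthetic lighting scenarios and sleep schedules.

Generates annual melanopic-irradiance series with the temporal structure of
three operational lighting conditions in a daylit, east-facing care space:

* ``daylight`` — daylight only, with dynamic shades that lower whenever the
  unshaded vertical eye illuminance would exceed a photopic trigger
  (default 3000 lx), producing a short morning spike followed by a shaded
  period until early afternoon;
* ``electric`` — daylight plus constant cool (6500 K) electric light during
  all waking hours (06:00–24:00) and a cool screen in the evening
  (18:00–24:00);
* ``dimming`` — as ``electric``, but the luminaires switch to a warm 2800 K
  preset 18:00–22:00 and run at half power 22:00–24:00, and the screen
  switches to a blue-depleted 1900 K preset 21:00–24:00.

Sleep schedules cover a well-rested ``scheduled`` type (00:00–06:00 nightly)
and a ``disrupted`` hospital-patient type (delayed onset, three nocturnal
awakenings, midday nap).

The generator is deterministic: identical configuration yields identical
series, so worked examples and regression tests are exact.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .units import K_MEL, MelanopicIrradianceSeries

__all__ = [
    "ScenarioConfig",
    "SleepSchedule",
    "build_sleep_schedule",
    "generate_daylight_series",
    "compose_scenario",
    "SCENARIO_IDS",
]

SCENARIO_IDS = ("daylight", "electric", "dimming")

#: Scalar melanopic-irradiance presets (W m⁻²) standing in for the source
#: spectra; synthetic fixtures, overridable per config.
DEFAULT_PRESETS = {
    "electric_6500K": 0.35,
    "electric_2800K": 0.10,
    "screen_6500K": 0.12,
    "screen_1900K": 0.02,
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic lighting scenario."""

    scenario: str = "daylight"
    #: Peak diffuse daylight melanopic irradiance at the window (W m⁻²).
    daylight_peak: float = 2.0
    #: Peak of the unshaded morning direct-sun lobe at the window (W m⁻²).
    morning_spike_peak: float = 8.0
    #: Shades lower when unshaded photopic vertical illuminance exceeds this (lx).
    shade_trigger_lx: float = 3000.0
    #: Transmittance of the lowered shade.
    shade_transmittance: float = 0.12
    #: Melanopic irradiance presets per source/CCT (W m⁻²).
    presets: dict = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    #: Mean day length (h) and its seasonal modulation amplitude (h).
    day_length_mean: float = 12.0
    day_length_amplitude: float = 2.0
    #: Photopic lx per W m⁻² of daylight melanopic irradiance.  Daylight is
    #: close to D65, so melanopic EDI ≈ photopic illuminance and the factor
    #: defaults to 1 / K_MEL.
    photopic_per_melanopic: float = 1.0 / K_MEL
    start_date: _dt.date = _dt.date(2021, 1, 1)

    def __post_init__(self):
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("daylight_peak", "morning_spike_peak", "shade_trigger_lx",
                     "shade_transmittance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.presets.values()):
            raise ValueError("presets must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if isinstance(d.get("start_date"), str):
            d["start_date"] = _dt.date.fromisoformat(d["start_date"])
        return cls(**d)


@dataclass
class SleepSchedule:
    """Per-day sleep intervals in clock hours, identical every day.

    ``intervals`` is a sorted list of non-overlapping ``(start, end)`` pairs
    with ``0 <= start < end <= 24`` (minute resolution).
    """

    intervals: list[tuple[float, float]]
    sleep_type: str = "scheduled"

    def __post_init__(self):
        iv = sorted((float(a), float(b)) for a, b in self.intervals)
        for a, b in iv:
            if not (0.0 <= a < b <= 24.0):
                raise ValueError(f"interval ({a}, {b}) outside [0, 24]")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise ValueError("sleep intervals overlap")
        self.intervals = iv

    def is_asleep(self, clock_hours) -> np.ndarray:
        """Vectorised sleep mask for clock times in hours."""
        h = np.asarray(clock_hours, dtype=float) % 24.0
        mask = np.zeros(h.shape, dtype=bool)
        for a, b in self.intervals:
            mask |= (h >= a) & (h < b)
        return mask

    @property
    def main_sleep(self) -> tuple[float, float]:
        """Wall-clock span of the main (nocturnal) bout, awakenings included."""
        night = [iv for iv in self.intervals if iv[0] < 12.0]
        return (night[0][0], night[-1][1])

    def total_sleep_hours(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def to_json(self) -> str:
        return json.dumps(
            {"sleep_type": self.sleep_type, "intervals": self.intervals}
        )

    @classmethod
    def from_json(cls, text: str) -> "SleepSchedule":
        d = json.loads(text)
        return cls([tuple(iv) for iv in d["intervals"]], d["sleep_type"])


def build_sleep_schedule(sleep_type: str) -> SleepSchedule:
    """Construct one of the two packaged sleep types.

    ``scheduled``
        One interval [00:00, 06:00) every day — a moderately short but
        perfectly regular sleeper.
    ``disrupted``
        Lies down at midnight but falls asleep at 00:24; the main bout
        proceeds for 5.6 h (so waking lands at 06:00, like the scheduled
        type), broken by three 12-min awakenings placed at the quartile
        points of the bout, plus a midday nap [15:00, 16:20).
    """
    if sleep_type == "scheduled":
        return SleepSchedule([(0.0, 6.0)], "scheduled")
    if sleep_type == "disrupted":
        onset = 24.0 / 60.0  # 00:24
        span = 5.6  # main bout wall-clock span → ends 06:00
        gap = 12.0 / 60.0  # awakening length
        seg = (span - 3.0 * gap) / 4.0  # four equal sleep segments
        intervals = []
        t = onset
        for _ in range(4):
            intervals.append((t, t + seg))
            t += seg + gap
        intervals.append((15.0, 15.0 + 80.0 / 60.0))  # nap 15:00–16:20
        return SleepSchedule(intervals, "disrupted")
    raise ValueError(f"unknown sleep type {sleep_type!r}")


# ---------------------------------------------------------------------------
# daylight generation
# ---------------------------------------------------------------------------

def _day_length_hours(config: ScenarioConfig, doy: np.ndarray) -> np.ndarray:
    # longest day near the June solstice (day-of-year 172)
    return config.day_length_mean + config.day_length_amplitude * np.cos(
        2.0 * np.pi * (doy - 172.0) / 365.25
    )


def generate_daylight_series(
    config: ScenarioConfig,
    year_days: int = 365,
    view_depth: float = 0.0,
    dt: float = 60.0,
) -> MelanopicIrradianceSeries:
    """Synthesize an annual daylight melanopic-irradiance series.

    The unshaded profile is a raised-cosine diffuse component between
    sunrise and sunset plus a morning direct-sun lobe (east façade).  Shades
    lower whenever the implied unshaded photopic illuminance exceeds the
    trigger, scaling the received light by the shade transmittance, and
    re-raise as soon as the unshaded level falls back below the trigger.
    ``view_depth`` ∈ [0, 1] attenuates the whole profile from window-front
    (0) to the back of the space (1).
    """
    if not 0.0 <= view_depth <= 1.0:
        raise ValueError("view_depth must lie in [0, 1]")
    t = np.arange(0.0, year_days * 86400.0, dt)
    hours = (t / 3600.0) % 24.0
    doy = (t // 86400.0) + (config.start_date.timetuple().tm_yday - 1)

    length = _day_length_hours(config, doy)
    sunrise = 12.0 - length / 2.0
    sunset = 12.0 + length / 2.0
    up = (hours >= sunrise) & (hours < sunset)

    # diffuse raised cosine peaking at solar noon
    phase = np.where(up, (hours - sunrise) / np.maximum(length, 1e-9), 0.0)
    diffuse = config.daylight_peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))

    # east-facing direct lobe in the first third of the day
    lobe = np.clip(1.0 - (phase - 0.18) ** 2 / 0.028, 0.0, None)
    direct = config.morning_spike_peak * np.where(up, lobe, 0.0)

    unshaded = diffuse + direct
    depth_factor = 1.0 - 0.85 * view_depth
    # shade logic evaluated on the window-front (depth 0) unshaded level
    photopic_unshaded = unshaded * config.photopic_per_melanopic
    shaded = photopic_unshaded > config.shade_trigger_lx
    received = np.where(shaded, unshaded * config.shade_transmittance, unshaded)
    values = received * depth_factor
    photopic = values * config.photopic_per_melanopic
    return MelanopicIrradianceSeries(
        t, values, start_date=config.start_date, photopic=photopic
    )


def _interval_mask(hours: np.ndarray, start: float, end: float) -> np.ndarray:
    return (hours >= start) & (hours < end)


def compose_scenario(
    config: ScenarioConfig,
    sleep: SleepSchedule | None = None,
    year_days: int = 365,
    view_depth: float = 0.0,
    dt: float = 60.0,
) -> MelanopicIrradianceSeries:
    """Compose daylight + electric + screen contributions for a scenario.

    Electric/screen sources follow fixed clock schedules; the sleep
    schedule is accepted for interface symmetry (sources are assumed on
    during the scheduled waking hours regardless of momentary naps — the
    photobiological model gates retinal input during sleep itself).
    """
    day = generate_daylight_series(config, year_days, view_depth, dt)
    hours = day.clock_hours()
    values = day.values.copy()
    photopic = day.photopic.copy() if day.photopic is not None else np.zeros_like(values)
    p = config.presets

    if config.scenario == "electric":
        electric = p["electric_6500K"] * _interval_mask(hours, 6.0, 24.0)
        screen = p["screen_6500K"] * _interval_mask(hours, 18.0, 24.0)
        values = values + electric + screen
    elif config.scenario == "dimming":
        electric = (
            p["electric_6500K"] * _interval_mask(hours, 6.0, 18.0)
            + p["electric_2800K"] * _interval_mask(hours, 18.0, 22.0)
            + 0.5 * p["electric_6500K"] * _interval_mask(hours, 22.0, 24.0)
        )
        screen = (
            p["screen_6500K"] * _interval_mask(hours, 18.0, 21.0)
            + p["screen_1900K"] * _interval_mask(hours, 21.0, 24.0)
        )
        values = values + electric + screen
    # "daylight": no additional sources

    return MelanopicIrradianceSeries(
        day.t, values, start_date=config.start_date, photopic=photopic
    )
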