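"""Melanopic unit conversions and calendar/period partitioning.

All downstream metrics run on a single scalar light quantity: melanopic
irradiance ``E_e,mel`` in W m⁻² at the eye.  Three photometric scales are
interconverted here:

* melanopic irradiance (W m⁻²) — the model's native input,
* melanopic EDI (lx) — illuminance of a D65 reference producing the same
  melanopic effect,
* EML (equivalent melanopic lux, Lucas toolbox scale).

The calendar helpers define the meteorological seasons and the fixed
time-of-day periods (alertness, melatonin and N-VE windows) every seasonal
metric aggregates over.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "K_MEL",
    "R_EML",
    "MelanopicIrradianceSeries",
    "mel_edi_to_irradiance",
    "irradiance_to_mel_edi",
    "eml_to_mel_edi",
    "mel_edi_to_eml",
    "resample_series",
    "season_of_date",
    "season_day_counts",
    "ALERTNESS_PERIODS",
    "MELATONIN_WINDOWS",
    "NVE_PERIODS",
    "period_mask",
    "SEASONS",
]

#: Melanopic irradiance (W m⁻²) per melanopic-EDI lux — the CIE S 026
#: melanopic efficacy of luminous radiation for standard daylight (D65).
K_MEL = 1.3262e-3

#: EML per melanopic-EDI lux (EML = R_EML × melanopic EDI).
R_EML = 1.103

SEASONS = ("spring", "summer", "fall", "winter")

#: Alertness aggregation periods, clock hours [start, end).
ALERTNESS_PERIODS = {
    "morning": (8.0, 12.0),
    "afternoon": (12.0, 18.0),
    "evening": (18.0, 24.0),
}

#: Melatonin-suppression windows (afternoon omitted: circulating melatonin
#: is near zero then for a night-sleeping, entrained person).
MELATONIN_WINDOWS = {
    "morning": (8.0, 12.0),
    "evening": (18.0, 24.0),
}

#: N-VE (non-visual effect) periods; "avoidance" wraps midnight.
NVE_PERIODS = {
    "resetting": (6.0, 10.0),
    "alerting": (10.0, 18.0),
    "avoidance": (18.0, 30.0),  # 18:00 → 06:00 next day
}


def _check_nonneg(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and >= 0")


def mel_edi_to_irradiance(edi):
    """Convert melanopic EDI (lx) to melanopic irradiance (W m⁻²).

    Inverse of :func:`irradiance_to_mel_edi`.  250 lx ↦ 0.33 W m⁻²,
    754 lx ↦ 1.0 W m⁻².
    """
    _check_nonneg(edi, "melanopic EDI")
    return np.multiply(edi, K_MEL)


def irradiance_to_mel_edi(e):
    """Convert melanopic irradiance (W m⁻²) to melanopic EDI (lx)."""
    _check_nonneg(e, "melanopic irradiance")
    return np.divide(e, K_MEL)


def eml_to_mel_edi(eml):
    """Convert EML to melanopic EDI (lx): melanopic EDI = EML / R_EML."""
    _check_nonneg(eml, "EML")
    return np.divide(eml, R_EML)


def mel_edi_to_eml(edi):
    """Convert melanopic EDI (lx) to EML: EML = R_EML × melanopic EDI."""
    _check_nonneg(edi, "melanopic EDI")
    return np.multiply(edi, R_EML)


@dataclass
class MelanopicIrradianceSeries:
    """Uniformly gridded eye-level melanopic irradiance over whole days.

    Parameters
    ----------
    t : ndarray
        Seconds since simulation start; strictly increasing uniform grid
        starting at 0.
    values : ndarray
        Melanopic irradiance ``E_e,mel`` in W m⁻², all >= 0.
    start_date : datetime.date
        Calendar date of the first sample (local civil time).
    utc_offset_hours : float
        Fixed local-time offset; informational only (no DST handling).
    photopic : ndarray or None
        Optional matching photopic vertical illuminance (lx) used by the
        shade trigger and N-VE logic.
    """

    t: np.ndarray
    values: np.ndarray
    start_date: _dt.date = _dt.date(2021, 1, 1)
    utc_offset_hours: float = 0.0
    photopic: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.values.shape:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("series needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-6):
            raise ValueError("time grid must be strictly increasing and uniform")
        if np.any(self.values < 0):
            raise ValueError("melanopic irradiance must be >= 0")
        span = self.t[-1] - self.t[0] + dt[0]
        if abs(span / 86400.0 - round(span / 86400.0)) > 1e-6:
            raise ValueError("series must cover an integer number of whole days")
        if self.photopic is not None:
            self.photopic = np.asarray(self.photopic, dtype=float)
            if self.photopic.shape != self.values.shape:
                raise ValueError("photopic channel must match the grid")

    @property
    def dt(self) -> float:
        """Grid step in seconds."""
        return float(self.t[1] - self.t[0])

    @property
    def n_days(self) -> int:
        return int(round((self.t[-1] - self.t[0] + self.dt) / 86400.0))

    def clock_hours(self) -> np.ndarray:
        """Local clock time of each sample in hours, [0, 24)."""
        return (self.t / 3600.0) % 24.0

    def day_index(self) -> np.ndarray:
        """Whole days elapsed since start for each sample."""
        return (self.t // 86400.0).astype(int)

    def dates(self) -> np.ndarray:
        """Calendar date of each sample."""
        base = np.datetime64(self.start_date)
        return base + self.day_index().astype("timedelta64[D]")

    def interpolator(self):
        """Return ``f(t_seconds) -> E_e,mel`` with linear interpolation,
        zero outside the sampled range."""
        t, v = self.t, self.values
        return lambda q: np.interp(q, t, v, left=0.0, right=0.0)

    def to_frame(self) -> pd.DataFrame:
        ts = pd.Timestamp(self.start_date) + pd.to_timedelta(self.t, unit="s")
        frame = pd.DataFrame({"timestamp": ts, "E_e_mel_W_m2": self.values})
        if self.photopic is not None:
            frame["E_v_lx"] = self.photopic
        return frame


def resample_series(
    times_s,
    values,
    dt: float,
    *,
    start_date: _dt.date = _dt.date(2021, 1, 1),
    n_days: int | None = None,
) -> MelanopicIrradianceSeries:
    """Linearly interpolate irregular samples onto a uniform grid.

    Values outside the sampled range are 0.  The grid spans ``n_days``
    whole days (default: the smallest whole-day span covering the input).
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_s.size == 0:
        raise ValueError("no samples to resample")
    if times_s.shape != values.shape:
        raise ValueError("times and values must have the same length")
    order = np.argsort(times_s, kind="stable")
    times_s, values = times_s[order], values[order]
    dup = np.diff(times_s) == 0
    if np.any(dup & (np.diff(values) != 0)):
        raise ValueError("duplicate timestamps with differing values")
    _check_nonneg(values, "values")
    if n_days is None:
        n_days = max(1, int(np.ceil((times_s[-1] + 1e-9) / 86400.0)))
    grid = np.arange(0.0, n_days * 86400.0, dt)
    out = np.interp(grid, times_s, values, left=0.0, right=0.0)
    return MelanopicIrradianceSeries(grid, out, start_date=start_date)


# ---------------------------------------------------------------------------
# calendar partitioning
# ---------------------------------------------------------------------------

_SEASON_STARTS = {3: "spring", 6: "summer", 9: "fall", 12: "winter"}


def season_of_date(date: _dt.date) -> str:
    """Meteorological season of a civil date.

    Boundaries are Mar 1 / Jun 1 / Sep 1 / Dec 1; Feb 29 counts as winter.
    """
    m = date.month
    if 3 <= m <= 5:
        return "spring"
    if 6 <= m <= 8:
        return "summer"
    if 9 <= m <= 11:
        return "fall"
    return "winter"


def season_day_counts(year: int) -> dict[str, int]:
    """Days per meteorological season in a calendar year."""
    counts = dict.fromkeys(SEASONS, 0)
    d = _dt.date(year, 1, 1)
    one = _dt.timedelta(days=1)
    while d.year == year:
        counts[season_of_date(d)] += 1
        d += one
    return counts


def period_mask(clock_hours: np.ndarray, period: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples whose clock time lies in [start, end).

    ``end`` may exceed 24 to express a window wrapping midnight
    (e.g. the N-VE avoidance window 18:00→06:00 is (18, 30)).
    """
    h = np.asarray(clock_hours, dtype=float)
    start, end = period
    if end <= 24.0:
        return (h >= start) & (h < end)
    return (h >= start) | (h < end - 24.0)
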