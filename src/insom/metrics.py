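"""Seasonal and time-of-day metrics derived from a simulated trajectory.

Four families of descriptive (not evaluative) outputs:

* **daily / seasonal phase shift** — day-to-day change in the clock time of
  the plasma-melatonin peak, wrapped to (−12 h, +12 h]; an advance
  (earlier peak) is negative.  The seasonal value is the cumulative sum of
  daily shifts over consecutive day pairs within a meteorological season.
* **melatonin suppression** — percent reduction of the melatonin
  area-under-curve in a window relative to a matched dark-reference
  trajectory (same entrained initial state and sleep schedule, light
  zeroed): ``100 · (AUC_dark − AUC_day) / AUC_dark``.
* **period statistics** — per-season means of KSS / vPVTRT over awake,
  valid samples in the morning / afternoon / evening periods (the first
  2 h after a main wake are masked).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PhysiologicalTrajectory
from .units import (
    ALERTNESS_PERIODS,
    MELATONIN_WINDOWS,
    SEASONS,
    period_mask,
    season_of_date,
)

__all__ = [
    "UndefinedResultError",
    "melatonin_peak_time",
    "daily_phase_shift",
    "seasonal_phase_shift",
    "melatonin_suppression",
    "period_statistics",
    "SeasonalMetricSet",
    "seasonal_metrics",
]


class UndefinedResultError(ValueError):
    """A metric has no defined value (flat melatonin, empty window...)."""


def _wrap_hours(delta: float) -> float:
    """Wrap a clock-time difference to (−12, +12] hours."""
    return -((-delta + 12.0) % 24.0 - 12.0)


def melatonin_peak_time(traj: PhysiologicalTrajectory, day: int) -> float:
    """Clock time (hours) of the plasma-melatonin peak assigned to ``day``.

    The peak is searched in a 24-h window centred on the subjective night
    ending on the morning of ``day`` (15:00 of the previous civil day to
    15:00 of ``day``), so peaks that straddle midnight are not split, and
    is refined to sub-grid resolution by a parabolic fit through the three
    samples around the argmax.
    """
    m = traj.melatonin
    t = traj.t
    lo = (day - 1) * 86400.0 + 15.0 * 3600.0
    hi = day * 86400.0 + 15.0 * 3600.0
    sel = np.flatnonzero((t >= lo) & (t < hi))
    if sel.size < 3:
        raise UndefinedResultError(f"day {day} not fully covered")
    seg = m[sel]
    if np.ptp(seg) <= 1e-9:
        raise UndefinedResultError(f"flat melatonin on day {day}: no peak")
    k = int(np.argmax(seg))
    i = sel[k]
    t_pk = t[i]
    if 0 < k < len(seg) - 1:
        y0, y1, y2 = seg[k - 1], seg[k], seg[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            t_pk += 0.5 * (y0 - y2) / denom * traj.dt
    return (t_pk / 3600.0) % 24.0


def daily_phase_shift(traj: PhysiologicalTrajectory, day_i: int, day_j: int) -> float:
    """Signed melatonin-peak clock-time change from ``day_i`` to ``day_j``
    in minutes, wrapped to (−12 h, +12 h].  Advance (earlier) is negative."""
    pi = melatonin_peak_time(traj, day_i)
    pj = melatonin_peak_time(traj, day_j)
    return _wrap_hours(pj - pi) * 60.0


def _season_day_indices(traj: PhysiologicalTrajectory, season: str) -> np.ndarray:
    start = traj.start_date or _dt.date(2021, 1, 1)
    n_days = int(round((traj.t[-1] + traj.dt) / 86400.0))
    days = np.arange(n_days)
    labels = np.array(
        [season_of_date(start + _dt.timedelta(days=int(d))) for d in days]
    )
    return days[labels == season]


def seasonal_phase_shift(traj: PhysiologicalTrajectory, season: str) -> float:
    """Cumulative phase shift (minutes) over a meteorological season:
    sum of daily shifts over consecutive day pairs within the season."""
    days = _season_day_indices(traj, season)
    if days.size < 2:
        raise UndefinedResultError(f"season {season!r} not fully simulated")
    total = 0.0
    for d0, d1 in zip(days[:-1], days[1:]):
        if d1 == d0 + 1:
            total += daily_phase_shift(traj, int(d0), int(d1))
    return total


def melatonin_suppression(
    traj_light: PhysiologicalTrajectory,
    traj_dark: PhysiologicalTrajectory,
    window: str,
    day: int,
) -> float:
    """Percent melatonin suppression on ``day`` in a named window.

    ``100 · (AUC_dark − AUC_day) / AUC_dark`` with trapezoid integration of
    plasma melatonin over the window (``'morning'`` 08–12, ``'evening'``
    18–24).  The dark trajectory must share the grid and represent the
    same run with light zeroed.
    """
    if window not in MELATONIN_WINDOWS:
        raise ValueError(f"window must be one of {sorted(MELATONIN_WINDOWS)}")
    if traj_light.t.shape != traj_dark.t.shape:
        raise ValueError("trajectories must share the time grid")
    lo, hi = MELATONIN_WINDOWS[window]
    sel = (traj_light.day_index() == day) & period_mask(
        traj_light.clock_hours(), (lo, hi)
    )
    if not np.any(sel):
        raise UndefinedResultError(f"day {day} window {window!r} not covered")
    dt_h = traj_light.dt / 3600.0
    auc_day = np.trapezoid(traj_light.melatonin[sel], dx=dt_h)
    auc_dark = np.trapezoid(traj_dark.melatonin[sel], dx=dt_h)
    if auc_dark <= 0.0:
        raise UndefinedResultError(
            f"dark AUC is zero on day {day} ({window}); suppression undefined"
        )
    return 100.0 * (auc_dark - auc_day) / auc_dark


def period_statistics(
    traj: PhysiologicalTrajectory,
    metric: str,
    season: str | None = None,
) -> dict[str, float]:
    """Mean of ``metric`` (``'KSS'`` or ``'vPVTRT'``) per alertness period.

    Averages awake, valid samples only (sleep and the 2-h post-wake mask
    excluded).  Restricting to a season uses its calendar dates.  Empty
    periods yield NaN (missing), not zero.
    """
    values = {"KSS": traj.kss, "vPVTRT": traj.vpvtrt}.get(metric)
    if values is None:
        raise ValueError("metric must be 'KSS' or 'vPVTRT'")
    hours = traj.clock_hours()
    ok = traj.awake & traj.alertness_valid & np.isfinite(values)
    if season is not None:
        day_sel = np.isin(traj.day_index(), _season_day_indices(traj, season))
        ok = ok & day_sel
    out = {}
    for name, bounds in ALERTNESS_PERIODS.items():
        sel = ok & period_mask(hours, bounds)
        out[name] = float(np.mean(values[sel])) if np.any(sel) else float("nan")
    return out


@dataclass
class SeasonalMetricSet:
    """Per-season aggregates for one simulated unit (view × scenario × sleep).

    ``phase_shift`` maps season → cumulative shift (min); ``suppression``
    maps (season, window) → mean daily percent; ``kss`` / ``vpvtrt`` map
    (season, period) → mean.
    """

    phase_shift: dict = field(default_factory=dict)
    suppression: dict = field(default_factory=dict)
    kss: dict = field(default_factory=dict)
    vpvtrt: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        base = dict(self.meta)
        for season, v in self.phase_shift.items():
            rows.append({**base, "season": season, "period": "",
                         "metric": "phase_shift_min", "value": v})
        for (season, win), v in self.suppression.items():
            rows.append({**base, "season": season, "period": win,
                         "metric": "melatonin_suppression_pct", "value": v})
        for (season, per), v in self.kss.items():
            rows.append({**base, "season": season, "period": per,
                         "metric": "KSS", "value": v})
        for (season, per), v in self.vpvtrt.items():
            rows.append({**base, "season": season, "period": per,
                         "metric": "vPVTRT_ms", "value": v})
        return pd.DataFrame(rows)


def seasonal_metrics(
    traj_light: PhysiologicalTrajectory,
    traj_dark: PhysiologicalTrajectory | None = None,
    seasons=SEASONS,
    meta: dict | None = None,
) -> SeasonalMetricSet:
    """Assemble the full per-season metric set for one simulated unit.

    Seasonal suppression is the mean of daily suppression values across the
    season's days (days with an undefined value are skipped).
    """
    out = SeasonalMetricSet(meta=meta or {})
    for season in seasons:
        days = _season_day_indices(traj_light, season)
        if days.size == 0:
            continue
        if days.size >= 2:
            try:
                out.phase_shift[season] = seasonal_phase_shift(traj_light, season)
            except UndefinedResultError:
                pass
        for metric, store in (("KSS", out.kss), ("vPVTRT", out.vpvtrt)):
            stats = period_statistics(traj_light, metric, season)
            for per, v in stats.items():
                store[(season, per)] = v
        if traj_dark is not None:
            for win in MELATONIN_WINDOWS:
                vals = []
                for d in days:
                    try:
                        vals.append(
                            melatonin_suppression(traj_light, traj_dark, win, int(d))
                        )
                    except UndefinedResultError:
                        continue
                if vals:
                    out.suppression[(season, win)] = float(np.mean(vals))
    return out
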