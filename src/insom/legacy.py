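"""Pre-existing ipRGC-influenced lighting metrics and the comparison suite.

Implements the threshold/saturation-based metrics that predate explicit
photobiological simulation, plus Pearson-correlation comparison between
them and the simulated physiological outputs:

* **N-VE / CP** — probability of a non-visual effect as a clamped linear
  function of D55 equivalent illuminance (0% at ≤210 lx, 100% at ≥960 lx,
  ``100·E_D55/750 − 28`` between), and circadian potential, its mean over
  a time-of-day period across a year.
* **nvRD** — a cumulative daily light-dose ("non-visual direct response")
  on a 6-min grid, normalized so that 824 lx of D65 vertical illuminance
  sustained for 5 h scores 4.2.
* **WELL** — compliance with the EML workplace tiers (>150 / >250 lx for
  ≥4 consecutive hours beginning at or before noon) and the residential
  evening cap (<50 EML after 20:00).
* **Brown et al. consensus** — fraction of daytime samples with melanopic
  EDI ≥ 250 lx, pre-bed (3 h) samples ≤ 10 lx and sleep samples ≤ 1 lx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .scenarios import SleepSchedule
from .units import (
    K_MEL,
    NVE_PERIODS,
    MelanopicIrradianceSeries,
    R_EML,
    period_mask,
)

__all__ = [
    "nve_probability",
    "circadian_potential",
    "nvrd_daily",
    "nvrd_series",
    "well_compliance",
    "brown_compliance",
    "ferguson_label",
    "correlate",
    "LegacyMetricSet",
    "legacy_metrics",
]

#: D55 equivalent illuminance (lx) per W m⁻² of melanopic irradiance.
#: The D55-weighting of the original N-VE framework is not recoverable
#: from a scalar melanopic series; D55 and D65 daylight spectra are close
#: on the melanopic band, so the melanopic-EDI constant is reused as a
#: documented approximation (configurable).
D55_LX_PER_W = 1.0 / K_MEL


def nve_probability(e_d55):
    """Probability (%) of a non-visual effect at D55 equivalent illuminance.

    0 at or below 210 lx, 100 at or above 960 lx, ``100·E/750 − 28``
    between — continuous and non-decreasing.
    """
    e = np.asarray(e_d55, dtype=float)
    if np.any(e < 0):
        raise ValueError("illuminance must be >= 0")
    p = 100.0 * e / 750.0 - 28.0
    out = np.clip(p, 0.0, 100.0)
    return float(out) if np.isscalar(e_d55) else out


def circadian_potential(
    series: MelanopicIrradianceSeries,
    nve_period: str,
    d55_lx_per_w: float = D55_LX_PER_W,
) -> float:
    """Circadian potential (%): mean N-VE probability within a named
    period (resetting / alerting / avoidance) across the whole series."""
    if nve_period not in NVE_PERIODS:
        raise ValueError(f"period must be one of {sorted(NVE_PERIODS)}")
    e_d55 = series.values * d55_lx_per_w
    sel = period_mask(series.clock_hours(), NVE_PERIODS[nve_period])
    return float(np.mean(nve_probability(e_d55[sel])))


# --- nvRD ------------------------------------------------------------------

NVRD_GRID_S = 360.0          # 6-min evaluation grid
NVRD_TARGET = 4.2            # daily target at the calibration condition
NVRD_CAL_LX = 824.0          # calibration vertical illuminance (D65)
NVRD_CAL_HOURS = 5.0
NVRD_C50_LX = 300.0          # half-response illuminance of the dose term
NVRD_HILL = 2.0


def _nvrd_response(e_v_lx: np.ndarray) -> np.ndarray:
    """Relative per-sample direct response: saturating Hill dose term."""
    e = np.asarray(e_v_lx, dtype=float)
    return e ** NVRD_HILL / (e ** NVRD_HILL + NVRD_C50_LX ** NVRD_HILL)


#: Scale factor fixing the calibration anchor exactly:
#: 824 lx sustained 5 h → daily nvRD 4.2.
_NVRD_SCALE = NVRD_TARGET / (float(_nvrd_response(NVRD_CAL_LX)) * NVRD_CAL_HOURS)


def nvrd_daily(e_v_lx, dt_s: float = NVRD_GRID_S) -> float:
    """Daily non-visual direct response from one day of vertical photopic
    illuminance (D65) sampled at 6-min intervals.

    A saturating-dose accumulator calibrated to the published anchor
    (824 lx for 5 h → 4.2); the interior dose-response constants are this
    package's own (flagged in output metadata by :func:`legacy_metrics`).
    Monotone in both level and duration.
    """
    if abs(dt_s - NVRD_GRID_S) > 1e-6:
        raise ValueError("nvRD is defined on a 6-min grid")
    e = np.asarray(e_v_lx, dtype=float)
    if np.any(e < 0):
        raise ValueError("illuminance must be >= 0")
    return float(_NVRD_SCALE * np.sum(_nvrd_response(e)) * dt_s / 3600.0)


def nvrd_series(series: MelanopicIrradianceSeries) -> np.ndarray:
    """Daily nvRD for every day of an exposure series.

    Uses the photopic channel when present, otherwise converts the
    melanopic channel at the daylight (D65-like) ratio; the series is
    resampled to the 6-min grid by averaging or interpolation.
    """
    e = (series.photopic if series.photopic is not None
         else series.values / K_MEL)
    per_day = int(round(86400.0 / series.dt))
    n_days = series.n_days
    grid = np.arange(0.0, 86400.0, NVRD_GRID_S)
    out = np.empty(n_days)
    for d in range(n_days):
        day = e[d * per_day:(d + 1) * per_day]
        t_day = series.t[:per_day] - series.t[0]
        e6 = np.interp(grid, t_day, day)
        out[d] = nvrd_daily(e6)
    return out


# --- WELL ------------------------------------------------------------------

WELL_TIERS = {"150EML": 150.0, "250EML": 250.0, "residential": 50.0}


def _eml(series: MelanopicIrradianceSeries) -> np.ndarray:
    return series.values / K_MEL * R_EML


def well_compliance(
    series: MelanopicIrradianceSeries,
    tier: str,
    mode: str = "days",
) -> float:
    """WELL circadian-lighting compliance (%) for an exposure series.

    Daytime tiers (``'150EML'``, ``'250EML'``): the EML threshold must be
    exceeded for at least 4 consecutive hours beginning at or before noon.
    ``'residential'``: EML must stay below 50 lx after 20:00.

    ``mode='days'`` returns the percentage of days compliant;
    ``mode='fraction'`` returns the percentage of qualifying timesteps
    meeting the threshold (daytime tiers: samples 08:00–noon-start
    window... evaluated over the tier's qualifying hours 06:00–18:00;
    residential: samples after 20:00).
    """
    if tier not in WELL_TIERS:
        raise ValueError(f"tier must be one of {sorted(WELL_TIERS)}")
    if mode not in ("days", "fraction"):
        raise ValueError("mode must be 'days' or 'fraction'")
    eml = _eml(series)
    hours = series.clock_hours()
    per_day = int(round(86400.0 / series.dt))
    n_days = series.n_days
    thr = WELL_TIERS[tier]

    if mode == "fraction":
        if tier == "residential":
            sel = hours >= 20.0
            return float(100.0 * np.mean(eml[sel] < thr))
        sel = (hours >= 6.0) & (hours < 18.0)
        return float(100.0 * np.mean(eml[sel] > thr))

    need = int(round(4.0 * 3600.0 / series.dt))
    ok_days = 0
    for d in range(n_days):
        sl = slice(d * per_day, (d + 1) * per_day)
        h = hours[sl]
        v = eml[sl]
        if tier == "residential":
            ok_days += bool(np.all(v[h >= 20.0] < thr))
            continue
        above = v > thr
        # longest run start must be at or before noon and run >= 4 h
        run = 0
        met = False
        for i in range(per_day):
            run = run + 1 if above[i] else 0
            if run >= need and h[i] - (run - 1) * series.dt / 3600.0 <= 12.0:
                met = True
                break
        ok_days += met
    return 100.0 * ok_days / n_days


def brown_compliance(
    series: MelanopicIrradianceSeries,
    schedule: SleepSchedule,
) -> dict[str, float]:
    """Compliance (%) with the consensus melanopic-EDI recommendations.

    * daytime: melanopic EDI ≥ 250 lx throughout the daytime (waking hours
      outside the pre-bed window),
    * nighttime: ≤ 10 lx in the 3 h before bedtime,
    * sleep: ≤ 1 lx during sleep.

    Thresholds are inclusive ("a minimum of" / "not exceed").
    """
    edi = series.values / K_MEL
    hours = series.clock_hours()
    asleep = schedule.is_asleep(hours)
    bedtime = schedule.main_sleep[0]
    prebed = period_mask(hours, ((bedtime - 3.0) % 24.0,
                                 (bedtime - 3.0) % 24.0 + 3.0)) & ~asleep
    daytime = ~asleep & ~prebed
    out = {}
    out["daytime"] = float(100.0 * np.mean(edi[daytime] >= 250.0)) \
        if np.any(daytime) else float("nan")
    out["nighttime"] = float(100.0 * np.mean(edi[prebed] <= 10.0)) \
        if np.any(prebed) else float("nan")
    out["sleep"] = float(100.0 * np.mean(edi[asleep] <= 1.0)) \
        if np.any(asleep) else float("nan")
    return out


# --- comparison ------------------------------------------------------------

FERGUSON_LABELS = (
    (0.8, "strong"),
    (0.5, "moderate"),
    (0.2, "practically significant"),
    (0.0, "not practically significant"),
)


def ferguson_label(r: float) -> str:
    """Effect-size label for a Pearson coefficient by |r|.

    Cut-points 0.2 / 0.5 / 0.8, half-open at the left (|r| = 0.2 is
    already practically significant).
    """
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError("|r| must be <= 1")
    a = abs(r)
    for cut, label in FERGUSON_LABELS:
        if a >= cut:
            return label
    return FERGUSON_LABELS[-1][1]


@dataclass
class LegacyMetricSet:
    """Legacy metric values for one exposure unit (view/scenario/season)."""

    nvrd_mean: float = float("nan")
    cp: dict = field(default_factory=dict)            # period → %
    well: dict = field(default_factory=dict)          # tier → %
    brown: dict = field(default_factory=dict)         # window → %
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{**self.meta, "metric": "nvRD", "period": "",
                 "value": self.nvrd_mean}]
        rows += [{**self.meta, "metric": "N-VE", "period": k, "value": v}
                 for k, v in self.cp.items()]
        rows += [{**self.meta, "metric": "WELL", "period": k, "value": v}
                 for k, v in self.well.items()]
        rows += [{**self.meta, "metric": "Brown", "period": k, "value": v}
                 for k, v in self.brown.items()]
        return pd.DataFrame(rows)


def legacy_metrics(
    series: MelanopicIrradianceSeries,
    schedule: SleepSchedule,
    meta: dict | None = None,
) -> LegacyMetricSet:
    """Compute the full legacy metric set for one exposure series."""
    out = LegacyMetricSet(meta=meta or {})
    out.meta.setdefault("nvrd_model", "saturating-dose accumulator, 4.2 anchor")
    out.nvrd_mean = float(np.mean(nvrd_series(series)))
    for per in NVE_PERIODS:
        out.cp[per] = circadian_potential(series, per)
    for tier in WELL_TIERS:
        out.well[tier] = well_compliance(series, tier, mode="fraction")
    out.brown = brown_compliance(series, schedule)
    return out


def correlate(
    legacy_table: pd.DataFrame,
    insom_table: pd.DataFrame,
    unit_keys=("view", "scenario", "season"),
) -> pd.DataFrame:
    """Pearson correlation between legacy and simulated metric columns.

    Both tables carry one row per unit (``unit_keys``) and one column per
    metric; rows are aligned on the keys.  Zero-variance columns yield a
    missing ``r`` flagged in the output.  Requires at least 3 matched
    units.
    """
    merged = legacy_table.merge(insom_table, on=list(unit_keys), how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched units to correlate")
    lcols = [c for c in legacy_table.columns if c not in unit_keys]
    icols = [c for c in insom_table.columns if c not in unit_keys]
    rows = []
    for lc in lcols:
        for ic in icols:
            x = merged[lc].to_numpy(dtype=float)
            y = merged[ic].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"legacy_metric": lc, "insom_metric": ic,
                             "n": int(len(x)), "r": float("nan"),
                             "p": float("nan"), "effect_size": "undefined"})
                continue
            r, p = _stats.pearsonr(x, y)
            rows.append({"legacy_metric": lc, "insom_metric": ic,
                         "n": int(len(x)), "r": float(r), "p": float(p),
                         "effect_size": ferguson_label(float(np.clip(r, -1, 1)))})
    return pd.DataFrame(rows)
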