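"""End-to-end orchestration: scenario → entrainment → simulation → metrics.

A run is described by a plain configuration mapping (YAML/JSON on disk):

.. code-block:: yaml

    schema: 1
    year_days: 365
    start_date: 2021-01-01
    dt_model_s: 20
    scenarios: [daylight, electric, dimming]
    sleep_types: [scheduled, disrupted]
    view_depths: [0.0, 0.5, 1.0]
    out_dir: results/run1

Each (scenario × sleep type × view depth) combination is one *unit*: its
annual exposure is synthesized, the virtual occupant is entrained for
seven days to the schedule under the scenario's first-day light, the year
is integrated twice (as lit, and as the matched dark reference), and the
seasonal physiological metrics plus the legacy lighting metrics are
tabulated.  With at least three units per sleep type the two metric
families are correlated.  Everything is deterministic.
"""

from __future__ import annotations

import datetime as _dt
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .legacy import correlate, legacy_metrics
from .metrics import seasonal_metrics
from .model import ModelParams, entrain, integrate
from .scenarios import (
    SCENARIO_IDS,
    ScenarioConfig,
    build_sleep_schedule,
    compose_scenario,
)
from .units import MelanopicIrradianceSeries, SEASONS, season_of_date

__all__ = ["load_config", "validate_config", "run_pipeline", "subset_days"]

DEFAULT_CONFIG = {
    "schema": 1,
    "year_days": 365,
    "start_date": "2021-01-01",
    "dt_model_s": 20.0,
    "dt_light_s": 60.0,
    "entrain_days": 7,
    "scenarios": ["daylight", "electric", "dimming"],
    "sleep_types": ["scheduled", "disrupted"],
    "view_depths": [0.0, 0.5, 1.0],
    "scenario_params": {},
    "model_params": {},
    "plots": False,
    "out_dir": "insom_results",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    merged = {**DEFAULT_CONFIG, **cfg}
    validate_config(merged)
    return merged


def validate_config(cfg: dict) -> None:
    if cfg.get("schema") != 1:
        raise ConfigError("unsupported or missing schema version (expected 1)")
    for sc in cfg["scenarios"]:
        if sc not in SCENARIO_IDS:
            raise ConfigError(f"unknown scenario {sc!r}")
    for st in cfg["sleep_types"]:
        if st not in ("scheduled", "disrupted"):
            raise ConfigError(f"unknown sleep type {st!r}")
    for d in cfg["view_depths"]:
        if not 0.0 <= float(d) <= 1.0:
            raise ConfigError(f"view depth {d} outside [0, 1]")
    if int(cfg["year_days"]) < 1:
        raise ConfigError("year_days must be >= 1")


def subset_days(series: MelanopicIrradianceSeries,
                day_indices) -> MelanopicIrradianceSeries:
    """Concatenate selected whole days into a new uniform series.

    Clock times are preserved (each day keeps its 00:00–24:00 layout), so
    clock-based metrics are unaffected by the days being non-contiguous
    (as for a winter that wraps the calendar year).
    """
    per_day = int(round(86400.0 / series.dt))
    idx = np.concatenate(
        [np.arange(d * per_day, (d + 1) * per_day) for d in day_indices]
    )
    vals = series.values[idx]
    photopic = series.photopic[idx] if series.photopic is not None else None
    t = np.arange(len(vals)) * series.dt
    return MelanopicIrradianceSeries(t, vals, start_date=series.start_date,
                                     photopic=photopic)


def _season_days(start: _dt.date, n_days: int) -> dict[str, np.ndarray]:
    labels = np.array([
        season_of_date(start + _dt.timedelta(days=d)) for d in range(n_days)
    ])
    return {s: np.flatnonzero(labels == s) for s in SEASONS}


def _legacy_seasonal_rows(series, schedule, seasons, meta) -> list[dict]:
    rows = []
    for season, days in seasons.items():
        if days.size == 0:
            continue
        sub = subset_days(series, days)
        lm = legacy_metrics(sub, schedule, meta={**meta, "season": season})
        rows.append(lm.to_frame())
    return rows


def _pivot_legacy(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["column"] = frame["metric"] + np.where(
        frame["period"].astype(str) != "", "_" + frame["period"].astype(str), ""
    )
    return frame.pivot_table(
        index=["view", "scenario", "season"], columns="column", values="value"
    ).reset_index()


def _pivot_insom(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["column"] = frame["metric"] + np.where(
        frame["period"].astype(str) != "", "_" + frame["period"].astype(str), ""
    )
    return frame.pivot_table(
        index=["view", "scenario", "season"], columns="column", values="value"
    ).reset_index()


def run_pipeline(config, log=print) -> dict:
    """Execute a full configured run; returns a summary dict.

    Writes per-unit metric tables, correlation tables (when at least three
    units exist per sleep type), optional plots and a manifest into
    ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {**DEFAULT_CONFIG, **config}
        validate_config(cfg)
    t0 = time.time()
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    start_date = _dt.date.fromisoformat(str(cfg["start_date"]))
    n_days = int(cfg["year_days"])
    params = ModelParams(**cfg["model_params"])
    seasons = _season_days(start_date, n_days)

    metric_frames, legacy_frames = [], []
    for scenario in cfg["scenarios"]:
        sc_cfg = ScenarioConfig(
            scenario=scenario, start_date=start_date, **cfg["scenario_params"]
        )
        for depth in cfg["view_depths"]:
            exposure = compose_scenario(
                sc_cfg, year_days=n_days, view_depth=float(depth),
                dt=float(cfg["dt_light_s"]),
            )
            dark = MelanopicIrradianceSeries(
                exposure.t, np.zeros_like(exposure.values),
                start_date=start_date,
            )
            for sleep_type in cfg["sleep_types"]:
                schedule = build_sleep_schedule(sleep_type)
                meta = {"view": f"depth{depth}", "scenario": scenario,
                        "sleep_type": sleep_type}
                log(f"[insom] unit {meta}")
                s0 = entrain(schedule, params, days=int(cfg["entrain_days"]),
                             exposure=exposure, dt=float(cfg["dt_model_s"]))
                lit = integrate(exposure, schedule, params,
                                dt=float(cfg["dt_model_s"]), initial_state=s0)
                lit.start_date = start_date
                drk = integrate(dark, schedule, params,
                                dt=float(cfg["dt_model_s"]), initial_state=s0)
                drk.start_date = start_date
                mset = seasonal_metrics(lit, drk, meta=meta)
                metric_frames.append(mset.to_frame())
                legacy_frames.extend(
                    _legacy_seasonal_rows(exposure, schedule, seasons, meta)
                )

    metrics_table = pd.concat(metric_frames, ignore_index=True)
    legacy_table = pd.concat(legacy_frames, ignore_index=True)
    metrics_table.to_csv(out_dir / "insom_metrics.csv", index=False)
    legacy_table.to_csv(out_dir / "legacy_metrics.csv", index=False)

    summary = {"units": len(metric_frames), "out_dir": str(out_dir)}
    corr_paths = []
    for sleep_type in cfg["sleep_types"]:
        msel = metrics_table[metrics_table["sleep_type"] == sleep_type]
        lsel = legacy_table[legacy_table["sleep_type"] == sleep_type]
        units = msel[["view", "scenario", "season"]].drop_duplicates()
        if len(units) < 3:
            log(f"[insom] correlation skipped for {sleep_type}: "
                f"{len(units)} unit(s) < 3")
            continue
        table = correlate(_pivot_legacy(lsel), _pivot_insom(msel))
        path = out_dir / f"correlation_{sleep_type}.csv"
        table.to_csv(path, index=False)
        corr_paths.append(str(path))
    summary["correlations"] = corr_paths

    if cfg.get("plots"):
        from .viz import render_ring_plot

        first = metric_frames[0]
        # re-derive the metric set of the first unit for illustration
        # (plots are a per-unit view; the tables carry the full results)
        log("[insom] plots requested: rendering first-unit ring plots")
        # reconstruct from the frame
        from .metrics import SeasonalMetricSet

        ms = SeasonalMetricSet()
        for _, row in first.iterrows():
            if row["metric"] == "KSS":
                ms.kss[(row["season"], row["period"])] = row["value"]
            elif row["metric"] == "vPVTRT_ms":
                ms.vpvtrt[(row["season"], row["period"])] = row["value"]
            elif row["metric"] == "phase_shift_min":
                ms.phase_shift[row["season"]] = row["value"]
            elif row["metric"] == "melatonin_suppression_pct":
                ms.suppression[(row["season"], row["period"])] = row["value"]
        for mid in ("KSS", "vPVTRT", "phase_shift", "suppression"):
            try:
                render_ring_plot(ms, mid, out_dir / f"ring_{mid}.svg")
            except ValueError:
                log(f"[insom] ring plot {mid} skipped (incomplete seasons)")

    summary["wall_s"] = round(time.time() - t0, 2)
    _io.write_manifest(out_dir / "manifest.json", cfg, extra=summary)
    log(f"[insom] done in {summary['wall_s']} s → {out_dir}")
    return summary
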