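"""File formats: exposure CSV, schedule JSON, trajectory and metrics tables.

All writers emit plain text (CSV / JSON) and every format round-trips
through the matching reader in this module.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PhysiologicalTrajectory, STATE_NAMES
from .scenarios import SleepSchedule
from .units import MelanopicIrradianceSeries

__all__ = [
    "write_exposure_csv",
    "read_exposure_csv",
    "write_schedule_json",
    "read_schedule_json",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_manifest",
]


def write_exposure_csv(series: MelanopicIrradianceSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_exposure_csv(path) -> MelanopicIrradianceSeries:
    frame = pd.read_csv(path, parse_dates=["timestamp"])
    ts = frame["timestamp"]
    start = ts.iloc[0]
    t = (ts - start.normalize()).dt.total_seconds().to_numpy()
    photopic = frame["E_v_lx"].to_numpy() if "E_v_lx" in frame else None
    return MelanopicIrradianceSeries(
        t, frame["E_e_mel_W_m2"].to_numpy(),
        start_date=start.date(), photopic=photopic,
    )


def write_schedule_json(schedule: SleepSchedule, path) -> None:
    Path(path).write_text(schedule.to_json())


def read_schedule_json(path) -> SleepSchedule:
    return SleepSchedule.from_json(Path(path).read_text())


def write_trajectory_csv(traj: PhysiologicalTrajectory, path,
                         stride: int = 1) -> None:
    """Write a trajectory (optionally strided) as the standard CSV layout."""
    sl = slice(None, None, stride)
    start = pd.Timestamp(traj.start_date or _dt.date(2021, 1, 1))
    frame = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(traj.t[sl], unit="s"),
        "E_e_mel": traj.light[sl],
        "awake": traj.awake[sl].astype(int),
        "H": traj.states[sl, 2],
        "C": traj.circadian[sl],
        "melatonin_pmol_L": traj.melatonin[sl],
        "KSS": traj.kss[sl],
        "vPVTRT_ms": traj.vpvtrt[sl],
        "alertness_valid": traj.alertness_valid[sl].astype(int),
    })
    for j, name in enumerate(STATE_NAMES):
        frame[f"state_{name}"] = traj.states[sl, j]
    frame.to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def write_manifest(path, config: dict, extra: dict | None = None) -> dict:
    """Record config hash, package version and wall-clock info for a run."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "written_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    manifest.update(extra or {})
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
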