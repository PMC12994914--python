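"""Seasonal ring plots and model-dynamics panels.

The ring plot summarizes one metric for one view location: the four
quadrants are the meteorological seasons and the concentric bands are
time-of-day periods, innermost = morning.  The phase-shift variant uses a
single band with a signed (diverging) colour scale.  The dynamics figure
stacks the model's state and output panels over a day range, optionally
overlaying a dark-reference trajectory.

Rendering is deterministic: SVG output uses a fixed hash salt and no date
metadata, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import SeasonalMetricSet
from .model import PhysiologicalTrajectory
from .units import SEASONS

__all__ = ["render_ring_plot", "render_dynamics"]

_QUADRANT = {"spring": 90.0, "summer": 0.0, "fall": 270.0, "winter": 180.0}
_SVG_OPTS = {"metadata": {"Date": None, "Creator": None}}


def _deterministic_rc():
    plt.rcParams["svg.hashsalt"] = "insom"


def _cells(metrics: SeasonalMetricSet, metric_id: str):
    """(season, band index, band name, value) cells for a metric id."""
    if metric_id == "phase_shift":
        return [(s, 0, "season", metrics.phase_shift.get(s)) for s in SEASONS], 1
    if metric_id == "suppression":
        bands = ("morning", "evening")
    elif metric_id in ("KSS", "vPVTRT"):
        bands = ("morning", "afternoon", "evening")
    else:
        raise ValueError(f"unknown metric id {metric_id!r}")
    store = {"suppression": metrics.suppression, "KSS": metrics.kss,
             "vPVTRT": metrics.vpvtrt}[metric_id]
    cells = [(s, b, band, store.get((s, band)))
             for s in SEASONS for b, band in enumerate(bands)]
    return cells, len(bands)


def render_ring_plot(
    metrics: SeasonalMetricSet,
    metric_id: str,
    path,
    cmap: str | None = None,
    title: str | None = None,
) -> None:
    """Render a seasonal ring plot of one metric to SVG/PNG.

    Quadrants are seasons (spring NE, summer SE, fall SW, winter NW by
    default orientation); bands are periods with morning innermost.
    Missing cells are hatched; all four seasons must be present.
    """
    _deterministic_rc()
    cells, n_bands = _cells(metrics, metric_id)
    present = {s for s, _, _, v in cells if v is not None and np.isfinite(v)}
    missing = [s for s in SEASONS if s not in present]
    if missing:
        raise ValueError(f"metric {metric_id!r} missing seasons: {missing}")

    vals = np.array([v for *_, v in cells if v is not None], dtype=float)
    signed = metric_id == "phase_shift"
    if signed:
        lim = max(np.max(np.abs(vals)), 1e-9)
        vmin, vmax = -lim, lim
        cmap = cmap or "coolwarm"
    else:
        vmin, vmax = float(np.min(vals)), float(np.max(vals))
        if vmin == vmax:
            vmin, vmax = vmin - 0.5, vmax + 0.5
        cmap = cmap or "viridis"
    cm = plt.get_cmap(cmap)
    norm = plt.Normalize(vmin, vmax)

    fig, ax = plt.subplots(
        figsize=(4.2, 4.2), subplot_kw={"projection": "polar"}
    )
    ax.set_theta_direction(-1)
    ax.set_theta_zero_location("N")
    r0, width = 0.25, 0.7 / n_bands
    for season, band, _name, value in cells:
        theta0 = np.deg2rad(_QUADRANT[season])
        inner = r0 + band * width
        if value is None or not np.isfinite(value):
            ax.bar(theta0 + np.pi / 4, width, width=np.pi / 2, bottom=inner,
                   color="white", edgecolor="0.4", hatch="///")
        else:
            ax.bar(theta0 + np.pi / 4, width, width=np.pi / 2, bottom=inner,
                   color=cm(norm(value)), edgecolor="white", linewidth=0.8)
    # view-direction arrow at the centre
    ax.annotate("", xy=(0.0, r0 * 0.8), xytext=(np.pi, r0 * 0.5),
                arrowprops={"arrowstyle": "-|>", "color": "black"})
    for season, ang in _QUADRANT.items():
        ax.text(np.deg2rad(ang + 45.0), r0 + 0.82, season,
                ha="center", va="center", fontsize=9)
    ax.set_ylim(0, r0 + 0.95)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or metric_id)
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cm), ax=ax,
                 shrink=0.7, pad=0.08)
    fig.savefig(path, **(_SVG_OPTS if str(path).endswith(".svg") else {}))
    plt.close(fig)


def render_dynamics(
    traj: PhysiologicalTrajectory,
    path,
    day_range: tuple[int, int] | None = None,
    dark: PhysiologicalTrajectory | None = None,
) -> None:
    """Stacked panels H, C, sleep state, E_e,mel, KSS, vPVTRT and melatonin
    over a day range; a dark-reference trajectory is overlaid in grey."""
    _deterministic_rc()
    d0, d1 = day_range or (0, min(3, traj.t[-1] // 86400 + 1))
    if d1 <= d0:
        raise ValueError("empty day range")
    sel = (traj.t >= d0 * 86400.0) & (traj.t < d1 * 86400.0)
    if not np.any(sel):
        raise ValueError("day range outside trajectory")
    days = traj.t[sel] / 86400.0

    panels = [
        ("H", traj.homeostatic, "nM"),
        ("C", traj.circadian, ""),
        ("state", traj.awake.astype(float), "wake=1"),
        ("$E_{e,mel}$", traj.light, "W m$^{-2}$"),
        ("KSS", traj.kss, "1–9"),
        ("vPVTRT", traj.vpvtrt, "ms"),
        ("Mel.", traj.melatonin, "pmol L$^{-1}$"),
    ]
    dark_panels = {}
    if dark is not None:
        dark_panels = {"H": dark.homeostatic, "C": dark.circadian,
                       "Mel.": dark.melatonin, "KSS": dark.kss,
                       "vPVTRT": dark.vpvtrt}
    fig, axes = plt.subplots(len(panels), 1, figsize=(7.5, 9.5), sharex=True)
    for ax, (name, values, unit) in zip(axes, panels):
        if name in dark_panels:
            ax.plot(days, dark_panels[name][sel], color="0.75", lw=0.9)
        ax.plot(days, values[sel], color="C0", lw=0.9)
        ax.set_ylabel(f"{name}\n{unit}" if unit else name, fontsize=8)
    axes[-1].set_xlabel("day")
    fig.align_ylabels(axes)
    fig.tight_layout()
    fig.savefig(path, **(_SVG_OPTS if str(path).endswith(".svg") else {}))
    plt.close(fig)
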