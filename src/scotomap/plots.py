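"""Figure-style renderings of logged data: staircase traces, border-point
overlays, heat maps and psychometric scaling curves.  All functions are
pure renderings — inputs are never mutated — and return a matplotlib
Figure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .geometry import FieldPoint
from .validation import HeatMapGrid, SigmoidFit, VisibilityMatrix

__all__ = ["plot_trace", "plot_overlay", "plot_heatmap", "plot_curve"]


def plot_trace(trace: pd.DataFrame):
    """Increment vs successful-trial index with responses and reversal marks."""
    if len(trace) == 0:
        raise ValueError("empty staircase trace")
    ok = trace[trace["fixation_ok"]] if "fixation_ok" in trace else trace
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(1, len(ok) + 1)
    y = ok["increment_pix"].to_numpy()
    ax.plot(x, y, "-o", color="tab:blue", ms=5)
    ax.axhline(0.0, color="gray", lw=0.8, ls=":")
    for xi, yi, resp, rev in zip(x, y, ok["response"], ok["reversal"]):
        ax.annotate(resp[0].upper(), (xi, yi), textcoords="offset points", xytext=(0, 7), ha="center", fontsize=8)
        if rev:
            ax.annotate("R", (xi, yi), textcoords="offset points", xytext=(0, -14), ha="center", fontsize=8, color="tab:red")
    ax.set_xlabel("successful trial")
    ax.set_ylabel("increment (pix, + toward blind-spot centre)")
    fig.tight_layout()
    return fig


def _closed(points: list[FieldPoint]) -> tuple[np.ndarray, np.ndarray]:
    # order vertices by angle around the centroid so the polygon closes sanely
    cx = np.mean([p.x for p in points])
    cy = np.mean([p.y for p in points])
    pts = sorted(points, key=lambda p: np.arctan2(p.y - cy, p.x - cx))
    xs = [p.x for p in pts] + [pts[0].x]
    ys = [p.y for p in pts] + [pts[0].y]
    return np.asarray(xs), np.asarray(ys)


def plot_overlay(
    raw_points: list[FieldPoint],
    adjusted_points: list[FieldPoint],
    location: FieldPoint,
):
    """Raw (dashed) and staircase-adjusted (solid) border polygons."""
    if len(raw_points) < 3 or len(adjusted_points) < 3:
        raise ValueError("need at least 3 border points per stage")
    fig, ax = plt.subplots(figsize=(5, 5))
    for pts, style, label in ((raw_points, "--", "raw"), (adjusted_points, "-", "adjusted")):
        xs, ys = _closed(pts)
        ax.plot(xs, ys, style, marker="o", ms=4, label=label)
    ax.plot([location.x], [location.y], "k+", ms=10, label="location")
    ax.set_xlabel("horizontal eccentricity (deg)")
    ax.set_ylabel("vertical eccentricity (deg)")
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def plot_heatmap(matrix: VisibilityMatrix, grid: HeatMapGrid, overlay: list[FieldPoint] | None = None):
    """Visibility matrix in field coordinates, optional border-point overlay."""
    if matrix.values.shape != (grid.rows, grid.cols):
        raise ValueError("matrix and grid shapes do not match")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    extent = [
        grid.center.x - grid.width / 2,
        grid.center.x + grid.width / 2,
        grid.center.y - grid.height / 2,
        grid.center.y + grid.height / 2,
    ]
    im = ax.imshow(matrix.values, origin="upper", extent=extent, vmin=0.0, vmax=1.0, cmap="viridis", aspect="auto")
    fig.colorbar(im, ax=ax, label="visibility")
    if overlay:
        ax.plot([p.x for p in overlay], [p.y for p in overlay], "wo", mec="k", ms=5)
    ax.set_xlabel("horizontal eccentricity (deg)")
    ax.set_ylabel("vertical eccentricity (deg)")
    fig.tight_layout()
    return fig


def plot_curve(sizes, proportions, fit: SigmoidFit | None = None, n_trials: int = 10):
    """Scaling curve with binomial standard-error bars and optional fit."""
    sizes = np.asarray(sizes, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if sizes.shape != props.shape:
        raise ValueError("sizes and proportions must have matching lengths")
    se = np.sqrt(props * (1 - props) / n_trials)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(sizes, 100 * props, yerr=100 * se, fmt="o", capsize=3, label="observed")
    if fit is not None:
        xs = np.linspace(sizes.min(), sizes.max(), 200)
        ax.plot(xs, fit.predict(xs), "-", label=f"logistic fit (x0={fit.x0:.2f})")
        ax.axhline(50.0, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("scaling coefficient")
    ax.set_ylabel("visibility (%)")
    ax.set_ylim(-5, 105)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
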