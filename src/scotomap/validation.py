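"""Validation procedures: perimetric heat map, scaling curve, sigmoid fit.

*Heat Map* grids a rectangle covering the estimated blind spot (1.1x the
estimated width, 1.2x the estimated height) into rows x cols congruent
cells and measures the per-cell detection proportion over repeated trials
of a cell-filling target; sub-threshold cells constitute the mapped blind
spot.  *Scaling* presents centre-anchored ellipses with the estimated
aspect ratio at 10 scaling coefficients in [0.6, 1.2] and records the
detection proportion per size; the resulting curve is summarised by a
logistic ``f(x) = 100% / (1 + exp(-t (x - x0)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import FieldPoint
from .observer import ScotomaObserver, Stimulus, answer

__all__ = [
    "HeatMapGrid",
    "VisibilityMatrix",
    "HeatmapEstimate",
    "ScalingResult",
    "SigmoidFit",
    "build_heatmap_grid",
    "run_heatmap",
    "blind_spot_from_heatmap",
    "scaling_coefficients",
    "run_scaling",
    "fit_sigmoid",
    "zero_visible_size",
]

WIDTH_FACTOR = 1.1
HEIGHT_FACTOR = 1.2


@dataclass(frozen=True)
class HeatMapGrid:
    """Rows x cols grid of congruent cells tiling a field rectangle.

    Cells are indexed row-major with row 0 at the *top* (largest y),
    matching matrix display order.
    """

    center: FieldPoint
    width: float
    height: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0 and self.rows >= 1 and self.cols >= 1):
            raise ValueError("grid requires positive extents and counts")

    @property
    def cell_width(self) -> float:
        return self.width / self.cols

    @property
    def cell_height(self) -> float:
        return self.height / self.rows

    def cell_rect(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell."""
        x0 = self.center.x - self.width / 2.0 + col * self.cell_width
        y1 = self.center.y + self.height / 2.0 - row * self.cell_height
        return (x0, y1 - self.cell_height, x0 + self.cell_width, y1)

    def cell_center(self, row: int, col: int) -> FieldPoint:
        x0, y0, x1, y1 = self.cell_rect(row, col)
        return FieldPoint((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def build_heatmap_grid(
    center: FieldPoint,
    est_width: float,
    est_height: float,
    rows: int = 10,
    cols: int = 10,
) -> HeatMapGrid:
    """Grid covering the estimated blind spot with the standard margins."""
    if not (est_width > 0 and est_height > 0):
        raise ValueError("estimated sizes must be positive")
    return HeatMapGrid(center, WIDTH_FACTOR * est_width, HEIGHT_FACTOR * est_height, rows, cols)


@dataclass
class VisibilityMatrix:
    """Per-cell detection proportions (each a multiple of 1/trials_per_cell)."""

    values: np.ndarray
    trials_per_cell: int
    log: list[dict] | None = None


def run_heatmap(
    grid: HeatMapGrid,
    obs: ScotomaObserver,
    rng: np.random.Generator,
    trials_per_cell: int = 10,
    fixation_tolerance: float | None = None,
) -> VisibilityMatrix:
    """Measure the visual-sensitivity matrix over the grid.

    Trials are the cells x repetitions in one randomly shuffled order;
    each trial presents a rectangular target fully filling its cell.  When
    ``fixation_tolerance`` is given, out-of-tolerance trials are logged
    and re-run without advancing the count.
    """
    order = np.repeat(np.arange(grid.rows * grid.cols), trials_per_cell)
    rng.shuffle(order)
    yes = np.zeros((grid.rows, grid.cols))
    log: list[dict] = []
    for seq, flat in enumerate(order):
        row, col = divmod(int(flat), grid.cols)
        stim = Stimulus("rect", grid.cell_center(row, col), grid.cell_width, grid.cell_height)
        while True:
            seen, gaze = answer(stim, obs, rng)
            valid = fixation_tolerance is None or gaze.norm() <= fixation_tolerance
            log.append(
                {
                    "seq": seq,
                    "row": row,
                    "col": col,
                    "response": "yes" if seen else "no",
                    "fixation_ok": valid,
                }
            )
            if valid:
                break
        yes[row, col] += seen
    return VisibilityMatrix(yes / trials_per_cell, trials_per_cell, log)


@dataclass
class HeatmapEstimate:
    cells: list[tuple[int, int]]
    width: float
    height: float


def blind_spot_from_heatmap(
    matrix: VisibilityMatrix, grid: HeatMapGrid, threshold: float = 0.5
) -> HeatmapEstimate:
    """Extract the sub-threshold cell set and its outer-edge extents.

    The blind-spot cells are those with visibility strictly below
    ``threshold``; the width is the separation between the outer edges of
    the leftmost and rightmost member columns, the height likewise for
    rows.  An empty set yields zero sizes.  Connectivity is deliberately
    not enforced.
    """
    rows, cols = matrix.values.shape
    if (rows, cols) != (grid.rows, grid.cols):
        raise ValueError("matrix and grid shapes do not match")
    members = [(r, c) for r in range(rows) for c in range(cols) if matrix.values[r, c] < threshold]
    if not members:
        return HeatmapEstimate([], 0.0, 0.0)
    rs = [r for r, _ in members]
    cs = [c for _, c in members]
    width = (max(cs) - min(cs) + 1) * grid.cell_width
    height = (max(rs) - min(rs) + 1) * grid.cell_height
    return HeatmapEstimate(members, width, height)


def scaling_coefficients(n: int = 10, lo: float = 0.6, hi: float = 1.2) -> np.ndarray:
    """Evenly spaced scaling coefficients from ``lo`` to ``hi`` inclusive."""
    if n < 2:
        raise ValueError("need at least 2 coefficients")
    if lo >= hi:
        raise ValueError("lo must be below hi")
    return np.linspace(lo, hi, n)


@dataclass
class ScalingResult:
    coefficients: np.ndarray
    proportions: np.ndarray
    trials_per_size: int
    log: list[dict] | None = None


def run_scaling(
    center: FieldPoint,
    est_width: float,
    est_height: float,
    obs: ScotomaObserver,
    rng: np.random.Generator,
    n_sizes: int = 10,
    trials_per_size: int = 10,
    lo: float = 0.6,
    hi: float = 1.2,
    fixation_tolerance: float | None = None,
) -> ScalingResult:
    """Detection proportion per scaling coefficient.

    Each coefficient ``c`` is tested with an elliptical target of size
    ``(c * est_width, c * est_height)`` at the estimated centre, keeping
    the estimated aspect ratio.
    """
    coeffs = scaling_coefficients(n_sizes, lo, hi)
    props = np.zeros(n_sizes)
    log: list[dict] = []
    for i, c in enumerate(coeffs):
        stim = Stimulus("ellipse", center, c * est_width, c * est_height)
        n_yes = 0
        for rep in range(trials_per_size):
            while True:
                seen, gaze = answer(stim, obs, rng)
                valid = fixation_tolerance is None or gaze.norm() <= fixation_tolerance
                log.append(
                    {
                        "coefficient": float(c),
                        "rep": rep,
                        "response": "yes" if seen else "no",
                        "fixation_ok": valid,
                    }
                )
                if valid:
                    break
            n_yes += seen
        props[i] = n_yes / trials_per_size
    return ScalingResult(coeffs, props, trials_per_size, log)


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic visibility-vs-size fit ``f(x) = 100 / (1 + exp(-t (x - x0)))``.

    ``x0`` is the scaling coefficient of 50 % visibility and ``t`` the
    (positive) slope constant.
    """

    t: float
    x0: float

    def predict(self, x) -> np.ndarray:
        """Fitted visibility in percent."""
        return 100.0 / (1.0 + np.exp(-self.t * (np.asarray(x, dtype=float) - self.x0)))


def _logistic_pct(x, t, x0):
    return 100.0 / (1.0 + np.exp(-t * (x - x0)))


def fit_sigmoid(sizes, proportions) -> SigmoidFit:
    """Least-squares logistic fit to a scaling curve.

    ``proportions`` are detection proportions in [0, 1]; the fit is done
    on the percentage scale.  Multi-start over candidate inflection points
    guards against local minima; degenerate data (all proportions equal)
    are unfittable and raise ``ValueError``.
    """
    x = np.asarray(sizes, dtype=float)
    y = 100.0 * np.asarray(proportions, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct sizes")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate scaling data: all proportions identical")
    best: tuple[float, float, float] | None = None
    for x0_start in np.unique(x):
        for t_start in (5.0, 10.0, 30.0):
            try:
                popt, _ = curve_fit(
                    _logistic_pct,
                    x,
                    y,
                    p0=(t_start, x0_start),
                    bounds=([1e-9, x.min() - 10.0], [1e6, x.max() + 10.0]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((y - _logistic_pct(x, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, float(popt[0]), float(popt[1]))
    if best is None:
        raise ValueError("sigmoid fit failed to converge from every start")
    return SigmoidFit(t=best[1], x0=best[2])


def zero_visible_size(sizes, proportions) -> float | None:
    """Largest tested coefficient at and below which nothing was ever seen.

    Returns ``None`` when already the smallest tested size drew positive
    responses.
    """
    x = np.asarray(sizes, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("sizes must be strictly ascending")
    last = None
    for xi, pi in zip(x, p):
        if pi == 0.0:
            last = float(xi)
        else:
            break
    return last
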