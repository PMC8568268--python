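"""Simulated observer with a ground-truth elliptical scotoma.

The observer stands in for a human participant (and eye tracker): it holds
an upright, axis-aligned elliptical blind region in field coordinates and
answers "did you see it?" trials stochastically.  The visibility of a point
follows a logistic psychometric function of the signed distance to the
ellipse boundary, floored/ceiled by guess and lapse rates; gaze error is a
single isotropic Gaussian offset per trial; positional reports on the
moving-probe task carry their own Gaussian click error.

The default parameters mirror the average healthy right-eye blind spot:
centre 16.0 deg temporal and 2.05 deg below the meridian, 6.28 deg wide by
7.02 deg tall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import FieldPoint

__all__ = [
    "ScotomaObserver",
    "Stimulus",
    "signed_boundary_distance",
    "point_visibility",
    "stimulus_visibility",
    "answer",
    "random_observers",
    "DEFAULT_OBSERVER",
]


@dataclass(frozen=True)
class ScotomaObserver:
    """Ground-truth elliptical blind spot plus response-noise parameters.

    Parameters
    ----------
    center:
        Ellipse centre in field coordinates (deg).
    width, height:
        Full horizontal / vertical diameters (deg), strictly positive.
    boundary_slope:
        Logistic softness of the visibility transition in deg; ``0`` gives
        a sharp (step) boundary.
    lapse_rate:
        Probability of answering "no" to a clearly visible stimulus.
    guess_rate:
        Probability of answering "yes" to a clearly invisible stimulus.
    fixation_jitter_sd:
        Isotropic Gaussian SD of gaze error (deg).
    click_error_sd:
        SD of positional error on moving-probe reports (deg).
    """

    center: FieldPoint = field(default_factory=lambda: FieldPoint(16.00, -2.05))
    width: float = 6.28
    height: float = 7.02
    boundary_slope: float = 0.15
    lapse_rate: float = 0.02
    guess_rate: float = 0.02
    fixation_jitter_sd: float = 0.3
    click_error_sd: float = 0.2

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("scotoma width and height must be strictly positive")
        if not (0 <= self.lapse_rate and 0 <= self.guess_rate):
            raise ValueError("lapse and guess rates must be non-negative")
        if not self.lapse_rate + self.guess_rate < 1:
            raise ValueError("lapse_rate + guess_rate must be below 1")
        for name in ("boundary_slope", "fixation_jitter_sd", "click_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


DEFAULT_OBSERVER = ScotomaObserver()


@dataclass(frozen=True)
class Stimulus:
    """Axis-aligned visual target: a point, an ellipse, or a rectangle.

    ``width`` and ``height`` are full extents in deg (0 for a point).
    """

    kind: str
    center: FieldPoint
    width: float = 0.0
    height: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "ellipse", "rect"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.width < 0 or self.height < 0:
            raise ValueError("stimulus extents must be non-negative")


def signed_boundary_distance(p: FieldPoint, obs: ScotomaObserver) -> float:
    """Approximate signed Euclidean distance from ``p`` to the scotoma boundary.

    Negative inside the ellipse, zero on it, positive outside.  Computed as
    ``(r - 1) * s`` with ``r`` the elliptical radius of ``p`` and ``s`` the
    along-ray distance scale ``w*h / (2*sqrt((h*cos(th))^2 + (w*sin(th))^2))``;
    exact on the axes, smooth and monotone elsewhere, which is all the
    psychometric model needs.
    """
    dx = p.x - obs.center.x
    dy = p.y - obs.center.y
    a = obs.width / 2.0
    b = obs.height / 2.0
    r = math.hypot(dx / a, dy / b)
    theta = math.atan2(dy, dx) if (dx or dy) else 0.0
    scale = (obs.width * obs.height) / (
        2.0 * math.hypot(obs.height * math.cos(theta), obs.width * math.sin(theta))
    )
    return (r - 1.0) * scale


def _psychometric(d: float, obs: ScotomaObserver) -> float:
    if obs.boundary_slope == 0.0:
        core = 0.5 if d == 0.0 else (1.0 if d > 0.0 else 0.0)
    else:
        z = np.clip(d / obs.boundary_slope, -500.0, 500.0)
        core = 1.0 / (1.0 + math.exp(-z))
    return obs.guess_rate + (1.0 - obs.guess_rate - obs.lapse_rate) * core


def point_visibility(
    p: FieldPoint,
    obs: ScotomaObserver,
    gaze_offset: FieldPoint = FieldPoint(0.0, 0.0),
) -> float:
    """Probability that a point target at ``p`` is reported as seen.

    ``gaze_offset`` is the current gaze error: a stimulus at ``p`` lands on
    the retina where ``p - gaze_offset`` would with perfect fixation.  The
    see-probability is ``guess + (1 - guess - lapse) * sigma(d / slope)``
    where ``d`` is the signed boundary distance; a zero slope degenerates
    to the step function (0 inside, 1 outside, 0.5 on the boundary).
    """
    return _psychometric(signed_boundary_distance(p - gaze_offset, obs), obs)


# Deterministic sampling lattice for extended targets: 64 outline points
# plus 25 interior points ("seen if any part is visible").
_N_OUTLINE = 64
_INTERIOR_FRACS = (0.0, 0.2, 0.4, 0.6, 0.8)


def _sample_points(s: Stimulus) -> list[FieldPoint]:
    cx, cy = s.center.x, s.center.y
    if s.kind == "point" or (s.width == 0.0 and s.height == 0.0):
        return [s.center]
    pts: list[FieldPoint] = []
    if s.kind == "ellipse":
        a, b = s.width / 2.0, s.height / 2.0
        for k in range(_N_OUTLINE):
            t = 2.0 * math.pi * k / _N_OUTLINE
            pts.append(FieldPoint(cx + a * math.cos(t), cy + b * math.sin(t)))
        for fr in _INTERIOR_FRACS:
            for k in range(5):
                t = 2.0 * math.pi * k / 5.0
                pts.append(FieldPoint(cx + fr * a * math.cos(t), cy + fr * b * math.sin(t)))
    else:  # rect
        x0, x1 = cx - s.width / 2.0, cx + s.width / 2.0
        y0, y1 = cy - s.height / 2.0, cy + s.height / 2.0
        # the four corners are the extreme points and must be sampled exactly
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        pts.extend(FieldPoint(*c) for c in corners)
        n_edge = (_N_OUTLINE - 4) // 4
        for (ax, ay), (bx, by) in zip(corners, corners[1:] + corners[:1]):
            for k in range(1, n_edge + 1):
                f = k / (n_edge + 1)
                pts.append(FieldPoint(ax + f * (bx - ax), ay + f * (by - ay)))
        for fx in range(1, 6):
            for fy in range(1, 6):
                pts.append(
                    FieldPoint(x0 + s.width * fx / 6.0, y0 + s.height * fy / 6.0)
                )
    return pts


def stimulus_visibility(
    s: Stimulus,
    obs: ScotomaObserver,
    gaze_offset: FieldPoint = FieldPoint(0.0, 0.0),
) -> float:
    """See-probability of an extended target: max point visibility over a
    deterministic sample of its outline and interior (a stimulus is seen if
    any part of it is seen).  Point stimuli reduce to
    :func:`point_visibility`."""
    return max(point_visibility(p, obs, gaze_offset) for p in _sample_points(s))


def answer(
    s: Stimulus,
    obs: ScotomaObserver,
    rng: np.random.Generator,
) -> tuple[bool, FieldPoint]:
    """Simulate one yes/no trial.

    Draws a single gaze offset ``N(0, fixation_jitter_sd^2 I)`` for the
    trial, then a Bernoulli response with the stimulus's see-probability
    under that gaze.  Returns ``(seen, gaze_offset)`` so callers can log
    and gate on the gaze sample.
    """
    gx, gy = rng.normal(0.0, obs.fixation_jitter_sd, size=2)
    gaze = FieldPoint(float(gx), float(gy))
    p_see = stimulus_visibility(s, obs, gaze)
    return bool(rng.random() < p_see), gaze


def random_observers(
    n: int,
    rng: np.random.Generator,
    center_h: tuple[float, float] = (15.0, 17.0),
    center_v: tuple[float, float] = (-4.5, -0.5),
    width: tuple[float, float] = (5.4, 7.5),
    height: tuple[float, float] = (5.8, 8.2),
) -> list[ScotomaObserver]:
    """Draw ``n`` observers with uniformly distributed scotoma geometry.

    Noise parameters are kept at the defaults; ranges mirror the spread
    seen across healthy observers.  Used by the ``fixtures`` CLI command
    for batch simulation studies.
    """
    out = []
    for _ in range(n):
        out.append(
            ScotomaObserver(
                center=FieldPoint(float(rng.uniform(*center_h)), float(rng.uniform(*center_v))),
                width=float(rng.uniform(*width)),
                height=float(rng.uniform(*height)),
            )
        )
    return out
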