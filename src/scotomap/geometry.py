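"""Screen and visual-field geometry.

Two coordinate frames are used throughout the package:

* **Screen coordinates** (:class:`ScreenPoint`) — pixels, origin at the
  geometric centre of the monitor, x rightward, y upward.
* **Field coordinates** (:class:`FieldPoint`) — degrees of visual angle
  (eccentricity) relative to the fixation object, same axis conventions.
  The fixation object itself is at ``(0, 0)``; negative vertical values
  lie below the horizontal meridian.

Visual angle is computed *per axis* as ``arctan(physical offset /
viewing distance)``, the convention under which a 300 px offset on the
default 40 cm / 1280 px monitor viewed from 57 cm subtends 9.34 deg.
No ``2*arctan(half-extent)`` convention is used anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScreenModel",
    "ScreenPoint",
    "FieldPoint",
    "pix_to_deg",
    "deg_to_pix",
    "screen_to_field",
    "field_to_screen",
    "DEFAULT_SCREEN",
    "DEFAULT_FIXATION",
]


@dataclass(frozen=True)
class ScreenModel:
    """Physical monitor plus viewing geometry.

    Parameters
    ----------
    width_cm, height_cm:
        Physical display size in centimetres.
    width_pix, height_pix:
        Display resolution in pixels.
    viewing_distance_cm:
        Eye-to-screen-centre distance in centimetres.

    Pixels must be square: horizontal and vertical pixel densities may
    differ by at most 1 %, otherwise construction fails.
    """

    width_cm: float
    height_cm: float
    width_pix: int
    height_pix: int
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in (
            "width_cm",
            "height_cm",
            "width_pix",
            "height_pix",
            "viewing_distance_cm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScreenModel.{name} must be strictly positive")
        dx = self.width_pix / self.width_cm
        dy = self.height_pix / self.height_cm
        if abs(dx - dy) > 0.01 * dx:
            raise ValueError(
                "non-square pixels: horizontal density "
                f"{dx:.4g} px/cm vs vertical {dy:.4g} px/cm differ by more than 1%"
            )

    @property
    def cm_per_pix(self) -> float:
        return self.width_cm / self.width_pix


@dataclass(frozen=True)
class ScreenPoint:
    """Point on the display in pixels, origin at the screen centre."""

    x: float
    y: float


@dataclass(frozen=True)
class FieldPoint:
    """Visual-field location in degrees relative to fixation.

    ``x`` is the horizontal eccentricity (positive = temporal/right for a
    right-eye blind spot), ``y`` the vertical eccentricity (negative =
    below the horizontal meridian).
    """

    x: float
    y: float

    def __add__(self, other: "FieldPoint") -> "FieldPoint":
        return FieldPoint(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "FieldPoint") -> "FieldPoint":
        return FieldPoint(self.x - other.x, self.y - other.y)

    def norm(self) -> float:
        return math.hypot(self.x, self.y)


#: The apparatus the default configuration mirrors: a 40 x 30 cm CRT at
#: 1280 x 960 px viewed from 57 cm, fixation 300 px left of centre.
DEFAULT_SCREEN = ScreenModel(40.0, 30.0, 1280, 960, 57.0)
DEFAULT_FIXATION = ScreenPoint(-300.0, 0.0)


def pix_to_deg(offset_pix: float, screen: ScreenModel = DEFAULT_SCREEN) -> float:
    """Convert a signed pixel offset along one axis to degrees of visual angle.

    Odd, strictly increasing, and bounded in magnitude by 90 deg.  For
    small offsets it approaches the linear small-angle rate (about
    1 deg/cm at 57 cm).
    """
    return math.degrees(math.atan(offset_pix * screen.cm_per_pix / screen.viewing_distance_cm))


def deg_to_pix(angle_deg: float, screen: ScreenModel = DEFAULT_SCREEN) -> float:
    """Inverse of :func:`pix_to_deg`; ``|angle_deg|`` must be below 90."""
    if abs(angle_deg) >= 90.0:
        raise ValueError(f"angle {angle_deg} deg is outside the visual field (|angle| < 90)")
    return math.tan(math.radians(angle_deg)) * screen.viewing_distance_cm / screen.cm_per_pix


def screen_to_field(
    p: ScreenPoint,
    fixation: ScreenPoint = DEFAULT_FIXATION,
    screen: ScreenModel = DEFAULT_SCREEN,
) -> FieldPoint:
    """Express a screen point as an eccentricity relative to fixation.

    Applied per axis: ``FieldPoint(pix_to_deg(p.x - fix.x), pix_to_deg(p.y - fix.y))``.
    The fixation point itself maps to ``(0, 0)``.
    """
    return FieldPoint(
        pix_to_deg(p.x - fixation.x, screen),
        pix_to_deg(p.y - fixation.y, screen),
    )


def field_to_screen(
    f: FieldPoint,
    fixation: ScreenPoint = DEFAULT_FIXATION,
    screen: ScreenModel = DEFAULT_SCREEN,
) -> ScreenPoint:
    """Inverse of :func:`screen_to_field`."""
    return ScreenPoint(
        fixation.x + deg_to_pix(f.x, screen),
        fixation.y + deg_to_pix(f.y, screen),
    )
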