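"""JSON configuration for full runs.

A config file has four blocks — ``screen``, ``observer``, ``protocol``
and (inside protocol) ``validation`` — every key optional, defaults
mirroring the canonical apparatus (40 x 30 cm, 1280 x 960 px, 57 cm,
fixation 300 px left of centre) and the average healthy blind spot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .border import DEFAULT_PRIOR, FieldRect
from .geometry import FieldPoint, ScreenModel, ScreenPoint
from .observer import ScotomaObserver
from .session import BlockProtocol, ValidationSpec
from .staircase import StaircaseRules

__all__ = ["RunConfig", "default_config", "load_config", "config_from_dict"]


@dataclass(frozen=True)
class RunConfig:
    screen: ScreenModel
    fixation: ScreenPoint
    observer: ScotomaObserver
    protocol: BlockProtocol


def default_config() -> dict:
    """The default configuration as a plain JSON-serialisable dict."""
    return {
        "screen": {
            "width_cm": 40.0,
            "height_cm": 30.0,
            "width_pix": 1280,
            "height_pix": 960,
            "viewing_distance_cm": 57.0,
            "fixation_pix": [-300.0, 0.0],
        },
        "observer": {
            "center": [16.00, -2.05],
            "width": 6.28,
            "height": 7.02,
            "boundary_slope": 0.15,
            "lapse_rate": 0.02,
            "guess_rate": 0.02,
            "fixation_jitter_sd": 0.3,
            "click_error_sd": 0.2,
        },
        "protocol": {
            "mode": "low",
            "round_trips": 3,
            "fixation_tolerance": 1.5,
            "prior_region": [12.0, 20.0, -6.0, 2.0],
            "staircase": {
                "initial_increment": 50,
                "step_sizes": [30, 15, 7, 3],
                "n_trials": 20,
                "n_reversals": 4,
                "up_count": 1,
                "down_count": 3,
                "require_reversals": False,
            },
            "validation": {
                "kind": "scaling",
                "rows": 10,
                "cols": 10,
                "trials_per_cell": 10,
                "n_sizes": 10,
                "trials_per_size": 10,
                "lo": 0.6,
                "hi": 1.2,
            },
        },
    }


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


def config_from_dict(cfg: dict) -> RunConfig:
    """Validate and materialise a configuration dict."""
    _check_keys(cfg, {"screen", "observer", "protocol"}, "top-level")
    scr = {**default_config()["screen"], **cfg.get("screen", {})}
    _check_keys(
        scr,
        {"width_cm", "height_cm", "width_pix", "height_pix", "viewing_distance_cm", "fixation_pix"},
        "screen",
    )
    fix = scr.pop("fixation_pix")
    screen = ScreenModel(**scr)
    if not (abs(fix[0]) <= screen.width_pix / 2 and abs(fix[1]) <= screen.height_pix / 2):
        raise ValueError("fixation_pix lies off-screen")
    fixation = ScreenPoint(float(fix[0]), float(fix[1]))

    ob = {**default_config()["observer"], **cfg.get("observer", {})}
    center = ob.pop("center")
    observer = ScotomaObserver(center=FieldPoint(float(center[0]), float(center[1])), **ob)

    pr = {**default_config()["protocol"], **cfg.get("protocol", {})}
    _check_keys(
        pr,
        {"mode", "round_trips", "fixation_tolerance", "prior_region", "staircase", "validation"},
        "protocol",
    )
    st = {**default_config()["protocol"]["staircase"], **pr["staircase"]}
    st["step_sizes"] = tuple(float(s) for s in st["step_sizes"])
    va = {**default_config()["protocol"]["validation"], **cfg.get("protocol", {}).get("validation", {})}
    region = pr["prior_region"]
    protocol = BlockProtocol(
        mode=pr["mode"],
        round_trips=int(pr["round_trips"]),
        staircase=StaircaseRules(**st),
        validation=ValidationSpec(**va),
        fixation_tolerance=float(pr["fixation_tolerance"]),
        prior=FieldRect(*map(float, region)) if region else DEFAULT_PRIOR,
    )
    return RunConfig(screen=screen, fixation=fixation, observer=observer, protocol=protocol)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON configuration file."""
    with open(path) as fh:
        return config_from_dict(json.load(fh))
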