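"""Transformed 1-up-3-down staircase refinement of border points.

Each raw border point is re-examined with a yes/no staircase along the ray
from the point toward the estimated blind-spot centre.  The *increment* is
the signed displacement in pixels along that ray (0 = the raw point,
positive = toward the centre, i.e. deeper into the blind spot).

Rules: one "yes" (seen) moves the target one step *up* (inward); before
the first reversal the procedure is 1-up-1-down, so a single "no" moves it
one step down; after the first reversal three *consecutive* "no" answers
are required per down step (any "yes" resets the count).  Every reversal
advances the step-size schedule (largest first, capped at the smallest
step), and the reversal-causing move already uses the new step.  The
threshold is the final trial's increment ("final-1-trial").

The 1-up-3-down rule converges where the probability of a "no" answer is
``0.5**(1/3) ~ 0.794``, i.e. the adjusted points are ~79 % invisible
(21 % visible); :func:`convergence_probability` estimates this long-run
level by Monte-Carlo against an arbitrary monotone psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FieldPoint, ScreenModel, DEFAULT_SCREEN, pix_to_deg
from .observer import ScotomaObserver, Stimulus, answer

__all__ = [
    "StaircaseRules",
    "StaircaseState",
    "TrialOutcome",
    "staircase_step",
    "run_staircase",
    "StaircaseRun",
    "convergence_probability",
]


@dataclass(frozen=True)
class StaircaseRules:
    """Staircase parameters.

    ``step_sizes`` is the reversal-driven schedule, applied largest first;
    it must be strictly decreasing.  ``down_count`` is the number of
    consecutive "no" answers required per down step after the first
    reversal (3 for the standard 1-up-3-down; 1 gives plain 1-up-1-down).
    ``require_reversals`` optionally extends the run past ``n_trials``
    until ``n_reversals`` reversals have occurred.
    """

    initial_increment: float = 50.0
    step_sizes: tuple[float, ...] = (30.0, 15.0, 7.0, 3.0)
    n_trials: int = 20
    n_reversals: int = 4
    up_count: int = 1
    down_count: int = 3
    require_reversals: bool = False

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.step_sizes, self.step_sizes[1:])):
            raise ValueError("step_sizes must be strictly decreasing (largest first)")
        if self.n_trials < self.n_reversals:
            raise ValueError("n_trials must be at least n_reversals")
        if self.up_count != 1:
            raise ValueError("only 1-up rules are supported")
        if self.down_count < 1:
            raise ValueError("down_count must be >= 1")


@dataclass
class TrialOutcome:
    trial_index: int
    increment: float  # level presented on this trial
    response: str
    moved: int  # -1 down, 0 hold, +1 up
    reversal: bool
    step_size: float  # step in force for the move (0 on hold)


@dataclass
class StaircaseState:
    """Mutable state of one staircase run."""

    increment: float
    trial_index: int = 0
    step_index: int = 0
    reversal_count: int = 0
    consecutive_no: int = 0
    last_move: int = 0  # -1 down, +1 up, 0 = none yet
    history: list[TrialOutcome] = field(default_factory=list)

    @classmethod
    def fresh(cls, rules: StaircaseRules) -> "StaircaseState":
        return cls(increment=rules.initial_increment)


def staircase_step(state: StaircaseState, response: str, rules: StaircaseRules) -> StaircaseState:
    """Consume one response for the currently presented increment.

    ``response`` is ``"yes"`` (seen) or ``"no"``.  A "yes" always moves up
    and resets the no-counter.  A "no" moves down immediately before the
    first reversal, and only on the ``down_count``-th consecutive "no"
    afterwards.  A move opposite to the previous move is a reversal, which
    advances the step schedule; the reversal-causing move itself uses the
    new, smaller step.
    """
    if response not in ("yes", "no"):
        raise ValueError(f"response must be 'yes' or 'no', got {response!r}")
    presented = state.increment
    if response == "yes":
        state.consecutive_no = 0
        direction = 1
        do_move = True
    else:
        if state.reversal_count == 0 or rules.down_count == 1:
            direction = -1
            do_move = True
        else:
            state.consecutive_no += 1
            do_move = state.consecutive_no >= rules.down_count
            direction = -1
            if do_move:
                state.consecutive_no = 0
    reversal = False
    step = 0.0
    if do_move:
        if state.last_move != 0 and direction != state.last_move:
            reversal = True
            state.reversal_count += 1
            state.step_index = min(state.step_index + 1, len(rules.step_sizes) - 1)
        step = rules.step_sizes[state.step_index]
        state.increment = presented + direction * step
        state.last_move = direction
    state.trial_index += 1
    state.history.append(
        TrialOutcome(state.trial_index, presented, response, direction if do_move else 0, reversal, step)
    )
    return state


@dataclass
class StaircaseRun:
    adjusted_point: FieldPoint
    final_increment: float
    state: StaircaseState
    trace: list[dict]  # one row per attempted trial, incl. invalid fixations


def run_staircase(
    initial_point: FieldPoint,
    center: FieldPoint,
    obs: ScotomaObserver,
    rules: StaircaseRules,
    rng: np.random.Generator,
    screen: ScreenModel = DEFAULT_SCREEN,
    fixation_tolerance: float | None = 1.5,
) -> StaircaseRun:
    """Refine one border point against the simulated observer.

    Each trial presents a point target at ``initial_point`` displaced
    toward ``center`` by the current increment (pixels, converted to
    degrees through the screen model).  Trials whose sampled gaze falls
    outside ``fixation_tolerance`` are logged, discarded and re-run; the
    staircase consumes exactly ``rules.n_trials`` successful trials (or
    more when ``require_reversals`` is set and reversals are still
    outstanding).  The adjusted point sits at the final trial's increment
    along the same ray.
    """
    ray = center - initial_point
    ray_len = ray.norm()
    if ray_len == 0:
        raise ValueError("initial point coincides with the estimated centre")
    ux, uy = ray.x / ray_len, ray.y / ray_len

    def point_at(increment_pix: float) -> FieldPoint:
        d = pix_to_deg(increment_pix, screen)
        return FieldPoint(initial_point.x + ux * d, initial_point.y + uy * d)

    state = StaircaseState.fresh(rules)
    trace: list[dict] = []
    attempts = 0
    while True:
        done = state.trial_index >= rules.n_trials
        if done and rules.require_reversals:
            done = state.reversal_count >= rules.n_reversals
        if done:
            break
        attempts += 1
        if attempts > 1000 * rules.n_trials:
            raise RuntimeError("staircase exceeded the re-run attempt limit")
        presented = state.increment
        target = point_at(presented)
        seen, gaze = answer(Stimulus("point", target), obs, rng)
        valid = fixation_tolerance is None or gaze.norm() <= fixation_tolerance
        row = {
            "trial_index": state.trial_index + 1,
            "increment_pix": presented,
            "response": "yes" if seen else "no",
            "fixation_ok": valid,
            "gaze_x": gaze.x,
            "gaze_y": gaze.y,
            "reversal": False,
            "step_size": 0.0,
        }
        if not valid:
            row["trial_index"] = state.trial_index  # did not advance
            trace.append(row)
            continue
        staircase_step(state, row["response"], rules)
        out = state.history[-1]
        row["reversal"] = out.reversal
        row["step_size"] = out.step_size
        trace.append(row)
    final = state.history[-1].increment
    return StaircaseRun(point_at(final), final, state, trace)


def convergence_probability(
    rules: StaircaseRules,
    psychometric,
    n_runs: int,
    rng: np.random.Generator,
    n_trials: int = 200,
) -> float:
    """Monte-Carlo estimate of P("no") at the staircase's converged level.

    ``psychometric`` maps an increment level to P("yes") and must be
    monotone non-increasing in the level (deeper inside the blind spot is
    less visible).  Each of ``n_runs`` staircases is run for ``n_trials``
    (at least 200) trials on the abstract level axis; the converged level
    is the mean presented increment over the final half of each run,
    averaged across runs, and the returned value is ``1 - P(yes)`` there.

    For the default 1-up-3-down rule the transformed up-down theory
    predicts 0.5**(1/3) ~ 0.794; with ``down_count=1`` it predicts 0.5.
    """
    n_trials = max(n_trials, 200)
    probe = np.linspace(-100.0, 100.0, 9)
    vals = [psychometric(x) for x in probe]
    if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
        raise ValueError("psychometric must be monotone non-increasing in the level")
    levels = np.empty(n_runs)
    tail = n_trials // 2
    for i in range(n_runs):
        state = StaircaseState.fresh(rules)
        for _ in range(n_trials):
            p_yes = psychometric(state.increment)
            resp = "yes" if rng.random() < p_yes else "no"
            staircase_step(state, resp, rules)
        levels[i] = np.mean([t.increment for t in state.history[-tail:]])
    converged = float(levels.mean())
    return 1.0 - float(psychometric(converged))
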