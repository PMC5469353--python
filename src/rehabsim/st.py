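"""Subject-triggered (ST) controller: force-gated hold, then robot carry.

Two-state machine.  In HOLD the robot position-controls a virtual wall at
the start position while the subject pushes toward the cued target; when the
applied torque along the desired direction exceeds the threshold ``F_th``
the controller switches to MOVE and carries the passive limb to the target
along a minimum-jerk trajectory of duration ``t_ST``, then holds at the new
position.  ``F_th`` is raised session-by-session to keep the subject
challenged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .trajectory import TrajectorySpec, min_jerk

__all__ = ["STMode", "STState", "st_step", "threshold_schedule", "percent_change"]


class STMode(Enum):
    HOLD = "hold"
    MOVE = "move"


@dataclass(frozen=True)
class STState:
    """Runtime state of the subject-triggered state machine."""

    mode: STMode
    f_th: float
    t_st: float
    hold_target: float
    move_spec: Optional[TrajectorySpec] = None

    def __post_init__(self) -> None:
        if self.f_th <= 0 or self.t_st <= 0:
            raise ValueError("require f_th > 0 and t_st > 0")
        if (self.mode is STMode.MOVE) != (self.move_spec is not None):
            raise ValueError("move_spec must be present iff mode is MOVE")


def st_step(state: STState, applied_force: float, target: float, t: float):
    """Advance the ST machine one sample.

    Parameters
    ----------
    applied_force : float
        Subject torque (Nm); positive sign convention matches the joint axis.
    target : float
        Currently cued target position (deg); the desired direction is
        ``sign(target - hold_target)``.
    t : float
        Absolute time (s).

    Returns
    -------
    (state, command) : next state and commanded position (deg).  The force
    must exceed ``F_th`` *along the desired direction*; pushing away from
    the target never breaks the virtual wall.
    """
    if state.mode is STMode.HOLD:
        direction = float(np.sign(target - state.hold_target))
        if direction != 0 and applied_force * direction > state.f_th:
            spec = TrajectorySpec(
                x_start=state.hold_target, x_target=target, T_end=state.t_st, t_origin=t
            )
            state = replace(state, mode=STMode.MOVE, move_spec=spec)
            pos, _ = min_jerk(spec, t)
            return state, pos
        return state, state.hold_target
    # MOVE: robot-driven carry, subject input ignored
    spec = state.move_spec
    pos, _ = min_jerk(spec, t)
    if t >= spec.t_origin + spec.T_end:
        state = replace(state, mode=STMode.HOLD, hold_target=spec.x_target, move_spec=None)
        return state, spec.x_target
    return state, pos


def threshold_schedule(
    session_index: int,
    base_f_th: float,
    increments: float | Sequence[float] = 0.0,
) -> float:
    """Force threshold for a given session (1-based).

    ``increments`` is either a per-session fractional increase (scalar ``g``
    gives ``base * (1+g)**(k-1)``) or an explicit list of multiplicative
    factors indexed by session.  The schedule is the simulator's stand-in
    for the therapist's manual session-by-session adjustment and must be
    non-decreasing.
    """
    if session_index < 1:
        raise ValueError("session_index is 1-based")
    if np.ndim(increments) == 0:
        g = float(increments)
        if g < 0:
            raise ValueError("increments must be non-negative")
        return base_f_th * (1.0 + g) ** (session_index - 1)
    factors = np.asarray(increments, dtype=float)
    if np.any(np.diff(factors) < 0):
        raise ValueError("schedule factors must be non-decreasing")
    return base_f_th * float(factors[session_index - 1])


def percent_change(f_th: float, f_th_session1: float) -> float:
    """Percent change of the threshold relative to the first session."""
    return (f_th / f_th_session1 - 1.0) * 100.0
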