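"""Desired-trajectory generation and conditional trajectory recalculation.

Point-to-point reaching movements are commanded along a minimum-jerk quintic,
the standard model of physiological joint movement.  When the subject leads
the commanded trajectory, conditional trajectory recalculation (CTR) replans
the remainder of the movement through the subject's current state and
shortens the allotted time ``T_end`` by 1% per recalculation; a task without
any recalculation relaxes ``T_end`` by 0.2 s.  This implements the
challenge-adaptation half of the assist-as-needed paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrajectorySpec",
    "DesiredTrajectory",
    "CTRState",
    "InvalidSpecError",
    "CTRLogicError",
    "min_jerk",
    "ctr_gate",
    "ctr_recalculate",
    "allotted_time_update",
    "T_END_MIN",
    "T_END_MAX",
]

#: Allotted-time clamp (s); the adaptation rules give no natural bounds.
T_END_MIN = 0.5
T_END_MAX = 10.0


class InvalidSpecError(ValueError):
    """Raised for trajectory specifications that violate their invariants."""


class CTRLogicError(RuntimeError):
    """Raised when a CTR operation is invoked outside its precondition."""


@dataclass(frozen=True)
class TrajectorySpec:
    """One commanded point-to-point movement.

    Parameters
    ----------
    x_start, x_target : float
        Movement endpoints (deg).
    T_end : float
        Allotted movement time (s), strictly positive.
    t_origin : float
        Absolute time at which the movement starts (s).
    """

    x_start: float
    x_target: float
    T_end: float
    t_origin: float = 0.0

    def __post_init__(self) -> None:
        if not self.T_end > 0:
            raise InvalidSpecError(f"T_end must be > 0, got {self.T_end}")

    @property
    def amplitude(self) -> float:
        return self.x_target - self.x_start

    @property
    def direction(self) -> float:
        return float(np.sign(self.amplitude))


def min_jerk(spec: TrajectorySpec, t):
    """Evaluate the minimum-jerk quintic at time ``t``.

    Position is ``x_start + A (10 tau^3 - 15 tau^4 + 6 tau^5)`` with
    ``tau = (t - t_origin)/T_end``; velocity is its analytic derivative.
    Evaluation past ``T_end`` clamps to the target with zero velocity, and
    before ``t_origin`` to the start.

    Returns
    -------
    (position, velocity) : same shape as ``t`` (deg, deg/s)
    """
    a = spec.amplitude
    if isinstance(t, (int, float)):
        tau = (t - spec.t_origin) / spec.T_end
        tau = 0.0 if tau < 0.0 else (1.0 if tau > 1.0 else tau)
        t2 = tau * tau
        pos = spec.x_start + a * t2 * tau * (10.0 - 15.0 * tau + 6.0 * t2)
        vel = a / spec.T_end * 30.0 * t2 * (1.0 - tau) ** 2
        return pos, vel
    tau = np.clip((np.asarray(t, dtype=float) - spec.t_origin) / spec.T_end, 0.0, 1.0)
    pos = spec.x_start + a * tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    vel = a / spec.T_end * 30.0 * tau**2 * (1.0 - tau) ** 2
    return pos, vel


def _solve_recalc_poly(
    x0: float, v0: float, t0: float, x1: float, t1: float
) -> np.polynomial.Polynomial:
    """Quartic through (x0, v0) at t0 and (x1, 0 vel, 0 acc) at t1.

    Five boundary constraints determine the degree-4 polynomial uniquely.
    Solved in the shifted variable s = t - t0 for conditioning.
    """
    T = t1 - t0
    if T <= 0:
        raise InvalidSpecError("recalculation horizon must be positive")
    # rows: p(0), p'(0), p(T), p'(T), p''(T) for coefficients c0..c4 in s
    A = np.array(
        [
            [1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0, 0.0],
            [1.0, T, T**2, T**3, T**4],
            [0.0, 1.0, 2 * T, 3 * T**2, 4 * T**3],
            [0.0, 0.0, 2.0, 6 * T, 12 * T**2],
        ]
    )
    b = np.array([x0, v0, x1, 0.0, 0.0])
    coeffs = np.linalg.solve(A, b)
    return np.polynomial.Polynomial(coeffs, domain=[0, T], window=[0, T])


class DesiredTrajectory:
    """Nominal minimum-jerk trajectory plus any active recalculated piece.

    Calling the object returns ``(position, velocity)`` at absolute time
    ``t``.  After :meth:`recalculate` the active piece is the replanned
    polynomial; the nominal spec remains available for lead detection.
    """

    def __init__(self, spec: TrajectorySpec):
        self.spec = spec
        self._poly: np.polynomial.Polynomial | None = None
        self._coef: tuple | None = None
        self._dcoef: tuple | None = None
        self._poly_t0 = 0.0
        self._poly_t1 = 0.0

    @property
    def end_time(self) -> float:
        if self._poly is not None:
            return self._poly_t1
        return self.spec.t_origin + self.spec.T_end

    def nominal(self, t):
        return min_jerk(self.spec, t)

    def __call__(self, t):
        if self._poly is None:
            return min_jerk(self.spec, t)
        span = self._poly_t1 - self._poly_t0
        if isinstance(t, (int, float)):
            s = t - self._poly_t0
            if s >= span:
                return self.spec.x_target, 0.0
            if s < 0.0:
                s = 0.0
            pos = vel = 0.0
            for c in reversed(self._coef):
                pos = pos * s + c
            for c in reversed(self._dcoef):
                vel = vel * s + c
            return pos, vel
        s = np.clip(np.asarray(t, dtype=float) - self._poly_t0, 0.0, span)
        pos = self._poly(s)
        vel = self._poly.deriv()(s)
        done = s >= span
        return np.where(done, self.spec.x_target, pos), np.where(done, 0.0, vel)

    def recalculate(self, x_now: float, v_now: float, t_now: float, T_end_new: float) -> None:
        """Replace the active piece with a quartic through the current state."""
        t1 = self.spec.t_origin + T_end_new
        if t1 <= t_now:
            # remaining horizon exhausted: snap a short terminal piece
            t1 = t_now + 1e-3
        self._poly = _solve_recalc_poly(x_now, v_now, t_now, self.spec.x_target, t1)
        c = self._poly.coef
        self._coef = tuple(c)
        self._dcoef = tuple(c[i] * i for i in range(1, len(c)))
        self._poly_t0 = t_now
        self._poly_t1 = t1


@dataclass
class CTRState:
    """Runtime state of the conditional-trajectory-recalculation logic."""

    enabled: bool
    current_spec: TrajectorySpec
    ahead_fraction_c2p: float = 0.0
    ahead_fraction_p2c: float = 0.0
    recalc_count: int = 0
    trajectory: DesiredTrajectory = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.recalc_count < 0:
            raise InvalidSpecError("recalc_count must be >= 0")
        for f in (self.ahead_fraction_c2p, self.ahead_fraction_p2c):
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError("ahead fractions must lie in [0, 1]")
        if self.trajectory is None:
            self.trajectory = DesiredTrajectory(self.current_spec)


def _lead_fraction(position, desired_position, direction) -> float:
    """Fraction of samples where signed progress exceeds the desired progress."""
    x = np.asarray(position, dtype=float)
    xd = np.asarray(desired_position, dtype=float)
    if x.size == 0:
        raise ValueError("empty movement slice")
    return float(np.mean((x - xd) * direction > 0))


def ctr_gate(prev_movement_c2p, prev_movement_p2c, threshold: float = 0.10) -> bool:
    """Decide whether CTR may be enabled for the next task pair.

    Each argument is a movement slice: a mapping/DataFrame with ``position``
    and ``desired_position`` columns plus a ``direction`` (+1/-1) entry, or a
    ``(position, desired_position, direction)`` tuple.  CTR is enabled only
    if the subject led the nominal trajectory for at least ``threshold`` of
    the samples in *both* directions — leading only periphery-to-center is
    indistinguishable from passive elastic return of stretched muscles.
    """

    def frac(mov):
        if isinstance(mov, tuple):
            return _lead_fraction(*mov)
        return _lead_fraction(mov["position"], mov["desired_position"], mov["direction"])

    return frac(prev_movement_c2p) >= threshold and frac(prev_movement_p2c) >= threshold


def is_ahead(spec: TrajectorySpec, x: float, x_d: float, margin: float = 0.0) -> bool:
    """Subject leads when signed progress exceeds desired progress by ``margin``.

    A positive margin acts as a sensor-noise deadband so that jitter around
    the desired trajectory does not register as a lead.
    """
    return (x - x_d) * spec.direction > margin


def ctr_recalculate(state: CTRState, x_now: float, v_now: float, t_now: float) -> CTRState:
    """Replan through the subject's state and shave 1% off the allotted time.

    The reduced ``T_end`` applies to the current movement and persists for
    the next task.  Requires CTR enabled and the subject strictly ahead of
    the active desired trajectory.
    """
    if not state.enabled:
        raise CTRLogicError("ctr_recalculate called with CTR disabled")
    x_d, _ = state.trajectory(t_now)
    if not is_ahead(state.current_spec, x_now, x_d):
        raise CTRLogicError("ctr_recalculate called while subject not ahead")
    new_T = max(T_END_MIN, 0.99 * state.current_spec.T_end)
    new_spec = replace(state.current_spec, T_end=new_T)
    new_state = CTRState(
        enabled=True,
        current_spec=new_spec,
        ahead_fraction_c2p=state.ahead_fraction_c2p,
        ahead_fraction_p2c=state.ahead_fraction_p2c,
        recalc_count=state.recalc_count + 1,
        trajectory=state.trajectory,
    )
    new_state.trajectory.spec = new_spec
    new_state.trajectory.recalculate(x_now, v_now, t_now, new_T)
    return new_state


def allotted_time_update(state: CTRState, ctr_activated_this_task: bool) -> CTRState:
    """End-of-task update: grow ``T_end`` by 0.2 s if CTR never fired.

    The recalculation path has already compounded its 1% reductions, so an
    activated task leaves ``T_end`` unchanged here.
    """
    if ctr_activated_this_task:
        return state
    new_T = min(T_END_MAX, state.current_spec.T_end + 0.2)
    new_spec = replace(state.current_spec, T_end=new_T)
    return CTRState(
        enabled=state.enabled,
        current_spec=new_spec,
        ahead_fraction_c2p=state.ahead_fraction_c2p,
        ahead_fraction_p2c=state.ahead_fraction_p2c,
        recalc_count=state.recalc_count,
        trajectory=DesiredTrajectory(new_spec),
    )
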