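"""Simulated impaired subject and closed-loop therapy-program simulator.

The subject is a 1-DOF plant (inertia + viscous damping + gravity) driven by
two torques: the robot controller (assist-as-needed, subject-triggered, or
none for unpowered evaluation movements) and a synthetic human.  The human
applies direction-dependent, ability-scaled tracking effort toward an
internal reference moving at the subject's own preferred pace, plus a
passive elastic return toward the rest angle and Gaussian torque noise.
Impairment also manifests as intermittent effort (random telegraph gating),
which produces the arrest-rich speed profiles characteristic of impaired
reaching.  Ability improves by a fixed fraction per session, emulating
recovery across a multi-session therapy program.

Everything here is synthetic: the module generates study-like data for
exercising the controllers and the movement-quality metric pipeline; it is
not a physiological muscle model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from . import aan as _aan
from . import st as _st
from .aan import ControllerState, JointSpec, r_avg_percent
from .st import STMode, STState
from .trajectory import (
    CTRState,
    DesiredTrajectory,
    TrajectorySpec,
    allotted_time_update,
    ctr_recalculate,
    is_ahead,
    min_jerk,
)

__all__ = [
    "SubjectProfile",
    "SessionRecord",
    "MovementResult",
    "ProgramResult",
    "SimulationFault",
    "subject_torque",
    "simulate_movement",
    "simulate_program",
    "synth_speed_profile",
    "SpeedProfile",
    "SESSION_COLUMNS",
]

DEG = math.pi / 180.0

SESSION_COLUMNS = [
    "time",
    "position",
    "velocity",
    "desired_position",
    "desired_velocity",
    "commanded_torque",
    "subject_torque",
    "target_index",
    "event",
]


class SimulationFault(RuntimeError):
    """Integrator divergence (position far outside the joint's ROM)."""


@dataclass
class SubjectProfile:
    """Parameters of the synthetic impaired subject and the passive plant.

    ``ability_pos``/``ability_neg`` scale effort for positive/negative
    movement directions (agonist/antagonist asymmetry); ``max_torque`` caps
    the tracking effort before ability scaling.  ``elastic_k`` models the
    unintentional elastic return of stretched muscles toward ``rest_angle``.
    ``improvement_rate`` is the fractional ability gain per session.
    Plant-side constants (``inertia`` kg m^2, ``viscous_b`` Nms/deg,
    ``gravity_g0`` Nm for g0*cos(x)) live here as well so one object fully
    specifies a simulation.
    """

    ability_pos: float = 0.4
    ability_neg: float = 0.4
    max_torque: float = 4.0
    elastic_k: float = 0.005
    rest_angle: Optional[float] = None  # None -> center of ROM
    noise_sd: float = 0.05
    inertia: float = 0.05
    viscous_b: float = 0.01
    improvement_rate: float = 0.08
    gravity_g0: float = 1.0
    tracking_kp: float = 0.5  # Nm/deg of subject PD effort
    tracking_kv: float = 0.02  # Nms/deg
    gravity_comp: float = 0.9  # fraction of gravity the subject supports
    gate_off_rate: float = 1.5  # 1/s, scaled by (1 - ability)
    gate_on_rate: float = 2.0  # 1/s
    gate_off_gain: float = 0.15
    freeze_brake: float = 1.5  # Nms/deg co-contraction brake, scaled by (1-ability)^2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for a in (self.ability_pos, self.ability_neg):
            if not 0.0 <= a <= 1.0:
                raise ValueError("abilities must lie in [0, 1]")
        if self.inertia <= 0:
            raise ValueError("inertia must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def ability(self, direction: float, session: int = 1) -> float:
        """Direction-dependent ability at a given 1-based session."""
        base = self.ability_pos if direction >= 0 else self.ability_neg
        return min(1.0, base * (1.0 + self.improvement_rate) ** (session - 1))

    def preferred_duration(self, ability: float) -> float:
        """Movement time the subject attempts on their own (s).

        A more able subject moves faster; this is deliberately independent
        of the allotted time so that leading/lagging the commanded
        trajectory emerges from the dynamics.
        """
        return float(np.clip(2.0 * (1.5 - ability), 0.8, 4.0))


def subject_torque(
    profile: SubjectProfile,
    x: float,
    v: float,
    x_d: float,
    v_d: float,
    direction: float,
    ability: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    gate: float = 1.0,
    brake: float = 0.0,
) -> float:
    """Human torque: ability-scaled saturated PD effort + elastic return + noise.

    ``gate`` scales voluntary effort during freeze episodes; ``brake`` is an
    involuntary co-contraction viscosity (Nms/deg) active while frozen.
    """
    if ability is None:
        ability = profile.ability_pos if direction >= 0 else profile.ability_neg
    rest = profile.rest_angle if profile.rest_angle is not None else 0.0
    effort = (
        profile.tracking_kp * (x_d - x)
        + profile.tracking_kv * (v_d - v)
        + profile.gravity_comp * profile.gravity_g0 * math.cos(x * DEG)
    )
    effort = max(-profile.max_torque, min(profile.max_torque, effort))
    f = ability * gate * effort + profile.elastic_k * (rest - x) - brake * v
    if rng is not None and profile.noise_sd > 0:
        # motor noise (tremor) shrinks as ability recovers
        f += profile.noise_sd * (1.5 - ability) * rng.standard_normal()
    return f


@dataclass
class SessionRecord:
    """Uniformly sampled multi-channel record of one session (or slice)."""

    data: pd.DataFrame
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SESSION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"SessionRecord missing columns: {missing}")


@dataclass
class MovementResult:
    """Outcome of one simulated point-to-point movement."""

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    desired_position: np.ndarray
    desired_velocity: np.ndarray
    commanded_torque: np.ndarray
    subject_torque: np.ndarray
    reached: bool
    duration: float
    direction: float
    r_avg_pct: float = float("nan")
    recalc_count: int = 0
    lead_fraction: float = 0.0
    ctr: Optional[CTRState] = None
    st: Optional[STState] = None


def _gravity(profile: SubjectProfile, x: float) -> float:
    return profile.gravity_g0 * math.cos(x * DEG)


def _check_divergence(x: float, joint: JointSpec) -> None:
    span = 3.0 * max(abs(joint.rom_min), abs(joint.rom_max), joint.rom_amplitude)
    if not math.isfinite(x) or abs(x) > span + joint.rom_amplitude:
        raise SimulationFault(f"position {x:.1f} deg diverged beyond 3x ROM")


def _update_gate(gate_on: bool, ability: float, profile: SubjectProfile, dt: float, rng) -> bool:
    """Random-telegraph effort intermittency; weaker subjects drop out more."""
    if rng is None:
        return True
    if gate_on:
        if rng.random() < profile.gate_off_rate * (1.0 - ability) * dt:
            return False
        return True
    if rng.random() < profile.gate_on_rate * dt:
        return True
    return False


def _resolve_rest(profile: SubjectProfile, joint: JointSpec) -> SubjectProfile:
    """Default rest angle (elastic-return equilibrium) is the ROM center."""
    if profile.rest_angle is None:
        return replace(profile, rest_angle=0.5 * (joint.rom_min + joint.rom_max))
    return profile


def _aan_movement(
    profile: SubjectProfile,
    controller: ControllerState,
    joint: JointSpec,
    ctr: CTRState,
    dt: float,
    x0: float,
    v0: float,
    ability: float,
    rng,
    min_recalc_interval: float = 0.1,
    tol_frac: float = 0.05,
    lead_margin: float = 0.2,
) -> MovementResult:
    profile = _resolve_rest(profile, joint)
    spec = ctr.current_spec
    traj = ctr.trajectory
    nominal = DesiredTrajectory(spec)  # lead detection always vs the nominal profile
    # the subject aims for the target at their own preferred pace, independent
    # of the allotted time: leading or lagging the robot emerges dynamically
    spec_sub = TrajectorySpec(
        spec.x_start, spec.x_target, profile.preferred_duration(ability), spec.t_origin
    )
    direction = spec.direction
    tol = tol_frac * abs(spec.amplitude)
    t = spec.t_origin
    t_timeout = spec.t_origin + max(3.0 * spec.T_end, spec.T_end + 5.0)
    x, v = x0, v0
    theta = controller.rbf.theta
    centers = controller.rbf.centers
    inv2w2 = 1.0 / (2.0 * controller.rbf.width**2)
    nb = centers.size
    gamma = controller.gamma
    lam = controller.lam
    kd = controller.kd
    rom = joint.rom_amplitude
    inv_ieff = 1.0 / (profile.inertia * DEG)  # (deg/s^2) per Nm
    decay = math.exp(-dt / controller.decay_tau)
    gate_on = True
    last_recalc = -1e9
    activated = 0
    lead_n = 0
    n = 0
    rows_t, rows_x, rows_v, rows_xd, rows_vd, rows_fr, rows_fp = ([] for _ in range(7))
    r_abs_sum = 0.0
    reached = False
    while t < t_timeout:
        x_d, v_d = traj(t)
        xn_d, vn_d = nominal(t)
        sign = direction if vn_d == 0.0 else (1.0 if vn_d > 0 else -1.0)
        r = (v - v_d) + lam * (x - x_d)
        g = np.exp(-((x - centers) ** 2) * inv2w2)
        half = slice(0, nb) if sign >= 0 else slice(nb, 2 * nb)
        ff = float(g @ theta[half])
        f_r = ff - kd * r
        gate_on = _update_gate(gate_on, ability, profile, dt, rng)
        # during a freeze voluntary drive drops out; the robot's haptic
        # guidance suppresses the co-contraction braking seen in free
        # movement, so only the effort loss is modeled here
        x_s, v_s = min_jerk(spec_sub, t)
        f_p = subject_torque(
            profile, x, v, x_s, v_s, direction, ability=ability, rng=rng,
            gate=1.0 if gate_on else profile.gate_off_gain,
        )
        # feedback damping (K_D) and plant viscosity handled implicitly so the
        # integrator stays stable when the gain update drives K_D high
        f_expl = ff + kd * (v_d - lam * (x - x_d)) + f_p - _gravity(profile, x)
        c_visc = kd + profile.viscous_b
        v = (v + f_expl * inv_ieff * dt) / (1.0 + c_visc * inv_ieff * dt)
        x += v * dt
        t += dt
        # adaptation (forward Euler) with sub-threshold first-order decay
        r_pct = abs(r) / rom * 100.0
        theta[half] -= (g / gamma[half]) * (r * dt)
        if r_pct < joint.r_min:
            theta *= decay
        r_abs_sum += abs(r)
        n += 1
        if (x - xn_d) * direction > lead_margin:
            lead_n += 1
        if (
            ctr.enabled
            and t - last_recalc >= min_recalc_interval
            and t < traj.end_time
            and is_ahead(ctr.current_spec, x, traj(t)[0], lead_margin)
        ):
            ctr = ctr_recalculate(ctr, x, v, t)
            traj = ctr.trajectory
            last_recalc = t
            activated += 1
        rows_t.append(t)
        rows_x.append(x)
        rows_v.append(v)
        rows_xd.append(x_d)
        rows_vd.append(v_d)
        rows_fr.append(f_r)
        rows_fp.append(f_p)
        _check_divergence(x, joint)
        if abs(x - spec.x_target) <= tol and t >= spec.t_origin + 0.1 * spec.T_end:
            reached = True
            break
    controller.rbf.theta = theta
    controller.r_history.append(r_abs_sum / max(n, 1))
    return MovementResult(
        time=np.asarray(rows_t),
        position=np.asarray(rows_x),
        velocity=np.asarray(rows_v),
        desired_position=np.asarray(rows_xd),
        desired_velocity=np.asarray(rows_vd),
        commanded_torque=np.asarray(rows_fr),
        subject_torque=np.asarray(rows_fp),
        reached=reached,
        duration=t - spec.t_origin,
        direction=direction,
        r_avg_pct=r_avg_percent([r_abs_sum / max(n, 1)], rom),
        recalc_count=activated,
        lead_fraction=lead_n / max(n, 1),
        ctr=ctr,
    )


def _st_movement(
    profile: SubjectProfile,
    state: STState,
    joint: JointSpec,
    target: float,
    t0: float,
    dt: float,
    ability: float,
    rng,
    timeout: float = 6.0,
    ramp_time: float = 0.5,
) -> MovementResult:
    """Force-gated hold then robot-driven carry, under a stiff position servo."""
    ramp_time = ramp_time / (0.5 + ability)  # weaker subjects build force slower
    direction = float(np.sign(target - state.hold_target))
    kp_servo, kv_servo = 2000.0, 90.0  # 1/s^2, 1/s — near-critically damped
    x, v = state.hold_target, 0.0
    t = t0
    reached = False
    rows_t, rows_x, rows_v, rows_xd, rows_vd, rows_fr, rows_fp = ([] for _ in range(7))
    while t - t0 < timeout:
        if state.mode is STMode.HOLD:
            ramp = min(1.0, (t - t0) / ramp_time)
            f_p = ability * profile.max_torque * ramp * direction
            if rng is not None and profile.noise_sd > 0:
                f_p += profile.noise_sd * rng.standard_normal()
        else:
            f_p = 0.0  # passive during the carry
        state, cmd = _st.st_step(state, f_p, target, t)
        a = kp_servo * (cmd - x) - kv_servo * v
        v += a * dt
        x += v * dt
        t += dt
        rows_t.append(t)
        rows_x.append(x)
        rows_v.append(v)
        rows_xd.append(cmd)
        rows_vd.append(0.0)
        rows_fr.append(profile.inertia * DEG * a)
        rows_fp.append(f_p)
        _check_divergence(x, joint)
        if state.mode is STMode.HOLD and state.hold_target == target:
            reached = True
            break
    return MovementResult(
        time=np.asarray(rows_t),
        position=np.asarray(rows_x),
        velocity=np.asarray(rows_v),
        desired_position=np.asarray(rows_xd),
        desired_velocity=np.asarray(rows_vd),
        commanded_torque=np.asarray(rows_fr),
        subject_torque=np.asarray(rows_fp),
        reached=reached,
        duration=t - t0,
        direction=direction,
        st=state,
    )


def _free_movement(
    profile: SubjectProfile,
    joint: JointSpec,
    x_start: float,
    x_target: float,
    t0: float,
    dt: float,
    ability: float,
    rng,
    tol_frac: float = 0.05,
) -> MovementResult:
    """Unassisted evaluation movement: robot unpowered, subject at own pace."""
    profile = _resolve_rest(profile, joint)
    t_sub = profile.preferred_duration(ability)
    spec = TrajectorySpec(x_start, x_target, t_sub, t0)
    direction = spec.direction
    tol = tol_frac * abs(spec.amplitude)
    x, v = x_start, 0.0
    t = t0
    t_timeout = t0 + 3.0 * t_sub + 2.0
    gate_on = True
    inv_ieff = 1.0 / (profile.inertia * DEG)
    reached = False
    rows_t, rows_x, rows_v, rows_fp = [], [], [], []
    from .trajectory import min_jerk

    while t < t_timeout:
        gate_on = _update_gate(gate_on, ability, profile, dt, rng)
        x_d, v_d = min_jerk(spec, t)
        f_p = subject_torque(
            profile, x, v, x_d, v_d, direction, ability=ability, rng=rng,
            gate=1.0 if gate_on else profile.gate_off_gain,
            brake=0.0 if gate_on else profile.freeze_brake * (1.0 - ability) ** 2,
        )
        a = (f_p - profile.viscous_b * v - _gravity(profile, x)) * inv_ieff
        v += a * dt
        x += v * dt
        t += dt
        rows_t.append(t)
        rows_x.append(x)
        rows_v.append(v)
        rows_fp.append(f_p)
        _check_divergence(x, joint)
        if abs(x - x_target) <= tol and t >= t0 + 0.25 * t_sub:
            reached = True
            break
    n = len(rows_t)
    return MovementResult(
        time=np.asarray(rows_t),
        position=np.asarray(rows_x),
        velocity=np.asarray(rows_v),
        desired_position=np.full(n, x_target),
        desired_velocity=np.zeros(n),
        commanded_torque=np.zeros(n),
        subject_torque=np.asarray(rows_fp),
        reached=reached,
        duration=t - t0,
        direction=direction,
    )


def simulate_movement(
    profile: SubjectProfile,
    controller,
    spec: TrajectorySpec,
    joint: JointSpec,
    dt: float = 0.001,
    *,
    ctr: Optional[CTRState] = None,
    ability: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    x0: Optional[float] = None,
    v0: float = 0.0,
    tol_frac: float = 0.05,
) -> MovementResult:
    """Forward-integrate one movement with the chosen controller in the loop.

    ``controller`` is an AAN :class:`ControllerState` (mutated in place), an
    ST :class:`STState`, or ``None`` for an unpowered evaluation movement.
    """
    if dt <= 0 or dt > 0.002:
        raise ValueError("dt must lie in (0, 2 ms]")
    if ability is None:
        ability = profile.ability_pos if spec.direction >= 0 else profile.ability_neg
    if rng is None and profile.seed is not None:
        rng = np.random.default_rng(profile.seed)
    x0 = spec.x_start if x0 is None else x0
    if isinstance(controller, ControllerState):
        if ctr is None:
            ctr = CTRState(enabled=False, current_spec=spec)
        return _aan_movement(
            profile, controller, joint, ctr, dt, x0, v0, ability, rng, tol_frac=tol_frac
        )
    if isinstance(controller, STState):
        return _st_movement(profile, controller, joint, spec.x_target, spec.t_origin, dt, ability, rng)
    if controller is None:
        return _free_movement(profile, joint, x0, spec.x_target, spec.t_origin, dt, ability, rng)
    raise TypeError(f"unsupported controller: {type(controller)!r}")


def _movement_frame(mov: MovementResult, target_index: int, stride: int) -> pd.DataFrame:
    sl = slice(stride - 1, None, stride)
    n = mov.time[sl].size
    ev = np.array([""] * n, dtype=object)
    if n:
        ev[0] = "target_switch"
        ev[-1] = "target_reach" if mov.reached else "timeout"
    return pd.DataFrame(
        {
            "time": mov.time[sl],
            "position": mov.position[sl],
            "velocity": mov.velocity[sl],
            "desired_position": mov.desired_position[sl],
            "desired_velocity": mov.desired_velocity[sl],
            "commanded_torque": mov.commanded_torque[sl],
            "subject_torque": mov.subject_torque[sl],
            "target_index": target_index,
            "event": ev,
        }
    )


@dataclass
class ProgramResult:
    """Multi-session simulation output: per-session summary + records."""

    summary: pd.DataFrame
    eval_records: List[SessionRecord]
    records: Optional[List[SessionRecord]] = None


def simulate_program(
    profile: SubjectProfile,
    joint: JointSpec,
    controller: str = "aan",
    n_sessions: int = 10,
    session_minutes: float = 90.0,
    dt: float = 0.001,
    seed: Optional[int] = None,
    n_eval: int = 6,
    keep_records: bool = False,
    st_base_fth: float = 1.0,
    st_increment: float = 0.05,
    t_st: float = 2.0,
    sample_rate: Optional[float] = None,
    gate_threshold: float = 0.10,
    n_basis: int = 10,
    gamma: float = 50.0,
    lam: float = 1.0,
    decay_tau: float = 2.0,
    inter_trial: float = 0.5,
) -> ProgramResult:
    """Simulate a full therapy program and summarize it session by session.

    Each session holds a short unassisted evaluation block (``n_eval``
    movements, recorded for the movement-quality pipeline) followed by
    point-to-point training repetitions filling the ``session_minutes`` task
    budget.  Ability grows by ``improvement_rate`` per session.  The summary
    contains, per session, the mean feedback gain, final allotted time,
    repetition count and force threshold, plus their changes relative to
    session 1 (the controller-validation deltas).
    """
    if controller not in ("aan", "st"):
        raise ValueError("controller must be 'aan' or 'st'")
    rng = np.random.default_rng(seed if seed is not None else profile.seed)
    if sample_rate is None:
        sample_rate = 200.0 if controller == "aan" else 100.0
    stride = max(1, round(1.0 / (sample_rate * dt)))
    sample_rate = 1.0 / (stride * dt)  # effective rate after decimation
    center = 0.5 * (joint.rom_min + joint.rom_max)
    p_lo = joint.rom_min + 0.1 * joint.rom_amplitude
    p_hi = joint.rom_max - 0.1 * joint.rom_amplitude
    budget = session_minutes * 60.0

    ctrl = ControllerState.for_joint(joint, n_basis=n_basis, lam=lam, gamma=gamma, decay_tau=decay_tau)
    t_end = joint.t_init
    gate_on = False
    rows = []
    eval_records: List[SessionRecord] = []
    records: List[SessionRecord] = [] if keep_records else None

    for k in range(1, n_sessions + 1):
        ab_pos = profile.ability(+1, k)
        ab_neg = profile.ability(-1, k)
        # ---- evaluation block (robot unpowered, always recorded) ----
        eval_frames = []
        t_clock = 0.0
        for j in range(n_eval):
            periph = p_hi if j % 2 == 0 else p_lo
            for x_start, x_tgt in ((center, periph), (periph, center)):
                d = np.sign(x_tgt - x_start)
                mov = _free_movement(
                    profile, joint, x_start, x_tgt, t_clock, dt,
                    ab_pos if d >= 0 else ab_neg, rng,
                )
                eval_frames.append(_movement_frame(mov, j, stride))
                t_clock += mov.duration + inter_trial * (2.0 - (ab_pos if d >= 0 else ab_neg))
        if eval_frames:
            eval_records.append(
                SessionRecord(
                    data=pd.concat(eval_frames, ignore_index=True),
                    sample_rate=sample_rate,
                    meta={"session": k, "joint": joint.name, "controller": controller, "block": "eval"},
                )
            )
        # ---- training block ----
        t_clock = 0.0
        reps = reps_done = 0
        kd_vals: list = []
        r_avgs: list = []
        recalcs = 0
        f_th = _st.threshold_schedule(k, st_base_fth, st_increment)
        st_state = STState(mode=STMode.HOLD, f_th=f_th, t_st=t_st, hold_target=center)
        train_frames = [] if keep_records else None
        while t_clock < budget:
            periph = p_hi if reps % 2 == 0 else p_lo
            if controller == "aan":
                pair_lead = []
                for x_start, x_tgt in ((center, periph), (periph, center)):
                    d = np.sign(x_tgt - x_start)
                    spec = TrajectorySpec(x_start, x_tgt, t_end, t_clock)
                    ctr = CTRState(enabled=gate_on, current_spec=spec)
                    kd_vals.append(ctrl.kd)
                    mov = _aan_movement(
                        profile, ctrl, joint, ctr, dt, x_start, 0.0,
                        ab_pos if d >= 0 else ab_neg, rng,
                    )
                    activated = mov.recalc_count > 0
                    recalcs += mov.recalc_count
                    ctr = allotted_time_update(mov.ctr, activated)
                    t_end = ctr.current_spec.T_end
                    ctrl.kd = _aan.gain_update(joint, ctrl.kd, mov.r_avg_pct, ctrl.kd_ceiling)
                    r_avgs.append(mov.r_avg_pct)
                    pair_lead.append(mov.lead_fraction)
                    # rest between repetitions shortens as the subject recovers
                    t_clock += mov.duration + inter_trial * (2.0 - (ab_pos if d >= 0 else ab_neg))
                    reps += 1
                    reps_done += int(mov.reached)
                    if keep_records:
                        train_frames.append(_movement_frame(mov, reps, stride))
                gate_on = pair_lead[0] >= gate_threshold and pair_lead[1] >= gate_threshold
            else:
                for x_start, x_tgt in ((center, periph), (periph, center)):
                    d = np.sign(x_tgt - x_start)
                    st_state = replace(
                        st_state, mode=STMode.HOLD, hold_target=x_start, move_spec=None
                    )
                    mov = _st_movement(
                        profile, st_state, joint, x_tgt, t_clock, dt,
                        ab_pos if d >= 0 else ab_neg, rng,
                    )
                    st_state = mov.st
                    t_clock += mov.duration + inter_trial * (2.0 - (ab_pos if d >= 0 else ab_neg))
                    reps += 1
                    reps_done += int(mov.reached)
                    if keep_records:
                        train_frames.append(_movement_frame(mov, reps, stride))
        if keep_records:
            records.append(
                SessionRecord(
                    data=pd.concat(train_frames, ignore_index=True),
                    sample_rate=sample_rate,
                    meta={"session": k, "joint": joint.name, "controller": controller, "block": "train"},
                )
            )
        rows.append(
            {
                "session": k,
                "controller": controller,
                "mean_kd": float(np.mean(kd_vals)) if kd_vals else float("nan"),
                "t_end": t_end,
                "reps": reps,
                "reps_completed": reps_done,
                "recalcs": recalcs,
                "f_th": f_th if controller == "st" else float("nan"),
                "mean_r_avg_pct": float(np.mean(r_avgs)) if r_avgs else float("nan"),
                "ability_pos": ab_pos,
                "ability_neg": ab_neg,
            }
        )
    summary = pd.DataFrame(rows)
    first = summary.iloc[0]
    summary["d_kd"] = summary["mean_kd"] - first["mean_kd"]
    summary["d_t"] = summary["t_end"] - first["t_end"]
    summary["d_rep"] = summary["reps"] - first["reps"]
    if controller == "st":
        summary["fth_pct_change"] = (summary["f_th"] / first["f_th"] - 1.0) * 100.0
    return ProgramResult(summary=summary, eval_records=eval_records, records=records)


# ---------------------------------------------------------------------------
# parametric speed-profile generator (fixtures for the metric pipeline)
# ---------------------------------------------------------------------------


@dataclass
class SpeedProfile:
    """Synthetic speed series built from minimum-jerk submovement pulses."""

    time: np.ndarray
    speed: np.ndarray
    rate: float
    submovements: list

    def true_crossings(self, threshold_frac: float = 0.05, oversample: int = 20):
        """Ground-truth first/last threshold-crossing times on a dense grid."""
        t = np.arange(0.0, self.time[-1] + 1.0 / (self.rate * oversample), 1.0 / (self.rate * oversample))
        s = _pulse_sum(t, self.submovements)
        thr = threshold_frac * s.max()
        above = s >= thr
        idx = np.flatnonzero(above)
        if idx.size == 0:
            raise ValueError("profile never crosses threshold")
        return float(t[idx[0]]), float(t[idx[-1]])


def _pulse_sum(t: np.ndarray, submovements) -> np.ndarray:
    s = np.zeros_like(t, dtype=float)
    for amplitude, onset, duration in submovements:
        if duration <= 0:
            raise ValueError("submovement durations must be > 0")
        tau = np.clip((t - onset) / duration, 0.0, 1.0)
        s += amplitude * 30.0 * tau**2 * (1.0 - tau) ** 2 / duration
    return s


def synth_speed_profile(
    submovements, rate: float, duration: Optional[float] = None, noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SpeedProfile:
    """Sum of minimum-jerk speed pulses with known ground truth.

    Each submovement is ``(amplitude, onset, duration)``; its peak speed is
    the analytic minimum-jerk value ``1.875 * amplitude / duration``.  An
    empty list yields a zero series.
    """
    if duration is None:
        duration = max((on + d for _, on, d in submovements), default=1.0) + 0.2
    t = np.arange(0.0, duration, 1.0 / rate)
    s = _pulse_sum(t, list(submovements))
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        s = np.clip(s + noise_sd * rng.standard_normal(s.size), 0.0, None)
    return SpeedProfile(time=t, speed=s, rate=rate, submovements=list(submovements))
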