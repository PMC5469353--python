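"""Assist-as-needed (AAN) adaptive controller for a single joint.

The controller supplies a torque ``F_r = Y(x, sign(v_d)) theta_hat - K_D r``:
a radial-basis-function feedforward estimate of gravity minus the subject's
contribution, plus sliding-variable feedback.  The RBF amplitudes adapt
online (Slotine–Li style, inertial/Coriolis terms neglected) and the
feedback gain K_D is re-tuned once per completed task from the average
tracking error, so that assistance grows when the subject struggles and
fades as performance improves.

Units: angles deg, time s, torque Nm, K_D Nms/deg, Lambda 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JointSpec",
    "RBFNetwork",
    "ControllerState",
    "sliding_variable",
    "rbf_features",
    "adaptation_step",
    "assistance_force",
    "gain_update",
]

JOINT_NAMES = ("elbow", "wrist_PS", "wrist_FE", "wrist_RUD")


@dataclass(frozen=True)
class JointSpec:
    """One trained degree of freedom and its controller parameters.

    ``r_min`` and ``r_star`` are expressed as percent of the ROM amplitude;
    ``r_star`` is the error level at which the task-by-task gain change is
    zero, ``r_min`` the level at which it is ``-dkd_max``.  ``dkd_max``
    scales the trial-to-trial gain change (it is *not* a gain ceiling: for
    the wrist joints the initial gain exceeds it).
    """

    name: str
    rom_min: float
    rom_max: float
    r_min: float
    r_star: float
    kd_init: float
    dkd_max: float
    t_init: float = 2.0

    def __post_init__(self) -> None:
        if self.rom_min >= self.rom_max:
            raise ValueError("rom_min must be < rom_max")
        if not (self.r_star > self.r_min >= 0):
            raise ValueError("require r_star > r_min >= 0")
        if self.kd_init <= 0 or self.dkd_max <= 0 or self.t_init <= 0:
            raise ValueError("kd_init, dkd_max, t_init must be > 0")

    @property
    def rom_amplitude(self) -> float:
        return self.rom_max - self.rom_min


class RBFNetwork:
    """Direction-split Gaussian RBF expansion over the joint's ROM.

    Two equal-sized basis sets — one active for positive desired velocity,
    one for negative — let the controller learn different assistance for
    agonist and antagonist movement directions.  Centers are evenly spaced
    over [rom_min, rom_max]; the width equals the center spacing.
    """

    def __init__(self, centers: np.ndarray, width: float):
        if width <= 0:
            raise ValueError("width must be > 0")
        self.centers = np.asarray(centers, dtype=float)
        self.width = float(width)
        self.theta = np.zeros(2 * self.centers.size)

    @classmethod
    def for_joint(cls, spec: JointSpec, n_basis: int = 10) -> "RBFNetwork":
        centers = np.linspace(spec.rom_min, spec.rom_max, n_basis)
        width = centers[1] - centers[0] if n_basis > 1 else spec.rom_amplitude
        return cls(centers, width)

    @property
    def n_basis(self) -> int:
        return self.centers.size

    def features(self, x: float, v_d_sign: float) -> np.ndarray:
        """Activations for the directional set selected by sign(v_d)."""
        g = np.exp(-((x - self.centers) ** 2) / (2.0 * self.width**2))
        out = np.zeros(2 * self.n_basis)
        if v_d_sign >= 0:
            out[: self.n_basis] = g
        else:
            out[self.n_basis :] = g
        return out

    def feedforward(self, x: float, v_d_sign: float) -> float:
        """Y(x, sign) . theta_hat — the learned gravity-minus-subject torque."""
        return float(self.features(x, v_d_sign) @ self.theta)


@dataclass
class ControllerState:
    """Mutable AAN runtime state for one joint."""

    rbf: RBFNetwork
    kd: float
    lam: float = 1.0
    gamma: np.ndarray | float = 50.0
    decay_tau: float = 2.0
    kd_ceiling: float | None = None
    r_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            g = np.full(self.rbf.theta.size, float(g))
        if g.ndim != 1 or g.size != self.rbf.theta.size or np.any(g <= 0):
            raise ValueError("gamma must be a positive scalar or positive diagonal")
        self.gamma = g
        if self.kd < 0 or self.lam <= 0:
            raise ValueError("require kd >= 0 and lam > 0")

    @classmethod
    def for_joint(
        cls,
        spec: JointSpec,
        n_basis: int = 10,
        lam: float = 1.0,
        gamma: float = 50.0,
        decay_tau: float = 2.0,
    ) -> "ControllerState":
        return cls(
            rbf=RBFNetwork.for_joint(spec, n_basis),
            kd=spec.kd_init,
            lam=lam,
            gamma=gamma,
            decay_tau=decay_tau,
            kd_ceiling=10.0 * spec.kd_init,
        )


def sliding_variable(x: float, v: float, x_d: float, v_d: float, lam: float) -> float:
    """Composite tracking error r = (v - v_d) + lam (x - x_d)."""
    return (v - v_d) + lam * (x - x_d)


def rbf_features(net: RBFNetwork, x: float, v_d_sign: float) -> np.ndarray:
    """Feature row of the direction-dependent regressor Y(x, sign(v_d))."""
    return net.features(x, v_d_sign)


def adaptation_step(
    state: ControllerState,
    features: np.ndarray,
    r: float,
    dt: float,
    below_r_min: bool,
) -> ControllerState:
    """One Euler step of the amplitude adaptation law.

    theta_hat <- theta_hat - Gamma^-1 Y^T r dt.  When the error has dropped
    below r_min the amplitudes additionally decay first-order with time
    constant ``decay_tau``: with CTR active a lead-type error cannot occur,
    so without decay the feedforward estimate would only ratchet upward.
    Mutates and returns ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state.rbf.theta = state.rbf.theta - (features / state.gamma) * (r * dt)
    if below_r_min:
        state.rbf.theta = state.rbf.theta * math.exp(-dt / state.decay_tau)
    return state


def assistance_force(state: ControllerState, features: np.ndarray, r: float) -> float:
    """Assistance torque F_r = Y theta_hat - K_D r (Nm)."""
    return float(features @ state.rbf.theta) - state.kd * r


def gain_update(spec: JointSpec, kd: float, r_avg: float, kd_ceiling: float | None = None) -> float:
    """Task-by-task feedback-gain update.

    ``dK_D = dkd_max (r_avg - r_star) / (r_star - r_min)`` with ``r_avg``
    the mean |r| over the previous task expressed as percent of ROM
    amplitude; anchors: zero change at ``r_star``, ``-dkd_max`` at
    ``r_min``.  The result is clamped to [0, ceiling] (default 10x kd_init).
    """
    if r_avg < 0:
        raise ValueError("r_avg must be >= 0")
    ceiling = 10.0 * spec.kd_init if kd_ceiling is None else kd_ceiling
    dkd = spec.dkd_max * (r_avg - spec.r_star) / (spec.r_star - spec.r_min)
    return float(np.clip(kd + dkd, 0.0, ceiling))


def r_avg_percent(r_samples, rom_amplitude: float) -> float:
    """Mean |r| over a task as percent of ROM amplitude."""
    r = np.asarray(r_samples, dtype=float)
    if r.size == 0:
        raise ValueError("empty sliding-variable history")
    return float(np.mean(np.abs(r)) / rom_amplitude * 100.0)
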