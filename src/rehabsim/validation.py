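"""Self-verification scenarios for the simulator and analysis pipeline.

Each function sets up a fully specified synthetic experiment, runs the
package end-to-end, and returns the measured quantity.  They are used by
the test suite and by the acceptance script; the scenario definitions
(problem sizes, subject profiles, adaptation rates) are part of the
package and documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import freqz, savgol_coeffs

from .aan import ControllerState
from .kinematics import (
    MovementSegment,
    mapr,
    normalized_speed,
    segment_movement,
    sg_window,
    spectral_arc_length,
)
from .session_io import load_joints
from .subject import DEG, SubjectProfile, simulate_movement, simulate_program, synth_speed_profile
from .trial import mixed_anova, session_slope

__all__ = [
    "controller_trend",
    "gravity_learning_error",
    "segmentation_recovery",
    "filter_equivalence_gap",
    "sal_oracle_gap",
    "mapr_oracle_gap",
    "normalized_speed_min_jerk",
    "anova_type1_hits",
    "slope_ci_coverage",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def controller_trend(
    seed: int,
    joint_name: str = "wrist_PS",
    n_subjects: int = 3,
    n_sessions: int = 10,
    session_minutes: float = 2.0,
    dt: float = 0.002,
) -> dict:
    """Gain/repetition trends of a simulated improving therapy group.

    Mirrors the study's estimator: session deltas (relative to session 1)
    are averaged over a small simulated group, then regressed on session
    index with a t-based 95% CI.
    """
    joint = load_joints()[joint_name]
    kds, reps, tends = [], [], []
    for s in _child_seeds(seed, n_subjects):
        res = simulate_program(
            SubjectProfile(seed=s), joint, "aan",
            n_sessions=n_sessions, session_minutes=session_minutes, dt=dt, seed=s,
            n_eval=0,
        )
        kds.append(res.summary["d_kd"].to_numpy())
        reps.append(res.summary["d_rep"].to_numpy())
        tends.append(res.summary["d_t"].to_numpy())
    kd = session_slope(np.mean(kds, axis=0))
    rep = session_slope(np.mean(reps, axis=0))
    tend = session_slope(np.mean(tends, axis=0))
    return {
        "kd_slope": kd.slope,
        "kd_ci": (kd.ci_low, kd.ci_high),
        "kd_decreasing": kd.slope < 0 and kd.ci_high < 0,
        "rep_slope": rep.slope,
        "rep_ci": (rep.ci_low, rep.ci_high),
        "rep_increasing": rep.slope > 0 and rep.ci_low > 0,
        "t_end_slope": tend.slope,
    }


def gravity_learning_error(
    n_reaches: int = 52,
    T_end: float = 12.0,
    dt: float = 0.002,
    gamma: float = 5.0,
) -> float:
    """Worst-case error of the learned feedforward vs the plant's gravity.

    A zero-force subject (no voluntary torque, no noise, no elastic return)
    is carried through quasi-static reaches spanning the elbow ROM in both
    directions; slow movements isolate the configuration-dependent gravity
    torque that the position-only RBF regressor can represent.  Returns
    max |Y theta_hat - G| over the visited ROM and both directional basis
    sets, as a fraction of max |G|.  Deterministic.
    """
    joint = load_joints()["elbow"]
    prof = SubjectProfile(ability_pos=0.0, ability_neg=0.0, noise_sd=0.0, elastic_k=0.0)
    ctrl = ControllerState.for_joint(joint, gamma=gamma)
    center = 0.5 * (joint.rom_min + joint.rom_max)
    lo = joint.rom_min + 0.1 * joint.rom_amplitude
    hi = joint.rom_max - 0.1 * joint.rom_amplitude
    cycle = [(center, hi), (hi, center), (center, lo), (lo, center)]
    from .trajectory import TrajectorySpec

    t_clock = 0.0
    done = 0
    while done < n_reaches:
        a, b = cycle[done % 4]
        mov = simulate_movement(
            prof, ctrl, TrajectorySpec(a, b, T_end, t_clock), joint,
            dt=dt, ability=0.0, tol_frac=0.01,
        )
        t_clock += mov.duration + 0.2
        done += 1
    xs = np.linspace(lo + 1.0, hi - 1.0, 50)
    g_true = prof.gravity_g0 * np.cos(xs * DEG)
    worst = 0.0
    for sgn in (+1.0, -1.0):
        learned = np.array([ctrl.rbf.feedforward(x, sgn) for x in xs])
        worst = max(worst, float(np.max(np.abs(learned - g_true))))
    return worst / float(np.max(np.abs(g_true)))


def segmentation_recovery(
    seed: int, n_cases: int = 200, rate: float = 100.0, noise_frac: float = 0.01
) -> float:
    """Fraction of randomized noisy movements whose 5%-crossings are
    recovered within two samples of the generator's ground truth."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_cases):
        A = rng.uniform(5, 30)
        d = rng.uniform(0.5, 2.0)
        onset = rng.uniform(0.2, 0.5)
        peak = 1.875 * A / d
        prof = synth_speed_profile(
            [(A, onset, d)], rate, duration=onset + d + 0.5,
            noise_sd=noise_frac * peak, rng=rng,
        )
        t_in, t_fin = prof.true_crossings(0.05)
        try:
            seg = segment_movement(
                prof.time, prof.speed, t0=0.0, t_tar=prof.time[-1],
                direction=+1, rate=rate, smooth=True,
            )
        except ValueError:
            continue
        if abs(seg.t_in - t_in) <= 2 / rate and abs(seg.t_fin - t_fin) <= 2 / rate:
            ok += 1
    return ok / n_cases


def filter_equivalence_gap(omega_max: float = 10.0) -> float:
    """Max magnitude-response gap of the two rate-matched smoothing filters
    on the physical-frequency axis up to ``omega_max`` Hz."""
    grids = []
    for rate in (100.0, 200.0):
        c = savgol_coeffs(sg_window(rate), 3)
        f, h = freqz(c, worN=4096, fs=rate)
        grids.append((f, np.abs(h)))
    f_common = np.linspace(0, omega_max, 400)
    h1 = np.interp(f_common, *grids[0])
    h2 = np.interp(f_common, *grids[1])
    return float(np.max(np.abs(h1 - h2)))


def _min_jerk_pulse(rate: float = 100.0):
    prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate, duration=1.0)
    return MovementSegment(0.0, 1.0, prof.speed, rate)


def sal_oracle_gap(rate: float = 100.0) -> tuple[float, float]:
    """(implementation SAL, |gap| to a dense-grid DTFT oracle) for a 1-s pulse."""
    seg = _min_jerk_pulse(rate)
    impl = spectral_arc_length(seg)
    t = np.arange(seg.speed.size) / rate
    f = np.linspace(0, 10.0, 4001)
    V = np.abs(np.exp(-2j * np.pi * np.outer(f, t)) @ seg.speed)
    Vh = V / V[0]
    u = f / 10.0
    dV = np.gradient(Vh, u)
    oracle = -float(np.trapezoid(np.sqrt(1.0 + dV**2), u))
    return impl, abs(impl - oracle)


def mapr_oracle_gap(rate: float = 100.0) -> tuple[float, float]:
    """(implementation MAPR, |gap| to brute-force sample counting) for a
    min-jerk pulse cropped at its own 5% crossings."""
    prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate, duration=1.0)
    thr = 0.05 * prof.speed.max()
    idx = np.flatnonzero(prof.speed >= thr)
    seg = MovementSegment(idx[0] / rate, idx[-1] / rate, prof.speed[idx[0] : idx[-1] + 1], rate)
    impl = mapr(seg)
    count = 0
    for s in seg.speed:  # independent per-sample loop
        if s >= 0.05 * seg.speed.max():
            count += 1
    oracle = 100.0 * count / seg.speed.size
    return impl, abs(impl - oracle)


def normalized_speed_min_jerk(rate: float = 1000.0) -> float:
    """Normalized mean speed of an uncropped minimum-jerk pulse (analytic 8/15)."""
    prof = synth_speed_profile([(10.0, 0.0, 1.0)], rate, duration=1.0)
    return normalized_speed(MovementSegment(0.0, 1.0, prof.speed, rate))


def _null_longitudinal(rng, n_per_group: int = 7, n_sessions: int = 10) -> pd.DataFrame:
    rows = []
    for g in ("AAN", "ST"):
        for s in range(n_per_group):
            base = rng.normal(0, 1)
            for k in range(1, n_sessions + 1):
                rows.append(
                    {"subject": f"{g}{s:02d}", "group": g, "session": k,
                     "value": base + rng.normal(0, 1)}
                )
    return pd.DataFrame(rows)


def anova_type1_hits(seed: int, n_seeds: int = 50, alpha: float = 0.05) -> int:
    """Count of null-data replicates where the group effect is (falsely)
    significant; should be binomially consistent with ``alpha``."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        res = mixed_anova(_null_longitudinal(np.random.default_rng(s)))
        eff = res["effects"].set_index("effect")["p"]
        hits += int(eff["group"] < alpha)
    return hits


def type1_rate_consistent(hits: int, n: int, alpha: float = 0.05) -> bool:
    """Clopper-Pearson 95% interval of hits/n covers alpha."""
    lo, hi = stats.binomtest(hits, n).proportion_ci(0.95)
    return lo <= alpha <= hi


def slope_ci_coverage(seed: int, n_reps: int = 100) -> int:
    """How many of ``n_reps`` noisy-line replicates have the true slope in
    the 95% CI of :func:`~rehabsim.trial.session_slope`."""
    cov = 0
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        y = 0.5 * np.arange(1, 11) + rng.normal(0, 0.1, 10)
        r = session_slope(y)
        cov += int(r.ci_low <= 0.5 <= r.ci_high)
    return cov
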