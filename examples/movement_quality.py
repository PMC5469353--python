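"""Score movement smoothness on simulated evaluation records.

Unpowered evaluation movements are simulated at the start of each session
of an improving subject; each movement is segmented at 5% of its peak
speed and scored with MAPR (percent of movement time without arrests),
spectral arc length (SAL, closer to zero = smoother) and normalized mean
speed. All three should improve across sessions as arrests disappear.
"""

from rehabsim import SubjectProfile, session_slope, simulate_program
from rehabsim.kinematics import metrics_table
from rehabsim.session_io import load_joints

joint = load_joints()["wrist_PS"]
result = simulate_program(
    SubjectProfile(seed=5), joint, "aan",
    n_sessions=10, session_minutes=0.5, dt=0.002, seed=5, n_eval=8,
)
table = metrics_table(result.eval_records)
per_session = table.groupby("session")[["mapr", "sal", "norm_speed"]].mean()
print(per_session.round(3).to_string())

print()
for metric in ("mapr", "sal", "norm_speed"):
    r = session_slope(per_session[metric].to_numpy())
    print(f"{metric:>10} slope {r.slope:+.4f}/session "
          f"(95% CI {r.ci_low:+.4f} to {r.ci_high:+.4f})")
print("\nRising MAPR and normalized speed and a SAL moving toward zero all")
print("indicate fewer arrests and smoother speed profiles as ability recovers.")
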