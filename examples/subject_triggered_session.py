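"""One subject-triggered (ST) movement and the session force-threshold plan.

In ST mode the robot holds a virtual wall until the subject pushes past the
force threshold toward the cued target, then carries the passive limb along
a minimum-jerk path. The threshold rises session by session to keep the
subject challenged; its percent change relative to session 1 is the
intensity progression measure.
"""

from rehabsim import STMode, STState, SubjectProfile, simulate_movement, threshold_schedule
from rehabsim.session_io import load_joints
from rehabsim.trajectory import TrajectorySpec

joint = load_joints()["elbow"]
profile = SubjectProfile(noise_sd=0.0)
st = STState(mode=STMode.HOLD, f_th=1.0, t_st=1.5, hold_target=45.0)

mov = simulate_movement(profile, st, TrajectorySpec(45, 81, 2.0, 0.0), joint,
                        dt=0.002, ability=0.9)
print(f"movement reached={mov.reached} in {mov.duration:.2f} s "
      f"(threshold crossing + 1.5 s carry)")
print(f"final hold position: {mov.st.hold_target:.1f} deg")

print("\nsession force-threshold schedule (+5%/session from 1 Nm):")
for k in (1, 4, 7, 10):
    f = threshold_schedule(k, 1.0, 0.05)
    print(f"  session {k:2d}: F_th = {f:.3f} Nm ({(f - 1.0) * 100:+.1f}% vs session 1)")
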