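# Methods

`rehabsim` is a desk-scale simulator and analysis toolkit for upper-limb
robot-assisted rehabilitation of a single joint. It implements two therapy
controllers — an assist-as-needed (AAN) adaptive controller and a
subject-triggered (ST) two-state controller — closed around a synthetic
impaired-subject plant, together with the movement-quality metric pipeline
(Savitzky–Golay filtering, 5%-of-peak segmentation, MAPR, spectral arc
length, normalized speed) and the trial-design statistics used in
parallel-group robotic-therapy studies (covariate minimization, power and
sample size, longitudinal slope regression, mixed-design ANOVA with an
explicit missing-data policy). This note records the models, the defaults,
and the reasoning behind design choices the underlying specifications leave
open.

## Controllers

### Assist-as-needed (AAN)

The plant is treated in joint space with generalized coordinate x (deg).
The controller neglects inertial and Coriolis terms and applies

    F_r = Y(x, sign(v_d)) θ̂ − K_D r,        r = (v − v_d) + Λ (x − x_d),

where `Y θ̂` is a Gaussian radial-basis-function (RBF) estimate of the
gravity torque minus the subject's contribution, and `K_D r` is
sliding-variable feedback. The RBF set is duplicated per movement
direction (selected by the sign of the desired velocity, which avoids
chattering near v≈0) so that agonist and antagonist deficits can be
learned separately. Amplitudes adapt by forward-Euler integration of

    θ̂ ← θ̂ − Γ⁻¹ Yᵀ r dt,

with an additional first-order decay (time constant `decay_tau`) applied
only while |r| is below the joint's `r_min` threshold; without it the
estimates only ratchet upward once trajectory recalculation removes
lead-type errors.

Free parameters not fixed by the controller definition: 10 bases per
direction, centers evenly spaced over the joint ROM, width equal to the
center spacing; Λ = 1 s⁻¹; Γ = γI with γ = 50 by default; decay_tau = 2 s.
All are keyword-configurable. The per-joint parameters (r_min, r*, K_D
initial value, the ΔK_D,max scaling of the task-by-task gain update, and
the initial allotted time of 2 s) ship as the packaged `joints.yaml`
fixture. The "K_D,max" column is interpreted as the gain-update scaling
factor, not a ceiling — for the wrist joints the initial gain exceeds it,
so a ceiling reading is inconsistent; a separate configurable ceiling
(default 10× the initial gain) clamps K_D, and zero is the floor.

The task-by-task gain update is ΔK_D = ΔK_D,max (r_avg − r*)/(r* − r_min)
with r_avg the mean |r| over the previous task expressed as percent of the
ROM amplitude (the averaging norm is a package choice; mean absolute value
is the simplest consistent with r* and r_min being quoted as percentages
of ROM).

### Trajectory generation and conditional recalculation (CTR)

Nominal desired trajectories are minimum-jerk quintics — the standard
model of physiological point-to-point movement, and the profile the ST
controller explicitly uses. When CTR is enabled and the subject leads the
desired trajectory, the remainder is replanned as the uniquely determined
quartic through the subject's current position and velocity with zero end
velocity and acceleration at the target (five boundary conditions
determine degree four exactly; a quintic would be underdetermined). Each
recalculation shortens the allotted time T_end by 1%, persisting to the
next task; a task without any recalculation lengthens T_end by 0.2 s.
T_end is clamped to [0.5 s, 10 s] to avoid degeneracy. CTR is enabled for
a task pair only if the subject led the nominal trajectory for ≥10% of
samples in *both* the center-to-periphery and periphery-to-center
directions of the previous pair — passive elastic recoil of stretched
muscles can only produce periphery-to-center leads, so the two-sided gate
distinguishes intent from recoil. "Ahead" means signed progress along the
movement direction exceeds the desired progress by a 0.2 deg deadband
(an encoder/noise floor; without it sample-level jitter registers as
leads and T_end collapses geometrically). Successive recalculations are
spaced at least 0.1 s apart for the same reason. Whether the 1% reduction
rescales total duration or remaining time is not specified by the rule as
stated; total movement duration is reduced here.

### Subject-triggered (ST)

A two-state machine: in HOLD the robot position-controls a virtual wall at
the start position (realized as a stiff, near-critically damped servo —
the wall impedance is not part of the controller definition); when the
subject's torque along the cued direction exceeds F_th the controller
switches to MOVE and carries the passive limb along a minimum-jerk
trajectory of duration t_ST (default 2 s, mirroring the initial allotted
time; shared code path with the AAN trajectory generator), then holds at
the new position. Pushing away from the target never breaks the wall, and
threshold crossing is instantaneous (a sustained-force requirement would
be an alternative reading). F_th rises session-by-session on a
config-supplied schedule standing in for the therapist's manual
adjustment; the default is +5% per session, and percent change relative to
session 1 is the reported progression measure.

## Synthetic impaired subject

The plant is a 1-DOF rigid body: I ẍ = F_r + F_p − b ẋ − g₀ cos x, with
I = 0.05 kg·m², b = 0.01 Nms/deg, g₀ = 1 Nm (a generic robot-plus-limb
gravity model; the gravity shape is configurable). Integration is
semi-implicit Euler at 1 ms (2 ms is accepted); the feedback-damping and
viscous terms are treated implicitly so the integrator remains stable when
the gain update drives K_D high.

The human torque is

    F_p = a · clip(k_p (x_s − x) + k_v (v_s − v) + 0.9 g₀ cos x, ±F_max)
          + k_el (x_rest − x) + tremor,

where a ∈ [0,1] is the direction-dependent ability, (x_s, v_s) is the
subject's *internal* minimum-jerk reference moving at their own preferred
pace (clip(2(1.5 − a), 0.8, 4) s — independent of the allotted time, so
leading or lagging the robot emerges from the dynamics rather than being
scripted), k_p = 0.5 Nm/deg and k_v = 0.02 Nms/deg are effort gains,
the 0.9 g₀ cos x term is the subject's own anti-gravity support (scaled by
ability like all voluntary torque), F_max = 4 Nm, and k_el = 0.005 Nm/deg
pulls toward the mid-ROM rest angle (the unintentional elastic return that
aids periphery-to-center movements). Tremor is Gaussian torque noise with
SD 0.05·(1.5 − a) Nm — motor noise shrinks with recovery.

Impairment also produces intermittent voluntary drive: a random-telegraph
gate drops effort to 15% at rate 1.5(1 − a) s⁻¹ (recovery rate 2 s⁻¹).
In *unpowered evaluation movements* a dropout additionally engages a
co-contraction viscous brake of 1.5(1 − a)² Nms/deg, which halts the limb
and produces the arrest-rich speed profiles characteristic of impaired
reaching; during robot-assisted training the haptic guidance is assumed to
suppress this co-contraction, so only the effort loss is modeled there.
Ability grows by `improvement_rate` (default 8%) per session, capped at 1.

A simulated program interleaves a short unassisted evaluation block
(recorded at 200 Hz for AAN runs, 100 Hz for ST, mirroring the two
devices' acquisition rates) with training repetitions that fill the
session's task-time budget; rest between repetitions scales with
impairment (0.5·(2 − a) s). Reaches terminate on target entry within 5%
of the movement amplitude, the package's reading of "the software
acknowledged the reach".

What the generator emulates: direction-dependent weakness, elastic recoil,
tremor, arrest episodes, session-to-session recovery, and the closed-loop
interplay of all of these with both controllers. What it does not:
muscle-level physiology (no Hill-type dynamics), fatigue within a session,
spasticity as a velocity-dependent catch, multi-joint coupling, or
sensor artifacts. Passing tests therefore demonstrate that the
controllers and metrics behave as designed under plausible impaired-limb
dynamics, not that they would produce identical numbers on clinical data.

## Movement-quality pipeline

Velocity records are smoothed with a Savitzky–Golay filter, polynomial
order 3 (unspecified upstream; order 3 with the stated windows gives
smooth low-pass behavior), window 21 samples at 100 Hz and 41 at 200 Hz —
both spanning ≈0.2 s so the impulse responses match on the physical
frequency axis (verified to within 0.05 in magnitude up to 10 Hz); other
rates get the nearest odd window spanning the same interval. Edges are
handled by polynomial fits on truncated windows (`mode="interp"`).

Segmentation: within the window from target cue t₀ to registered reach
t_tar, movement start t_in is the first crossing of 5% of the peak speed.
Suprathreshold regions closer than 150 ms are merged (the proximity rule
needs a number; 150 ms is below any deliberate inter-movement pause),
regions after t_tar whose net displacement is toward the target (overshoot
corrections) extend the movement, and t_fin is the last threshold crossing
of the last toward-target region. A window with no suprathreshold region
raises a no-movement error and the movement counts as incomplete.

Metrics on the cropped speed profile: MAPR = 100·(time above 5% of
peak)/(t_fin − t_in); normalized speed = mean/max; spectral arc length
(SAL) = negative arc length of the zero-frequency-normalized magnitude
spectrum over 0–10 Hz with the frequency axis normalized by the 10 Hz
band edge, so a flat spectrum has length 1 and SAL ≤ −1 always. SAL uses
a zero-padded FFT with chord-length summation; the padding factor
defaults to 256 because the chord sum converges to the continuous value
only at ~10⁻³ with dense frequency sampling. Known SAL caveat: because
the spectrum is normalized per movement, a *longer* movement compresses
its spectral content and can score slightly smoother than a shorter one
with an extra submovement; the monotonicity property test allows 1%
exceptions for SAL on this account.

## Trial statistics

Covariate-adaptive minimization assigns each new subject to whichever
group minimizes Σ_c |mean_A − mean_B|/sd_c over age and baseline ARAT
(standardizing by the covariate SD makes years and points commensurate —
the imbalance functional itself is a package choice); ties break by a
seeded coin flip. Post hoc balance enumerates all equal-split labelings
(feasible to 22 subjects; beyond that, 10⁵ sampled labelings with a
warning) and reports the fraction strictly worse than the realized
assignment.

Sample size for the two-sample t-test uses the normal-approximation
formula n = ⌈2((z_{1−α/2} + z_{power})σ/δ)²⌉ per group, with enrollment
inflated by (1 + loss rate); for the design point δ = 3, σ = 2, 90%
power, 20% loss this gives 10 completers per group and 24 enrolled (the
exact noncentral-t answer is 11 per group; both are computed, labeled
separately, and the one-sample power routine likewise reports normal and
exact values).

Longitudinal slope analysis regresses group-averaged per-session changes
on session index (OLS, t-based 95% CI; exact collinearity is flagged and
yields a zero-width interval). The missing-data policy for the
longitudinal matrix: a subject missing three or more sessions (per DOF
and metric) is excluded; remaining gaps are filled with that subject's
observed mean, and the replacement count is reported. The mixed-design
ANOVA (between: group; within: session) delegates to pingouin;
Greenhouse–Geisser correction is applied when Mauchly's test rejects
sphericity at α = 0.05 (the test level is a package choice), a two-level
within factor has ε = 1 identically, and a significant interaction is
decomposed into per-group repeated-measures ANOVAs. No multiplicity
correction is applied across metrics by default (a Holm option exists in
the analysis scripts' spirit but is deliberately not wired into the ANOVA
itself). Verified calibrations: group-effect type-I rate binomially
consistent with 5% over null replicates, and ≥93/100 CI coverage for the
slope regression.

## Verification scenarios and problem sizes

The self-verification scenarios in `rehabsim.validation` fix their own
problem sizes, chosen so the full suite runs in a couple of minutes:

- **Controller trends**: 3 simulated subjects per replicate, wrist
  pronation/supination joint, 10 sessions of 2 simulated minutes of task
  time at dt = 2 ms; session deltas are averaged over the group before
  regression, matching how the per-session changes are analyzed
  statistically. Five seeded replicates; the expected outcome is a
  negative mean-gain slope and positive repetition slope with 95% CIs
  excluding zero in at least four of five.
- **Gravity learning**: a zero-force subject (no voluntary torque, noise,
  or elastic return) carried through 52 quasi-static reaches (T_end =
  12 s) spanning the elbow ROM in both directions, adaptation rate γ = 5
  and a 1% settling band. Slow reaches isolate the configuration-dependent
  gravity torque: the position-only regressor cannot represent viscous or
  inertial torques, which scale with speed, so fast reaches would fold
  them into the estimate. The learned feedforward is compared with the
  known plant gravity over the visited range; the scenario is
  deterministic.
- **Segmentation recovery**: 200 randomized single-submovement profiles
  with 1%-of-peak measurement noise, smoothed and segmented; ground truth
  is the generator's dense-grid threshold crossings.
- **Statistical calibration**: 50 null mixed-ANOVA replicates
  (7 + 7 subjects × 10 sessions) and 100 slope-regression replicates of a
  known line plus noise.

## Known limitations

- The elbow's very tight r* (0.5% of ROM) makes its task-by-task gain
  updates near-saturating in simulation; the wrist joints exercise the
  gain law in its proportional regime and are the default demonstration
  joints.
- The guidance-suppresses-co-contraction assumption above is a modeling
  convenience with qualitative literature support, not a fitted mechanism.
- Repetition counts in ST mode grow only through shorter rests and faster
  threshold crossings; the carry duration t_ST is fixed, so ST intensity
  trends are weaker than AAN ones.
- All angles are in degrees and torques in Nm throughout; gain units
  (Nms/deg) follow the packaged parameter table.
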