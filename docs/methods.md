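# Methods

## Rolling-resistance model

Rolling resistance of a four-wheeled hand-rim wheelchair is modelled as a
load-weighted sum over the two axles,

    F_IR = c_f · F_N,f + c_r · F_N,r,      F_N,tot = F_N,f + F_N,r,

with unitless coefficients c_f (small front casters) and c_r (large rear
wheels), normally c_f > c_r. Total normal force is taken constant within
a trial (vertical centre-of-mass accelerations are neglected), so the
only time-varying quantity is the front/rear load split.

**Calibration.** Substituting F_N,r = F_N,tot − F_N,f turns each static
drag-test condition into one linear equation in (c_f, c_r):
F_drag = c_r·F_N,tot + (c_f − c_r)·F_N,f. `DragTestCalibration` solves
the stacked system by ordinary least squares — exact for two conditions,
an overdetermined fit for the usual six (upright/bent-forward × three
ballast placements). No sign constraint is imposed: a fit with c_f ≤ c_r
or a negative coefficient is reported with a warning rather than clamped,
because such solutions indicate bad input data and silent repair would
hide that. Condition means are taken over the trailing 10 s of each
recording. F_N,tot comes from the static weight (total mass × 9.81), not
from summing load channels.

## Kinematic features

Eight per-sample predictors are derived from a trunk-mounted and a
wheel-mounted IMU sampled at 100 Hz (both resampled onto one uniform
grid; recordings with gaps above 0.1 s are rejected as incomplete,
shorter gaps are linearly interpolated):

* wheel speed `v_wc` = wheel-axis gyro (deg/s) × wheel diameter × π/360,
  and its derivative `a_wc` (central differences);
* trunk inclination `phi_tr` from a gradient-descent orientation filter
  (gyroscope integration corrected toward the accelerometer's gravity
  direction), its angular velocity `dphi_tr` (lateral-axis gyro) and
  angular acceleration `ddphi_tr`;
* trunk accelerometer channels: perpendicular-to-frontal-plane
  `a_tr_perp`, caudal-cranial `a_tr_par`, and the norm minus 9.81
  (`a_tr_mag`).

The orientation filter's gain β switches per sample: 0.0015 when
|a_wc| < 0.1 m/s² for at least five consecutive samples (evaluated
causally — the sample and its four predecessors must qualify; a value
exactly at the threshold does not), 0.9635 otherwise. During
quasi-constant-velocity propulsion the filter is therefore gyro-led and
recovers the trunk waveform to ≈1° RMSE at 1 % sensor noise. During
sustained high-gain phases (e.g. fast pushing with large speed ripple)
the accelerometer's linear-acceleration corruption leaks into the
estimate and the error grows to several degrees; this is a property of
the switching rule itself, and is why the predictive model rests on
`a_tr_perp` rather than on the inclination estimate.

All assembled channels, outcome included, are low-pass filtered once with
a second-order Butterworth at 3 Hz (trunk motion lives below ~2 Hz),
applied forward and backward. The zero-phase realisation is a design
choice: a causal filter's group delay would misalign predictors against
the outcome within a ~1.5–2.4 s push cycle. Differentiation happens
before filtering. Forward lean is defined positive, upright zero; with
the trunk sensor's z axis pointing left, forward pitch is a negative
rotation about z, so the angular-velocity channel is the negated z gyro.

## Load-distribution model

The outcome is the relative front-wheel load, F_N,f/F_N,tot × 100 %.
Features and outcome are z-scored with statistics fitted on the training
split only. Five estimator families share one interface (linear,
random forest, MLP, LSTM, GRU); the recurrent models consume sliding
windows (stride 1, outcome aligned to the window's last sample). The
default specification is the selected final configuration: a
single-hidden-layer LSTM with 50 units, learning rate 0.01, batch size
128, dropout 0.1 and a 20-sample window, on the three most predictive
features {`v_wc`, `a_wc`, `a_tr_perp`}.

The LSTM/GRU backends are implemented in numpy (BPTT, Adam at the stated
learning rate, MSE loss, gradient clipping at ±5, inverted dropout on the
readout input, early stopping on validation MAE with patience 20 within a
200-epoch budget, all seeded). An optional Gaussian-noise layer perturbs
the standardized inputs per batch during training; comparing test errors
with and without it is the overfitting diagnostic — a model whose output
is driven by white noise degrades visibly.

Splitting is session-wise: held-out participants and held-out wheelchair
configurations go wholesale to the test split; the remainder is divided
80/20 into train/validation by whole sessions. Exhaustive feature
selection scores every non-empty subset of the eight predictors with a
random-forest regressor under grouped k-fold cross-validation whose folds
partition sessions, never samples of one session. Predictions are
de-standardized and clipped to [0, 100] %.

Error conventions: model-fit metrics report ME = mean(observed −
predicted); method comparisons report estimate − reference, so that a
drag test that *under*estimates rolling resistance shows a *negative* ME.
Comparison errors are normalized by the trial-mean gold-standard F_IR and
expressed in percent.

## Simulator

The synthetic-trial generator supplies what an instrumented wheelchair
would: paired IMU streams, a ground-truth load trace and the true F_IR.
Its physics is a quasi-static moment balance about the rear-wheel
contact,

    F_N,f = m (g·x(t) − a(t)·h_com) / wheelbase,
    x(t) = x_static + m_trunk_fraction · trunk_lever · sin(phi(t)),

i.e. trunk lean shifts the centre of mass forward and chair acceleration
produces the backward tipping moment at CoM height. F_N,tot = m·g
throughout. Tip-over (front load leaving (0, F_N,tot)) raises an error
naming the sample.

Default rig: 75 kg total, 0.45 m wheelbase, 0.10 m static CoM offset,
0.60 m CoM height, trunk mass fraction 0.45, 0.25 m trunk lever, 0.66 m
rear wheels, (c_f, c_r) = (0.025, 0.008) — plausibility values for a
court-sports chair plus occupant. Pushing styles: style 1 = no trunk
motion at 1.2 m/s (40 pushes/min), style 2 = unrestricted trunk motion
at 1.2 m/s (25/min), style 3 = unrestricted trunk motion at 1.7 m/s
(40/min); trials last 60 s at 100 Hz.

Trunk motion is a push-locked sinusoid around a mean forward lean, with
a 30 % second harmonic in styles 2–3. The harmonic matters: for a pure
single-frequency sinusoid, angle and angular acceleration are
proportional at every sample, so a per-sample linear model could invert
the accelerometer map as well as any windowed model — an artefact
contradicting real, visibly non-sinusoidal push cycles. Amplitudes are
0.15 rad (style 2) and 0.35 rad (style 3); the propulsion lean offsets
(0.10 / 0.15 rad) encode that pushing means leaning further forward than
static sitting, which is exactly the mechanism that makes the constant
drag-test estimate underestimate rolling resistance. Belt-speed ripple
is small (0.5 / 2 / 3 % of mean speed per push for styles 1/2/3): on a
treadmill the wheel speed is essentially the belt speed. Sensor noise
defaults to 0.1 m/s² (≈1 % of g) and 0.005 rad/s per channel.

Virtual cohorts draw, per participant: total mass U(62, 88) kg; a natural
resting posture lean U(−0.17, 0.28) rad — all participants share one
wheelchair, so their mean load splits differ mainly through posture,
which the sternum accelerometer observes via gravity and which also sets
their drag-test posture; a small hidden seat-placement residual on the
static CoM offset U(0.09, 0.11) m that no sensor can see; and scalings of
trunk amplitude U(0.75, 1.25) and propulsion lean U(0.8, 1.2). This
yields between-participant mean front loads spanning ≥10 percentage
points. Wheelchair-configuration conditions enter through their only
physical channels: added mass raises total mass; lower tyre pressure
scales c_f.

A separate *planted-signal* cohort serves feature-selection diagnostics:
every predictor channel is an independent band-limited (2 Hz) Gaussian
process and the outcome is a weighted combination of a chosen subset
(default {`v_wc`, `a_wc`, `a_tr_perp`}) plus a mild quadratic term and
observation noise. Independence is the point — physics-generated
channels are mutually correlated (angle, angular velocity, angular
acceleration and trunk acceleration all derive from one waveform), so
"exactly this subset is best" is only a well-posed question on
independent channels.

What the simulator does **not** emulate: push-force impulses and arm
dynamics, wheel camber (13° on real court chairs), treadmill-belt or
bearing dynamics, slip, non-sagittal trunk motion, sensor mounting
misalignment beyond noise, and any load-pin measurement error structure.
Passing tests therefore show that the pipeline recovers what this
rigid-body world generates — not that the trained weights transfer to
real propulsion data.

## Test and experiment sizes

Unit and property tests use 5–30 s trials. The cohort experiment used by
the test suite and `scripts/acceptance.py` runs 12 virtual participants,
styles 2–3, 30-s trials, three seeds, with the LSTM at 24 units, 40
epochs and training-window stride 3 — the same architecture family as
the 50-unit default, sized so a full run completes in minutes on one
CPU. Exhaustive selection for the planted cohort uses 10-tree forests
capped at depth 10 on 400 samples per session.

## Known limitations

* The recurrent trainer is plain numpy: adequate for these problem
  sizes, not for large datasets or long windows.
* The orientation filter assumes a magnetometer-free, roll-light trunk;
  large sustained lateral lean would bias the sagittal projection.
* Straight-line propulsion only; wheel-speed-based velocity is not
  corrected for turning.
* The drag-test simulation places ballast at a fixed effective position
  (90 % of the wheelbase ahead of the rear contact); real footrest/leg
  placements vary.
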