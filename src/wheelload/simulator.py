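"""Synthetic propulsion trials with the mechanical structure the method assumes.

The generator stands in for an instrumented-wheelchair dataset: each trial
produces a trunk IMU stream, a wheel IMU stream, a ground-truth load trace
and the true rolling-resistance force, all from a quasi-static rigid-body
load-transfer model.

Physics. With the centre of mass a horizontal distance x(t) ahead of the
rear-wheel contact, moment balance about the rear contact gives the
front-wheel normal force

    FN_f(t) = m * (g * x(t) - a(t) * h_com) / wheelbase,

where a(t) is the horizontal chair acceleration acting at CoM height
h_com (the backward "tipping-over" term) and

    x(t) = x_static + m_trunk_fraction * trunk_lever * sin(phi_trunk(t))

captures the forward mass shift of trunk lean. Vertical CoM acceleration
is neglected, so FN_tot = m * g throughout, and the true rolling
resistance is FIR = cf*FN_f + cr*(FN_tot - FN_f).

Trunk motion is a push-rate-locked sinusoid around a style-dependent mean
forward lean; belt speed carries a small per-push ripple. Styles mirror a
treadmill protocol: style 1 = no trunk motion at 1.2 m/s, style 2 =
unrestricted trunk motion at 1.2 m/s (25 pushes/min), style 3 =
unrestricted trunk motion at 1.7 m/s (40 pushes/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import DragTestRecord
from .dataset import Session, SessionDataset
from .kinematics import (PREDICTORS, FeatureFrame, build_feature_frame)
from .signals import ImuStream, LoadTrace, lowpass

__all__ = [
    "RigConfig",
    "StyleConfig",
    "SimulatedTrial",
    "trunk_waveform",
    "load_transfer",
    "synthesize_imu",
    "simulate_trial",
    "simulate_drag_tests",
    "make_cohort",
    "make_planted_cohort",
    "TipOverError",
]

GRAVITY = 9.81


class TipOverError(ValueError):
    """Front-wheel load left (0, FN_tot): the simulated rig tips over."""


@dataclass(frozen=True)
class RigConfig:
    """Wheelchair + occupant rigid-body parameters."""

    total_mass: float = 75.0          # kg, wheelchair + user
    wheelbase: float = 0.45           # m, front-to-rear contact distance
    com_offset_static: float = 0.10   # m, CoM ahead of rear contact, upright
    com_height: float = 0.60          # m
    trunk_mass_fraction: float = 0.45
    trunk_lever: float = 0.25         # m, hip to trunk CoM
    rear_wheel_diameter: float = 0.66  # m
    cf_true: float = 0.025            # front-caster rolling coefficient
    cr_true: float = 0.008            # rear-wheel rolling coefficient
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        if not 0 < self.com_offset_static < self.wheelbase:
            raise ValueError("com_offset_static must lie in (0, wheelbase)")
        if not 0 < self.trunk_mass_fraction < 1:
            raise ValueError("trunk_mass_fraction must lie in (0, 1)")
        for name in ("total_mass", "wheelbase", "com_height", "trunk_lever",
                     "rear_wheel_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_STYLE_DEFAULTS = {
    # style: (speed m/s, pushes/min, amplitude rad, lean offset rad,
    #         speed ripple, 2nd-harmonic fraction); push-cycle trunk motion
    # is visibly non-sinusoidal, hence the harmonic content in styles 2-3
    1: (1.2, 40.0, 0.0, 0.0, 0.005, 0.0),
    2: (1.2, 25.0, 0.15, 0.10, 0.02, 0.3),
    3: (1.7, 40.0, 0.35, 0.15, 0.03, 0.3),
}


@dataclass(frozen=True)
class StyleConfig:
    """Pushing-style condition: trunk involvement, belt speed, push rate."""

    style: int = 2
    speed_mean: float = 1.2           # m/s
    push_rate: float = 25.0           # pushes/min
    trunk_amplitude: float = 0.15     # rad
    trunk_lean_offset: float = 0.10   # rad, extra forward lean while pushing
    posture_lean: float = 0.0         # rad, natural resting lean (also the
    #                                   drag-test posture)
    speed_ripple: float = 0.02        # proportion of mean speed per push
    duration: float = 60.0            # s
    rate_hz: float = 100.0
    noise_sd_accel: float = 0.1       # m/s^2, ~1 % of g
    noise_sd_gyro: float = 0.005      # rad/s
    trunk_phase: float = 0.0          # rad, push-cycle phase offset
    harmonic2: float = 0.0            # relative 2nd-harmonic amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if (self.trunk_amplitude == 0) != (self.style == 1):
            raise ValueError("trunk_amplitude == 0 if and only if style 1")

    @classmethod
    def preset(cls, style: int, **overrides) -> "StyleConfig":
        if style not in _STYLE_DEFAULTS:
            raise ValueError("style must be 1, 2 or 3")
        speed, rate, amp, lean, ripple, h2 = _STYLE_DEFAULTS[style]
        kw = dict(style=style, speed_mean=speed, push_rate=rate,
                  trunk_amplitude=amp, trunk_lean_offset=lean,
                  speed_ripple=ripple, harmonic2=h2)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimulatedTrial:
    """Paired synthetic IMU streams, ground-truth load and provenance."""

    trunk: ImuStream
    wheel: ImuStream
    load: LoadTrace
    truth: pd.DataFrame   # time_s, trunk_angle_rad, speed_ms, accel_ms2,
    #                       fn_front_N, f_ir_N
    rig: RigConfig
    style: StyleConfig

    @property
    def fn_total(self) -> float:
        return self.rig.total_mass * self.rig.gravity

    @property
    def rel_front_static(self) -> float:
        """Static front-load share in percent at the drag-test posture.

        During a drag test the occupant sits still in their natural
        resting posture (``posture_lean``) without the extra propulsion
        lean, so this is the load split the classical constant estimate
        is based on.
        """
        fn_f, fn_tot = load_transfer(self.rig, self.style.posture_lean, 0.0)
        return float(fn_f / fn_tot * 100.0)


def trunk_waveform(style: StyleConfig, t: np.ndarray):
    """(angle, angular velocity, angular acceleration) of the trunk.

    A push-rate-locked sinusoid of amplitude ``trunk_amplitude`` around
    ``trunk_lean_offset`` with an optional second harmonic; derivatives are
    analytic, so angle/velocity/acceleration are exactly consistent.
    """
    t = np.asarray(t, dtype=float)
    mean_lean = style.posture_lean + style.trunk_lean_offset
    if style.trunk_amplitude == 0:
        zero = np.zeros_like(t)
        return zero + mean_lean, zero.copy(), zero.copy()
    w = 2 * np.pi * style.push_rate / 60.0
    a1 = style.trunk_amplitude
    a2 = style.harmonic2 * a1
    ph = style.trunk_phase
    angle = (mean_lean + a1 * np.sin(w * t + ph)
             + a2 * np.sin(2 * w * t + 2 * ph))
    vel = a1 * w * np.cos(w * t + ph) + a2 * 2 * w * np.cos(2 * w * t + 2 * ph)
    acc = (-a1 * w**2 * np.sin(w * t + ph)
           - a2 * (2 * w)**2 * np.sin(2 * w * t + 2 * ph))
    return angle, vel, acc


def load_transfer(rig: RigConfig, trunk_angle, chair_accel):
    """Quasi-static front/total normal force from lean and acceleration."""
    trunk_angle = np.asarray(trunk_angle, dtype=float)
    chair_accel = np.asarray(chair_accel, dtype=float)
    x = (rig.com_offset_static
         + rig.trunk_mass_fraction * rig.trunk_lever * np.sin(trunk_angle))
    fn_front = rig.total_mass * (rig.gravity * x
                                 - chair_accel * rig.com_height) / rig.wheelbase
    fn_total = rig.total_mass * rig.gravity
    bad = (fn_front <= 0) | (fn_front >= fn_total)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise TipOverError(
            f"non-physical front load {np.atleast_1d(fn_front)[i]:.1f} N "
            f"at sample {i} (fn_total {fn_total:.1f} N)"
        )
    return fn_front, np.broadcast_to(fn_total, fn_front.shape)


def _speed_profile(style: StyleConfig, t: np.ndarray):
    w = 2 * np.pi * style.push_rate / 60.0
    amp = style.speed_ripple * style.speed_mean
    ph = style.trunk_phase
    speed = style.speed_mean + amp * np.sin(w * t + ph)
    accel = amp * w * np.cos(w * t + ph)
    return speed, accel


def synthesize_imu(rig: RigConfig, style: StyleConfig, t, trunk_angle,
                   trunk_vel, trunk_acc, speed, chair_accel,
                   rng=None):
    """Trunk and wheel IMU streams consistent with the truth kinematics.

    Wheel: z (axis) gyro channel = speed / wheel radius. Trunk: z (left
    lateral) gyro = -trunk angular velocity (forward pitch is a negative
    rotation about the left axis); accelerometer = gravity plus the chair
    and trunk-CoM linear accelerations rotated into the trunk frame.
    Zero-mean Gaussian noise at the configured sd is added to every
    channel.
    """
    if rng is None:
        rng = np.random.default_rng(style.seed)
    t = np.asarray(t, dtype=float)
    n = len(t)

    wheel_gyro = np.zeros((n, 3))
    wheel_gyro[:, 2] = speed / (rig.rear_wheel_diameter / 2.0)
    wheel_accel = np.zeros((n, 3))
    wheel_accel[:, 1] = rig.gravity  # frame-fixed, y up

    trunk_gyro = np.zeros((n, 3))
    trunk_gyro[:, 2] = -np.asarray(trunk_vel)

    # world-frame specific force of the trunk sensor (x anterior, y up)
    sphi, cphi = np.sin(trunk_angle), np.cos(trunk_angle)
    lx = rig.trunk_lever * (trunk_acc * cphi - trunk_vel**2 * sphi)
    ly = rig.trunk_lever * (-trunk_acc * sphi - trunk_vel**2 * cphi)
    fw_x = chair_accel + lx
    fw_y = ly + rig.gravity
    trunk_accel = np.zeros((n, 3))
    trunk_accel[:, 0] = cphi * fw_x - sphi * fw_y
    trunk_accel[:, 1] = sphi * fw_x + cphi * fw_y

    if style.noise_sd_gyro > 0:
        wheel_gyro = wheel_gyro + rng.normal(0, style.noise_sd_gyro, (n, 3))
        trunk_gyro = trunk_gyro + rng.normal(0, style.noise_sd_gyro, (n, 3))
    if style.noise_sd_accel > 0:
        wheel_accel = wheel_accel + rng.normal(0, style.noise_sd_accel, (n, 3))
        trunk_accel = trunk_accel + rng.normal(0, style.noise_sd_accel, (n, 3))

    trunk = ImuStream("trunk", t, trunk_gyro, trunk_accel, rate_hz=style.rate_hz)
    wheel = ImuStream("wheel", t, wheel_gyro, wheel_accel, rate_hz=style.rate_hz)
    return trunk, wheel


def simulate_trial(rig: RigConfig, style: StyleConfig) -> SimulatedTrial:
    """One 60-s (configurable) trial on a uniform grid."""
    n = int(round(style.duration * style.rate_hz)) + 1
    t = np.arange(n) / style.rate_hz
    rng = np.random.default_rng(style.seed)
    angle, vel, acc = trunk_waveform(style, t)
    speed, accel = _speed_profile(style, t)
    fn_front, fn_total = load_transfer(rig, angle, accel)
    f_ir = rig.cf_true * fn_front + rig.cr_true * (fn_total - fn_front)
    trunk, wheel = synthesize_imu(rig, style, t, angle, vel, acc,
                                  speed, accel, rng=rng)
    load = LoadTrace(t, fn_front, fn_total[0])
    truth = pd.DataFrame({
        "time_s": t,
        "trunk_angle_rad": angle,
        "speed_ms": speed,
        "accel_ms2": accel,
        "fn_front_N": fn_front,
        "f_ir_N": f_ir,
    })
    return SimulatedTrial(trunk=trunk, wheel=wheel, load=load, truth=truth,
                          rig=rig, style=style)


def simulate_drag_tests(rig: RigConfig, conditions=None, noise_sd: float = 0.0,
                        seed: int = 0) -> list:
    """Static drag-test records over posture/ballast conditions.

    ``conditions`` is a list of ``(condition_id, trunk_angle_rad,
    added_front_mass_kg)``; the default six mirror upright/bent-forward
    postures with 0 or 10 kg ballast near the footrests. Drag force is the
    true rolling resistance of each static load split, optionally with
    multiplicative measurement noise.
    """
    if conditions is None:
        conditions = [
            ("upright", 0.0, 0.0),
            ("bent", 0.5, 0.0),
            ("upright+10kg-feet", 0.0, 10.0),
            ("bent+10kg-feet", 0.5, 10.0),
            ("upright+10kg-legs", 0.0, 5.0),
            ("bent+10kg-legs", 0.5, 5.0),
        ]
    rng = np.random.default_rng(seed)
    records = []
    for cid, angle, m_add in conditions:
        base_front, base_total = load_transfer(rig, angle, 0.0)
        # ballast rides near the footrests, over the front axle
        x_add = 0.9 * rig.wheelbase
        fn_front = float(base_front) + m_add * rig.gravity * x_add / rig.wheelbase
        fn_total = float(base_total) + m_add * rig.gravity
        drag = rig.cf_true * fn_front + rig.cr_true * (fn_total - fn_front)
        if noise_sd > 0:
            drag *= 1.0 + rng.normal(0.0, noise_sd)
            fn_front *= 1.0 + rng.normal(0.0, noise_sd)
        records.append(DragTestRecord(condition_id=cid, f_drag_mean=drag,
                                      fn_front_mean=fn_front,
                                      fn_total=fn_total))
    fronts = [r.fn_front_mean for r in records]
    if len(records) >= 2 and np.ptp(fronts) < 1e-9:
        import warnings
        warnings.warn("all drag conditions share one front load; "
                      "the coefficient solve will be rank-deficient")
    return records


#: wheelchair-configuration surrogates: tyre pressure enters through the
#: front coefficient, added mass through total mass
_CONDITIONS = {
    "original": {},
    "+5kg": {"total_mass": +5.0},
    "+15kg": {"total_mass": +15.0},
    "-1.75bar": {"cf_scale": 1.3},
    "-3.5bar": {"cf_scale": 1.6},
}


def _apply_condition(rig: RigConfig, condition: str) -> RigConfig:
    mods = _CONDITIONS[condition]
    kw = {}
    if "total_mass" in mods:
        kw["total_mass"] = rig.total_mass + mods["total_mass"]
    if "cf_scale" in mods:
        kw["cf_true"] = rig.cf_true * mods["cf_scale"]
    return replace(rig, **kw) if kw else rig


def make_cohort(n_participants: int = 12, styles=(1, 2, 3),
                conditions=("original",), seed: int = 0,
                duration: float = 60.0, rate_hz: float = 100.0,
                rig_ranges: dict | None = None,
                base_rig: RigConfig | None = None) -> SessionDataset:
    """A virtual cohort: one session per participant/condition/style.

    Per participant, parameters are drawn from uniform ranges: total mass;
    a natural resting posture lean (all participants share one wheelchair,
    so their mean load splits differ mainly through posture, which the
    sternum sensor observes via gravity); a small seat-placement residual
    on the static CoM offset (unobservable by any sensor); and scalings of
    the style-dependent trunk amplitude and propulsion lean. Each
    session's feature frame is produced by the full sensing pipeline
    (noisy IMU synthesis, orientation filtering, feature extraction) with
    the measured load trace as outcome. Session ``meta`` carries what the
    downstream comparison needs: FN_tot, the true coefficients and the
    static front-load share at the drag-test posture.
    """
    if n_participants < 4:
        raise ValueError("need >= 4 participants so holdouts remain possible")
    ranges = {
        "total_mass": (62.0, 88.0),
        "posture_lean": (-0.17, 0.28),
        "com_offset_static": (0.09, 0.11),
        "amplitude_scale": (0.75, 1.25),
        "lean_scale": (0.8, 1.2),
    }
    if rig_ranges:
        ranges.update(rig_ranges)
    for name, (lo, hi) in ranges.items():
        if not hi > lo:
            raise ValueError(f"degenerate range for {name}")
    base = base_rig or RigConfig()
    rng = np.random.default_rng(seed)
    sessions = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        rig_p = replace(
            base,
            total_mass=float(rng.uniform(*ranges["total_mass"])),
            com_offset_static=float(rng.uniform(*ranges["com_offset_static"])),
        )
        amp_scale = float(rng.uniform(*ranges["amplitude_scale"]))
        lean_scale = float(rng.uniform(*ranges["lean_scale"]))
        posture = float(rng.uniform(*ranges["posture_lean"]))
        for condition in conditions:
            rig_c = _apply_condition(rig_p, condition)
            for st in styles:
                style = StyleConfig.preset(
                    st,
                    duration=duration,
                    rate_hz=rate_hz,
                    posture_lean=posture,
                    trunk_phase=float(rng.uniform(0, 2 * np.pi)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                if st != 1:
                    style = replace(
                        style,
                        trunk_amplitude=style.trunk_amplitude * amp_scale,
                        trunk_lean_offset=style.trunk_lean_offset * lean_scale,
                    )
                trial = simulate_trial(rig_c, style)
                frame = build_feature_frame(trial.trunk, trial.wheel,
                                            rig_c.rear_wheel_diameter,
                                            load=trial.load)
                sessions.append(Session(
                    participant_id=pid,
                    session_type=condition,
                    pushing_style=st,
                    frame=frame,
                    meta={
                        "fn_total": trial.fn_total,
                        "cf_true": rig_c.cf_true,
                        "cr_true": rig_c.cr_true,
                        "rel_front_static": trial.rel_front_static,
                        "speed_mean": style.speed_mean,
                    },
                ))
    return SessionDataset(sessions)


def make_planted_cohort(n_participants: int = 8, n_sessions_each: int = 2,
                        weights: dict | None = None, seed: int = 0,
                        duration: float = 30.0, rate_hz: float = 100.0,
                        noise_sd: float = 0.5) -> SessionDataset:
    """Diagnostic cohort with the outcome planted on a chosen feature subset.

    Every predictor channel is an independent band-limited Gaussian
    process (2-Hz low-passed white noise, unit variance), and the outcome
    is a weighted combination of the channels named in ``weights`` (plus a
    mild quadratic term and observation noise), centred at a realistic
    front-load level. Channels outside ``weights`` carry zero signal by
    construction, which makes exact subset recovery by feature selection
    well-posed — unlike physics-generated channels, which are mutually
    correlated.
    """
    if weights is None:
        weights = {"v_wc": 4.0, "a_wc": 3.0, "a_tr_perp": 3.0}
    unknown = set(weights) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown feature names {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    sessions = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for si in range(n_sessions_each):
            cols = {"time_s": t}
            z = {}
            for name in PREDICTORS:
                raw = rng.standard_normal(n)
                smooth = lowpass(raw, 2.0, rate_hz, 2)
                smooth = (smooth - smooth.mean()) / smooth.std()
                z[name] = smooth
                cols[name] = smooth
            y = np.full(n, 22.0)
            for name, w in weights.items():
                y = y + w * z[name]
            first = next(iter(weights))
            y = y + 0.5 * z[first] ** 2
            y = y + rng.normal(0.0, noise_sd, n)
            cols["rel_front"] = np.clip(y, 0.0, 100.0)
            frame = FeatureFrame(pd.DataFrame(cols))
            sessions.append(Session(
                participant_id=pid, session_type="planted",
                pushing_style=2 + (si % 2), frame=frame,
                meta={"weights": dict(weights)},
            ))
    return SessionDataset(sessions)
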