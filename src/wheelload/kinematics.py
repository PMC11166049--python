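"""Predictor features from trunk- and wheel-mounted inertial sensors.

Eight per-sample predictors describe wheelchair and trunk motion:

========== ==========================================================
name       meaning
========== ==========================================================
v_wc       wheelchair (belt-frame) velocity, m/s, from the wheel gyro
a_wc       wheelchair acceleration, m/s^2, derivative of v_wc
phi_tr     trunk inclination angle, rad, from a gradient-descent
           (Madgwick-type) orientation filter with a switching gain
dphi_tr    trunk angular velocity about the lateral axis, rad/s
ddphi_tr   trunk angular acceleration, rad/s^2
a_tr_perp  trunk acceleration perpendicular to the frontal plane, m/s^2
a_tr_par   trunk caudal-cranial acceleration, m/s^2
a_tr_mag   ||trunk accel||_2 - 9.81, m/s^2
========== ==========================================================

The outcome, when a load trace is supplied, is the relative front-wheel
load in percent.

Sign conventions: forward lean is positive inclination and upright is 0.
With the trunk sensor's z axis pointing to the left, forward pitch is a
negative rotation about z, so ``dphi_tr`` is the negated z gyro channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import ImuStream, LoadTrace, lowpass

__all__ = [
    "PREDICTORS",
    "FeatureFrame",
    "OrientationTrack",
    "wheel_velocity",
    "differentiate",
    "beta_schedule",
    "trunk_orientation",
    "trunk_inclination",
    "trunk_accel_features",
    "build_feature_frame",
    "align_streams",
]

PREDICTORS = (
    "v_wc",
    "a_wc",
    "phi_tr",
    "dphi_tr",
    "ddphi_tr",
    "a_tr_perp",
    "a_tr_par",
    "a_tr_mag",
)
OUTCOME = "rel_front"

GRAVITY = 9.81
#: filter gain during quasi-constant-velocity propulsion
BETA_LOW = 0.0015
#: filter gain otherwise
BETA_HIGH = 0.9635
#: |wheelchair acceleration| threshold for the low-gain state, m/s^2
BETA_ACCEL_THRESHOLD = 0.1
#: number of consecutive below-threshold samples required
BETA_CONSECUTIVE = 5
#: low-pass cut-off applied to the assembled frame, Hz (trunk motion < ~2 Hz)
FILTER_CUTOFF_HZ = 3.0
FILTER_ORDER = 2


@dataclass
class FeatureFrame:
    """Per-sample predictor features, optionally with the outcome.

    ``data`` holds one row per sample with a ``time_s`` column, the eight
    predictors and, when available, ``rel_front`` in percent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("time_s", *PREDICTORS):
            if c not in self.data.columns:
                raise ValueError(f"feature frame missing column {c!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def has_outcome(self) -> bool:
        return OUTCOME in self.data.columns

    def features(self, subset=None) -> np.ndarray:
        cols = list(subset) if subset is not None else list(PREDICTORS)
        return self.data[cols].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        if not self.has_outcome:
            raise ValueError("feature frame carries no outcome channel")
        return self.data[OUTCOME].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "FeatureFrame":
        return cls(pd.read_csv(path))


@dataclass
class OrientationTrack:
    """Quaternion (sensor-to-world, scalar first) and gain per sample."""

    q: np.ndarray      # (n, 4)
    beta: np.ndarray   # (n,)


def wheel_velocity(wheel_gyro_dps, rear_wheel_diameter: float):
    """Wheelchair velocity from the wheel-axis gyro channel.

    v = gyro[deg/s] * diameter * pi / 360, i.e. wheel angular velocity
    times wheel radius. Forward motion is positive.
    """
    if rear_wheel_diameter <= 0:
        raise ValueError("rear wheel diameter must be positive")
    return np.asarray(wheel_gyro_dps, dtype=float) * rear_wheel_diameter * np.pi / 360.0


def differentiate(series, rate_hz: float):
    """Time derivative: central differences interior, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / rate_hz, axis=0)


def beta_schedule(a_wc) -> np.ndarray:
    """Per-sample orientation-filter gain from wheelchair acceleration.

    A sample gets the low gain only when it is the 5th-or-later sample of a
    consecutive run with |a_wc| strictly below 0.1 m/s^2 (evaluated
    causally: the sample itself and the 4 preceding ones must qualify);
    otherwise the high gain applies.
    """
    a_wc = np.asarray(a_wc, dtype=float)
    below = np.abs(a_wc) < BETA_ACCEL_THRESHOLD
    beta = np.full(a_wc.shape, BETA_HIGH)
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= BETA_CONSECUTIVE:
            beta[i] = BETA_LOW
    return beta


def _quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def trunk_orientation(trunk: ImuStream, beta: np.ndarray) -> OrientationTrack:
    """Gradient-descent orientation filter over the trunk stream.

    Gyroscope integration corrected toward the accelerometer's gravity
    direction (world reference +y = up), with the per-sample gain from
    :func:`beta_schedule`. Initialised from the first-sample accelerometer
    tilt. Quaternions are unit norm after every update.
    """
    n = len(trunk)
    if len(beta) != n:
        raise ValueError("beta schedule length must match stream length")
    a0 = trunk.accel[0]
    if np.linalg.norm(a0) < 1e-9:
        raise ValueError("zero-norm accelerometer sample at initialization")
    phi0 = np.arctan2(-a0[0], a0[1])
    # sensor-to-world rotation for forward lean phi is Rot(z, -phi)
    q = np.array([np.cos(phi0 / 2), 0.0, 0.0, -np.sin(phi0 / 2)])
    dt = 1.0 / trunk.rate_hz
    out = np.empty((n, 4))
    out[0] = q
    gyro = trunk.gyro
    accel = trunk.accel
    for i in range(1, n):
        w, x, y, z = q
        gx, gy, gz = gyro[i]
        # qdot from gyro: 0.5 * q (x) (0, omega)
        qdw = 0.5 * (-x * gx - y * gy - z * gz)
        qdx = 0.5 * (w * gx + y * gz - z * gy)
        qdy = 0.5 * (w * gy - x * gz + z * gx)
        qdz = 0.5 * (w * gz + x * gy - y * gx)
        an = np.linalg.norm(accel[i])
        if an > 1e-9:
            ax, ay, az = accel[i] / an
            # estimated gravity direction in sensor frame minus measured
            f1 = 2.0 * (x * y + w * z) - ax
            f2 = 1.0 - 2.0 * (x * x + z * z) - ay
            f3 = 2.0 * (y * z - w * x) - az
            # gradient of the alignment objective, J^T f
            gw = 2.0 * z * f1 - 2.0 * x * f3
            gx_ = 2.0 * y * f1 - 4.0 * x * f2 - 2.0 * w * f3
            gy_ = 2.0 * x * f1 + 2.0 * z * f3
            gz_ = 2.0 * w * f1 - 4.0 * z * f2 + 2.0 * y * f3
            gn = np.sqrt(gw * gw + gx_ * gx_ + gy_ * gy_ + gz_ * gz_)
            if gn > 1e-12:
                b = beta[i] / gn
                qdw -= b * gw
                qdx -= b * gx_
                qdy -= b * gy_
                qdz -= b * gz_
        q = np.array([w + qdw * dt, x + qdx * dt, y + qdy * dt, z + qdz * dt])
        q = _quat_normalize(q)
        out[i] = q
    return OrientationTrack(q=out, beta=np.asarray(beta, dtype=float))


def trunk_inclination(track: OrientationTrack) -> np.ndarray:
    """Sagittal-plane angle of the trunk caudal-cranial axis vs vertical.

    The sensor y axis is rotated into the world frame and projected onto
    the sagittal (x-y) plane; forward lean is positive, upright is 0.
    """
    q = np.asarray(track.q)
    if q.size == 0:
        raise ValueError("empty orientation sequence")
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # world coordinates of the sensor y (cranial) axis
    ux = 2.0 * (x * y - w * z)
    uy = 1.0 - 2.0 * (x * x + z * z)
    return np.arctan2(ux, uy)


def trunk_accel_features(trunk: ImuStream):
    """(a_tr_perp, a_tr_par, a_tr_mag) from the trunk accelerometer.

    Perpendicular-to-frontal-plane and caudal-cranial components are the
    sensor x and y channels; the magnitude channel is the Euclidean norm
    of the 3-D signal minus 9.81.
    """
    a = trunk.accel
    return a[:, 0], a[:, 1], np.linalg.norm(a, axis=1) - GRAVITY


def align_streams(trunk: ImuStream, wheel: ImuStream,
                  rate_hz: float = 100.0) -> tuple[ImuStream, ImuStream]:
    """Resample both sensors onto one shared uniform grid over their overlap."""
    t0 = max(trunk.t[0], wheel.t[0])
    t1 = min(trunk.t[-1], wheel.t[-1])
    if t1 - t0 < 2.0 / rate_hz:
        raise ValueError("streams do not overlap long enough")
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    grid = t0 + np.arange(n) / rate_hz

    def _interp(s: ImuStream) -> ImuStream:
        gyro = np.column_stack([np.interp(grid, s.t, s.gyro[:, k]) for k in range(3)])
        accel = np.column_stack([np.interp(grid, s.t, s.accel[:, k]) for k in range(3)])
        return ImuStream(s.sensor_id, grid, gyro, accel, rate_hz=rate_hz)

    return _interp(trunk), _interp(wheel)


def build_feature_frame(trunk: ImuStream, wheel: ImuStream,
                        rear_wheel_diameter: float,
                        load: LoadTrace | None = None) -> FeatureFrame:
    """Assemble all eight predictors (and the outcome) on the shared grid.

    Both streams must already be on one uniform grid (see
    :func:`align_streams`). Derivatives are taken on the raw channels;
    the 3-Hz second-order zero-phase low-pass is then applied once to every
    assembled channel, outcome included.
    """
    if len(trunk) != len(wheel) or not np.allclose(trunk.t, wheel.t, atol=1e-9):
        raise ValueError("trunk and wheel streams are not on a common grid")
    if abs(trunk.rate_hz - wheel.rate_hz) > 1e-9:
        raise ValueError("trunk and wheel streams have different rates")
    rate = trunk.rate_hz
    t = trunk.t

    wheel_gyro_dps = np.degrees(wheel.gyro[:, 2])
    v_wc = wheel_velocity(wheel_gyro_dps, rear_wheel_diameter)
    a_wc = differentiate(v_wc, rate)
    beta = beta_schedule(a_wc)
    phi = trunk_inclination(trunk_orientation(trunk, beta))
    dphi = -trunk.gyro[:, 2]
    ddphi = differentiate(dphi, rate)
    a_perp, a_par, a_mag = trunk_accel_features(trunk)

    cols = {
        "time_s": t,
        "v_wc": v_wc,
        "a_wc": a_wc,
        "phi_tr": phi,
        "dphi_tr": dphi,
        "ddphi_tr": ddphi,
        "a_tr_perp": a_perp,
        "a_tr_par": a_par,
        "a_tr_mag": a_mag,
    }
    if load is not None:
        cols[OUTCOME] = np.interp(t, load.t, load.rel_front)
    for name, series in cols.items():
        if name == "time_s":
            continue
        cols[name] = lowpass(series, FILTER_CUTOFF_HZ, rate, FILTER_ORDER)
    if load is not None:
        cols[OUTCOME] = np.clip(cols[OUTCOME], 0.0, 100.0)
    return FeatureFrame(pd.DataFrame(cols))
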