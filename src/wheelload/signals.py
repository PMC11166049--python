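"""Time-series containers, CSV I/O, resampling and filtering.

Everything entering the pipeline is one of two containers:

* :class:`ImuStream` — one inertial sensor's gyroscope (rad/s internally,
  deg/s in files) and accelerometer (m/s^2) channels on a strictly
  increasing time base.
* :class:`LoadTrace` — front-wheel and total normal force with the derived
  relative front-wheel load in percent.

Axis convention (enforced by the simulator, documented in the README):
trunk sensor x = anterior, y = caudal->cranial, z = left lateral;
wheel sensor z = wheel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "ImuStream",
    "LoadTrace",
    "read_imu_csv",
    "write_imu_csv",
    "read_load_csv",
    "write_load_csv",
    "resample_to_grid",
    "lowpass",
    "GapError",
    "FormatError",
]

DEG2RAD = np.pi / 180.0
#: maximum tolerated gap between consecutive samples before a session is
#: rejected as incomplete (s)
MAX_GAP_S = 0.1

IMU_COLUMNS = (
    "time_s",
    "gyro_x_dps",
    "gyro_y_dps",
    "gyro_z_dps",
    "acc_x_ms2",
    "acc_y_ms2",
    "acc_z_ms2",
)
LOAD_COLUMNS = ("time_s", "fn_front_N", "fn_total_N")


class FormatError(ValueError):
    """A CSV file does not follow the expected dialect."""


class GapError(ValueError):
    """A recording contains a gap too long to repair; session incomplete."""


@dataclass
class ImuStream:
    """Timestamped 3-axis gyro/accel samples from one sensor.

    Parameters
    ----------
    sensor_id : {'trunk', 'wheel', 'frame'}
    t : (n,) seconds from session start, strictly increasing
    gyro : (n, 3) angular velocity, rad/s
    accel : (n, 3) specific force, m/s^2
    rate_hz : nominal sampling frequency
    """

    sensor_id: str
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(len(self.t), 3)
        self.accel = np.asarray(self.accel, dtype=float).reshape(len(self.t), 3)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.isfinite(self.t).all() and np.isfinite(self.gyro).all()
                and np.isfinite(self.accel).all()):
            raise ValueError("non-finite values in stream")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class LoadTrace:
    """Front/total normal force and relative front-wheel load.

    ``rel_front`` is fn_front / fn_total * 100 at every sample; the rear
    wheel force is the implied complement fn_total - fn_front.
    """

    t: np.ndarray
    fn_front: np.ndarray
    fn_total: np.ndarray
    rel_front: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fn_front = np.asarray(self.fn_front, dtype=float)
        self.fn_total = np.broadcast_to(
            np.asarray(self.fn_total, dtype=float), self.t.shape
        ).copy()
        if np.any(self.fn_total <= 0):
            raise ValueError("fn_total must be positive")
        self.rel_front = self.fn_front / self.fn_total * 100.0
        if np.any((self.rel_front < 0) | (self.rel_front > 100)):
            raise ValueError("rel_front outside [0, 100]")

    def __len__(self) -> int:
        return len(self.t)


def _repair_gaps(t: np.ndarray, channels: np.ndarray, rate_hz: float):
    """Reject gaps > MAX_GAP_S; shorter gaps are left to linear resampling."""
    dt = np.diff(t)
    if np.any(dt > MAX_GAP_S):
        i = int(np.argmax(dt > MAX_GAP_S))
        raise GapError(
            f"gap of {dt[i]:.3f} s at t={t[i]:.3f} s exceeds {MAX_GAP_S} s; "
            "session incomplete"
        )
    return t, channels


def read_imu_csv(path, sensor_id: str) -> ImuStream:
    """Read one sensor's session CSV.

    Gyro columns are converted from deg/s (file) to rad/s (internal) at this
    boundary. Samples are sorted by time and duplicate timestamps collapsed
    (first occurrence kept). Rows with non-finite values are dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.loc[np.isfinite(df[list(IMU_COLUMNS)]).all(axis=1)]
    df = df.sort_values("time_s").drop_duplicates("time_s", keep="first")
    if len(df) < 2:
        raise FormatError(f"{path}: fewer than 2 usable samples")
    t = df["time_s"].to_numpy()
    gyro = df[["gyro_x_dps", "gyro_y_dps", "gyro_z_dps"]].to_numpy() * DEG2RAD
    accel = df[["acc_x_ms2", "acc_y_ms2", "acc_z_ms2"]].to_numpy()
    rate = 1.0 / np.median(np.diff(t))
    _repair_gaps(t, gyro, rate)
    return ImuStream(sensor_id, t, gyro, accel, rate_hz=float(round(rate)))


def write_imu_csv(stream: ImuStream, path) -> None:
    """Inverse of :func:`read_imu_csv` (gyro back to deg/s)."""
    df = pd.DataFrame(
        {
            "time_s": stream.t,
            "gyro_x_dps": stream.gyro[:, 0] / DEG2RAD,
            "gyro_y_dps": stream.gyro[:, 1] / DEG2RAD,
            "gyro_z_dps": stream.gyro[:, 2] / DEG2RAD,
            "acc_x_ms2": stream.accel[:, 0],
            "acc_y_ms2": stream.accel[:, 1],
            "acc_z_ms2": stream.accel[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_load_csv(path) -> LoadTrace:
    df = pd.read_csv(path)
    missing = [c for c in LOAD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return LoadTrace(
        df["time_s"].to_numpy(),
        df["fn_front_N"].to_numpy(),
        df["fn_total_N"].to_numpy(),
    )


def write_load_csv(trace: LoadTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.t, "fn_front_N": trace.fn_front,
         "fn_total_N": trace.fn_total}
    ).to_csv(path, index=False, float_format="%.9g")


def resample_to_grid(stream: ImuStream, rate_hz: float = 100.0) -> ImuStream:
    """Linearly interpolate all channels onto a uniform grid at ``rate_hz``.

    The grid covers the original span; sensors logging asynchronously are
    brought onto one common time base this way before feature extraction.
    """
    if stream.duration < 2.0 / rate_hz:
        raise ValueError("stream too short to resample")
    n = int(np.floor(stream.duration * rate_hz)) + 1
    grid = stream.t[0] + np.arange(n) / rate_hz
    gyro = np.column_stack(
        [np.interp(grid, stream.t, stream.gyro[:, k]) for k in range(3)]
    )
    accel = np.column_stack(
        [np.interp(grid, stream.t, stream.accel[:, k]) for k in range(3)]
    )
    return ImuStream(stream.sensor_id, grid, gyro, accel, rate_hz=rate_hz)


def lowpass(series, cutoff_hz: float, rate_hz: float, order: int = 2):
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The zero-phase realisation keeps intra-cycle load features aligned in
    time with the outcome; a causal filter would lag predictors against the
    load trace within a ~1.5-s push cycle. DC gain is exactly 1.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist)")
    if series.shape[0] <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return _sig.sosfiltfilt(sos, series, axis=0)


def crop_overlap(a: ImuStream, b: ImuStream) -> tuple[ImuStream, ImuStream]:
    """Crop two streams to their common time span."""
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 <= t0:
        raise ValueError("streams do not overlap in time")

    def _crop(s: ImuStream) -> ImuStream:
        m = (s.t >= t0 - 1e-12) & (s.t <= t1 + 1e-12)
        return ImuStream(s.sensor_id, s.t[m], s.gyro[m], s.accel[m],
                         rate_hz=s.rate_hz)

    return _crop(a), _crop(b)
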