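"""Reading, calibrating, band-pass filtering, and trimming of raw IMU recordings.

A five-times sit-to-stand (FTSS) trial is recorded by a tri-axial
accelerometer + tri-axial gyroscope sampled at a nominal 102.4 Hz, with the
sensor strapped either to the sternum (torso) or along the lateral thigh.
The preprocessing chain is fixed: calibrate -> band-pass filter -> trim the
first second of sensor settling.  All downstream stages (segmentation,
feature extraction) assume this order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError, FormatError, ParameterError

NOMINAL_RATE_HZ = 102.4
#: default Butterworth band edges, Hz
DEFAULT_BAND_HZ = (0.01, 5.0)
#: seconds of sensor-settling data removed from the head of every trial
DEFAULT_TRIM_S = 1.0

SENSOR_LOCATIONS = ("torso", "thigh")

#: column order of the on-disk CSV dialect
CSV_COLUMNS = ("time_s", "ax", "ay", "az", "gx", "gy", "gz")

_G = 9.80665  # standard gravity, m/s² per g

ACCEL_UNIT_FACTORS = {"m/s2": 1.0, "g": _G}
GYRO_UNIT_FACTORS = {"deg/s": 1.0, "rad/s": 180.0 / np.pi}


@dataclass(frozen=True)
class ImuRecording:
    """One FTSS trial from one sensor location.

    accel columns are X, Y, Z in the sensor frame, m/s²; gyro columns are
    angular velocity about the same axes, deg/s.  Torso convention: the
    Z axis is approximately anteroposterior, so the primary movement channel
    is ``accel[:, 2]``.  Thigh convention: the Y axis runs along the femur,
    so the primary channel is ``accel[:, 1]``.
    """

    subject_id: str
    trial_id: str
    sensor_location: str
    sampling_rate_hz: float
    time_s: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    #: processing provenance, appended by each preprocessing stage
    history: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.accel, dtype=float)
        g = np.asarray(self.gyro, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "accel", a)
        object.__setattr__(self, "gyro", g)
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise ParameterError(f"unknown sensor location {self.sensor_location!r}")
        if self.sampling_rate_hz <= 0:
            raise ParameterError("sampling rate must be positive")
        if t.ndim != 1 or t.size < 2:
            raise DataError("recording needs at least 2 samples")
        if a.shape != (t.size, 3) or g.shape != (t.size, 3):
            raise DataError(
                f"accel/gyro must be T×3 matching time (T={t.size}), "
                f"got accel {a.shape}, gyro {g.shape}"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DataError("time vector must be strictly increasing")
        nominal = 1.0 / self.sampling_rate_hz
        if abs(np.median(dt) - nominal) > 0.05 * nominal:
            raise DataError(
                f"median sampling interval {np.median(dt):.6f}s deviates more than "
                f"5% from nominal {nominal:.6f}s"
            )

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def primary_accel(self) -> np.ndarray:
        """Movement channel used for segmentation (torso Z / thigh Y)."""
        return self.accel[:, 2] if self.sensor_location == "torso" else self.accel[:, 1]


@dataclass(frozen=True)
class CalibrationParams:
    """Ferraris-style sensor model: corrected = matrix · (raw − offset)."""

    accel_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    gyro_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        for name in ("accel_offset", "gyro_offset"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        for name in ("accel_matrix", "gyro_matrix"):
            m = np.asarray(getattr(self, name), dtype=float).reshape(3, 3)
            if abs(np.linalg.det(m)) < 1e-12:
                raise ParameterError(f"{name} is singular")
            object.__setattr__(self, name, m)

    @classmethod
    def neutral(cls) -> "CalibrationParams":
        return cls()


def read_recording(
    path,
    location: str,
    subject_id: str = "",
    trial_id: str = "",
    sampling_rate_hz: float = NOMINAL_RATE_HZ,
    accel_units: str = "m/s2",
    gyro_units: str = "deg/s",
) -> ImuRecording:
    """Read a delimited-text IMU trial into an :class:`ImuRecording`.

    The file is comma-separated with a header row; columns ``time_s`` (or
    ``time``), ``ax ay az gx gy gz``.  ``accel_units``/``gyro_units`` declare
    the on-disk units and are converted to m/s² and deg/s.
    """
    if accel_units not in ACCEL_UNIT_FACTORS:
        raise ParameterError(f"unknown accel units {accel_units!r}")
    if gyro_units not in GYRO_UNIT_FACTORS:
        raise ParameterError(f"unknown gyro units {gyro_units!r}")
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    time_col = cols.get("time_s") or cols.get("time")
    missing = [c for c in CSV_COLUMNS[1:] if c not in cols]
    if time_col is None:
        missing.insert(0, "time_s")
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    t = df[time_col].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    accel = df[[cols["ax"], cols["ay"], cols["az"]]].to_numpy(dtype=float)
    gyro = df[[cols["gx"], cols["gy"], cols["gz"]]].to_numpy(dtype=float)
    return ImuRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        sensor_location=location,
        sampling_rate_hz=sampling_rate_hz,
        time_s=t,
        accel=accel * ACCEL_UNIT_FACTORS[accel_units],
        gyro=gyro * GYRO_UNIT_FACTORS[gyro_units],
    )


def write_recording(rec: ImuRecording, path) -> None:
    """Write a recording in the CSV dialect read by :func:`read_recording`.

    Full float precision is preserved, so write -> read round-trips losslessly.
    """
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
            "gx": rec.gyro[:, 0],
            "gy": rec.gyro[:, 1],
            "gz": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12e")


def apply_calibration(rec: ImuRecording, cal: CalibrationParams) -> ImuRecording:
    """Apply the sensor model corrected = matrix · (raw − offset), per modality."""
    accel = (rec.accel - cal.accel_offset) @ cal.accel_matrix.T
    gyro = (rec.gyro - cal.gyro_offset) @ cal.gyro_matrix.T
    return replace(rec, accel=accel, gyro=gyro, history=rec.history + ("calibrate",))


def bandpass_filter(
    rec: ImuRecording,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> ImuRecording:
    """Zero-phase Butterworth band-pass of every accel and gyro channel.

    A 2nd-order design applied forward-backward (effective 4th order, zero
    phase) so that fiducial timing downstream is not skewed by filter delay.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got [{low_hz}, {high_hz}]"
        )
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate_hz, output="sos")
    # default sosfiltfilt padding; signal must exceed it
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if rec.n_samples <= padlen:
        raise DataError(
            f"signal of {rec.n_samples} samples is shorter than the filter "
            f"warm-up length ({padlen} samples)"
        )
    accel = sps.sosfiltfilt(sos, rec.accel, axis=0)
    gyro = sps.sosfiltfilt(sos, rec.gyro, axis=0)
    return replace(rec, accel=accel, gyro=gyro, history=rec.history + ("bandpass",))


def bandpass_gain(freq_hz, low_hz=DEFAULT_BAND_HZ[0], high_hz=DEFAULT_BAND_HZ[1],
                  fs=NOMINAL_RATE_HZ):
    """Magnitude response of the effective (forward-backward) band-pass filter."""
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(freq_hz) / fs)
    return np.abs(h) ** 2  # filtfilt applies the filter twice


def trim_settling(rec: ImuRecording, trim_s: float = DEFAULT_TRIM_S) -> ImuRecording:
    """Drop the first ``trim_s`` seconds (sensor settling) and re-reference time to 0."""
    if trim_s < 0:
        raise ParameterError("trim_s must be non-negative")
    if rec.duration_s <= trim_s:
        raise DataError(
            f"trial too short: duration {rec.duration_s:.3f}s <= trim {trim_s}s"
        )
    keep = rec.time_s >= rec.time_s[0] + trim_s
    t = rec.time_s[keep]
    return replace(
        rec,
        time_s=t - t[0],
        accel=rec.accel[keep],
        gyro=rec.gyro[keep],
        history=rec.history + ("trim",),
    )


def preprocess(
    rec: ImuRecording,
    cal: CalibrationParams | None = None,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    trim_s: float = DEFAULT_TRIM_S,
) -> ImuRecording:
    """Full preprocessing chain in the fixed order calibrate -> filter -> trim."""
    out = apply_calibration(rec, cal if cal is not None else CalibrationParams.neutral())
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    out = trim_settling(out, trim_s=trim_s)
    assert out.history[-3:] == ("calibrate", "bandpass", "trim")
    return out
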