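"""Per-trial movement features for the five-times sit-to-stand test.

The feature roster quantifies five aspects of test performance:

* **timing** — total test time and the mean/SD/coefficient-of-variation of
  the sit-stand-sit, rise, and descent durations;
* **endurance / stand speed** — mean and SD across cycles of the primary
  acceleration and angular-velocity values sampled at the fiducial times;
* **postural sway** — per-axis RMS of torso acceleration and angular
  velocity over the active part of the test (torso only: a thigh-mounted
  sensor cannot reasonably measure upper-body sway);
* **smoothness** — per-axis RMS of jerk (derivative of acceleration) and of
  angular acceleration (torso only);
* **complexity** — normalized spectral entropy of the acceleration channels.

The torso roster has exactly 38 named features, the thigh roster exactly 20.
Feature order and names are frozen under ``roster_version``
"reconstructed-v1"; the roster was reconstructed from the feature families
above under those fixed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ContractError, DataError, DegenerateInputError
from .segmentation import FiducialSet
from .signal_io import ImuRecording

ROSTER_VERSION = "reconstructed-v1"

_TIMING_NAMES = (
    "total_time",
    "n_cycles",
    "sss_time_mean",
    "sss_time_sd",
    "sss_time_cov",
    "rise_time_mean",
    "rise_time_sd",
    "rise_time_cov",
    "descent_time_mean",
    "descent_time_sd",
    "descent_time_cov",
)

_TORSO_FIDUCIAL_NAMES = tuple(
    f"{sig}_at_{fid}_{stat}"
    for sig in ("accel", "gyro")
    for fid in ("stand_start", "mid_stand", "sit_end")
    for stat in ("mean", "sd")
)

_THIGH_FIDUCIAL_NAMES = tuple(
    f"{sig}_at_{fid}_{stat}"
    for sig in ("accel", "gyro")
    for fid in ("stand_start", "mid_stand")
    for stat in ("mean", "sd")
)

_SWAY_NAMES = tuple(f"rms_accel_{ax}" for ax in "xyz") + tuple(
    f"rms_gyro_{ax}" for ax in "xyz"
)
_JERK_NAMES = tuple(f"rms_jerk_{ax}" for ax in "xyz") + tuple(
    f"rms_angular_accel_{ax}" for ax in "xyz"
)
_ENTROPY_TORSO = tuple(f"spectral_entropy_accel_{ax}" for ax in "xyz")
_ENTROPY_THIGH = ("spectral_entropy_accel_y",)

#: frozen feature order, torso: 11 timing + 12 fiducial + 6 RMS + 6 jerk + 3 entropy = 38
TORSO_ROSTER = _TIMING_NAMES + _TORSO_FIDUCIAL_NAMES + _SWAY_NAMES + _JERK_NAMES + _ENTROPY_TORSO
#: frozen feature order, thigh: 11 timing + 8 fiducial + 1 entropy = 20
THIGH_ROSTER = _TIMING_NAMES + _THIGH_FIDUCIAL_NAMES + _ENTROPY_THIGH

assert len(TORSO_ROSTER) == 38 and len(THIGH_ROSTER) == 20


@dataclass(frozen=True)
class FeatureVector:
    """Named scalar features for one trial, in frozen roster order."""

    sensor_location: str
    values: dict
    roster_version: str = ROSTER_VERSION
    #: per-trial metadata (e.g. which gyro axis was used as pitch)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        roster = TORSO_ROSTER if self.sensor_location == "torso" else THIGH_ROSTER
        if tuple(self.values) != roster:
            raise ContractError(
                f"{self.sensor_location} feature vector must carry exactly the "
                f"{len(roster)}-feature roster in order"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise DataError(f"non-finite features: {', '.join(bad)}")

    @property
    def names(self) -> tuple:
        return tuple(self.values)

    def to_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def _mean_sd_cov(durations: np.ndarray, prefix: str) -> dict:
    mean = float(np.mean(durations))
    sd = float(np.std(durations, ddof=1)) if durations.size > 1 else 0.0
    if abs(mean) < 1e-9:
        raise DegenerateInputError(f"{prefix} mean is ~0; CoV undefined")
    return {
        f"{prefix}_mean": mean,
        f"{prefix}_sd": sd,
        f"{prefix}_cov": sd / mean,
    }


def timing_features(fid: FiducialSet) -> dict:
    """Total time plus mean/SD/CoV of SSS, rise, and descent durations.

    SD and CoV are 0 by convention when only one cycle was detected.
    """
    if fid.n_cycles < 1:
        raise ContractError("empty fiducial set")
    ss = fid.times("stand_start")
    ms = fid.times("mid_stand")
    se = fid.times("sit_end")
    out = {
        "total_time": float(se[-1] - ss[0]),
        "n_cycles": float(fid.n_cycles),
    }
    out.update(_mean_sd_cov(se - ss, "sss_time"))
    out.update(_mean_sd_cov(ms - ss, "rise_time"))
    out.update(_mean_sd_cov(se - ms, "descent_time"))
    return out


def _active_window(rec: ImuRecording, fid: FiducialSet) -> np.ndarray:
    """Boolean mask for the active span: first stand-start to last sit-end."""
    t0 = fid.cycles[0].stand_start_s
    t1 = fid.cycles[-1].sit_end_s
    if t0 < rec.time_s[0] - 1e-9 or t1 > rec.time_s[-1] + 1e-9:
        raise ContractError("fiducials lie outside the recording span")
    return (rec.time_s >= t0) & (rec.time_s <= t1)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def sway_and_jerk_features(rec: ImuRecording, fid: FiducialSet) -> dict:
    """Per-axis RMS of acceleration/angular velocity and of their derivatives.

    Computed over the active window; derivatives by central differences on
    the recording's own time axis.  Torso only.
    """
    if rec.sensor_location != "torso":
        raise ContractError("sway and jerk features are defined for the torso sensor only")
    mask = _active_window(rec, fid)
    t = rec.time_s[mask]
    out = {}
    for name, sig in (("accel", rec.accel[mask]), ("gyro", rec.gyro[mask])):
        for j, ax in enumerate("xyz"):
            out[f"rms_{name}_{ax}"] = _rms(sig[:, j])
    for name, sig in (("jerk", rec.accel[mask]), ("angular_accel", rec.gyro[mask])):
        for j, ax in enumerate("xyz"):
            out[f"rms_{name}_{ax}"] = _rms(np.gradient(sig[:, j], t))
    return out


def spectral_entropy(channel: np.ndarray, fs: float) -> float:
    """Shannon entropy of the normalized power spectrum, scaled to [0, 1].

    Low for near-periodic movement (energy concentrated in few frequency
    bins), high for noise-like movement (flat spectrum).  The DC bin is
    excluded; band-passed signals carry no information there.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 64:
        raise DataError(f"spectral entropy needs >= 64 samples, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise DegenerateInputError("constant signal has no spectral entropy")
    _, psd = sps.periodogram(x, fs=fs, detrend="constant")
    psd = psd[1:]  # drop DC
    total = psd.sum()
    if total <= 0:
        raise DegenerateInputError("zero-power signal")
    p = psd / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(psd.size))


def pitch_axis(rec: ImuRecording, fid: FiducialSet) -> int:
    """Gyro axis carrying the sagittal rotation: maximal variance in the active window."""
    mask = _active_window(rec, fid)
    return int(np.argmax(np.var(rec.gyro[mask], axis=0)))


def fiducial_amplitude_features(rec: ImuRecording, fid: FiducialSet) -> dict:
    """Mean/SD across cycles of signal values sampled at the fiducial times.

    Signals: the primary acceleration channel (torso Z / thigh Y) and the
    pitch angular-velocity channel.  Torso uses all three fiducials; thigh
    uses stand-start and mid-stand.  Values at fiducial times are obtained
    by linear interpolation.  SDs are 0 by convention for a single cycle.
    """
    if fid.n_cycles < 1:
        raise ContractError("empty fiducial set")
    accel = rec.primary_accel
    gyro = rec.gyro[:, pitch_axis(rec, fid)]
    fiducials = (
        ("stand_start", "mid_stand", "sit_end")
        if rec.sensor_location == "torso"
        else ("stand_start", "mid_stand")
    )
    t0, t1 = rec.time_s[0], rec.time_s[-1]
    out = {}
    for sig_name, sig in (("accel", accel), ("gyro", gyro)):
        for f in fiducials:
            times = fid.times(f)
            if times.min() < t0 - 1e-9 or times.max() > t1 + 1e-9:
                raise ContractError(f"{f} fiducial outside recording span")
            vals = np.interp(times, rec.time_s, sig)
            out[f"{sig_name}_at_{f}_mean"] = float(np.mean(vals))
            out[f"{sig_name}_at_{f}_sd"] = (
                float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            )
    return out


def extract_features(rec: ImuRecording, fid: FiducialSet) -> FeatureVector:
    """Assemble the full location-specific roster for one segmented trial."""
    if rec.sensor_location != fid.source:
        raise ContractError(
            f"recording location {rec.sensor_location} != fiducial source {fid.source}"
        )
    values = dict(timing_features(fid))
    values.update(fiducial_amplitude_features(rec, fid))
    mask = _active_window(rec, fid)
    if rec.sensor_location == "torso":
        values.update(sway_and_jerk_features(rec, fid))
        for j, ax in enumerate("xyz"):
            values[f"spectral_entropy_accel_{ax}"] = spectral_entropy(
                rec.accel[mask, j], rec.sampling_rate_hz
            )
        roster = TORSO_ROSTER
    else:
        values["spectral_entropy_accel_y"] = spectral_entropy(
            rec.accel[mask, 1], rec.sampling_rate_hz
        )
        roster = THIGH_ROSTER
    ordered = {name: values[name] for name in roster}
    return FeatureVector(
        sensor_location=rec.sensor_location,
        values=ordered,
        meta={"pitch_axis": "xyz"[pitch_axis(rec, fid)]},
    )
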