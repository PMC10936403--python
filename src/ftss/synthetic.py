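"""Synthetic FTSS recordings and cohorts with known ground truth.

The clinical dataset behind this method is restricted, so every stage is
validated against simulation.  Two layers are provided:

* **signal level** — :func:`simulate_ftss_recording` builds one IMU trial
  whose primary channel is a train of smooth (Gaussian) pulses: for the
  torso Z axis a positive pulse at stand-start, a negative trough at
  mid-stand and a positive pulse at sit-end per cycle; for the thigh Y axis
  a dominant negative trough per cycle with positive seat-off /
  seat-contact deflections peaking at the scheduled stand-start and sit-end.
  Band-limited sway noise, quiet-sitting padding, and optional artifacts
  (spike, dropout, aborted half-rise) are added on top.  The scheduled
  fiducial times are returned as ground truth.
* **cohort level** — :func:`simulate_cohort` draws per-subject demographics
  and kinematic parameters, renders per-trial recordings for both sensor
  locations, and generates MMSE (Poisson, ceiling 30), BBS (Poisson,
  ceiling 56) and faller labels (logistic) from known coefficient vectors
  on the subjects' true kinematic characteristics.

Feature-level generators (:func:`make_classification_problem`,
:func:`make_poisson_problem`) bypass the signal layer and produce design
matrices with known coefficients for validating the model pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import brentq

from .cohort_stats import Cohort, SubjectRecord
from .errors import ParameterError
from .models import FORCED_FEATURE, DesignMatrix
from .segmentation import Cycle, FiducialSet
from .signal_io import NOMINAL_RATE_HZ, ImuRecording

#: deg/s of pitch angular velocity per m/s³ of primary-channel jerk
_GYRO_SCALE = 8.0


@dataclass(frozen=True)
class SynthesisConfig:
    """Kinematic parameters of one simulated FTSS trial.

    Defaults emulate a community-dwelling older adult performing the test
    briskly: five cycles of ~2.2 s, stand/sit acceleration peaks of
    2 m/s² on the torso (mid-stand troughs −1.5 m/s²), thigh mid-stand
    troughs of −3 m/s², and band-limited postural sway of 0.05 m/s² RMS.
    """

    n_cycles: int = 5
    cycle_duration_mean_s: float = 2.2
    cycle_duration_sd_s: float = 0.25
    rise_fraction: float = 0.45
    peak_accel: float = 2.0
    trough_accel: float = -1.5
    thigh_trough_accel: float = -3.0
    sway_noise_rms: float = 0.05
    pre_post_sit_s: float = 2.5
    pause_mean_s: float = 0.8
    pause_sd_s: float = 0.15
    sampling_rate_hz: float = NOMINAL_RATE_HZ
    #: None or {"type": "spike"|"dropout"|"aborted_rise", "magnitude": float}
    artifact: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.cycle_duration_mean_s <= 0 or self.pause_mean_s <= 0:
            raise ParameterError("durations must be positive")
        if not (self.trough_accel < 0 < self.peak_accel):
            raise ParameterError("need trough_accel < 0 < peak_accel")
        if not 0 < self.rise_fraction < 1:
            raise ParameterError("rise_fraction must be in (0, 1)")


def _band_limited_noise(rng, n: int, fs: float, rms: float) -> np.ndarray:
    """Postural-sway-like noise: white noise band-passed to 0.1–3 Hz at target RMS."""
    if rms <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 512)
    sos = sps.butter(2, [0.1, 3.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[256:256 + n]
    return x / max(np.sqrt(np.mean(x**2)), 1e-12) * rms


def _schedule(cfg: SynthesisConfig, rng) -> list:
    """Per-cycle (stand_start, mid_stand, sit_end, amplitudes) schedule."""
    cycles = []
    t = cfg.pre_post_sit_s
    for _ in range(cfg.n_cycles):
        dur = float(np.clip(
            rng.normal(cfg.cycle_duration_mean_s, cfg.cycle_duration_sd_s), 1.2, 4.0
        ))
        pause = float(np.clip(rng.normal(cfg.pause_mean_s, cfg.pause_sd_s), 0.55, 1.5))
        jit = rng.uniform(0.92, 1.08, size=3)
        # thigh troughs are tighter: their depth consistency is what the
        # 0.8·αy-min acceptance gate relies on in repeated sit-stands
        jit_thigh = rng.uniform(0.97, 1.03)
        cycles.append({
            "stand_start": t,
            "mid_stand": t + cfg.rise_fraction * dur,
            "sit_end": t + dur,
            "duration": dur,
            "amp_pos1": cfg.peak_accel * jit[0],
            "amp_neg": abs(cfg.trough_accel) * jit[1],
            "amp_pos2": cfg.peak_accel * jit[2],
            "amp_thigh": abs(cfg.thigh_trough_accel) * jit_thigh,
        })
        t += dur + pause
    return cycles


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _lobe_center(peak_t: float, mid_t: float, trough_amp: float,
                 trough_sigma: float, lobe_amp: float, lobe_sigma: float) -> float:
    """Lobe center such that lobe + trough peaks exactly at ``peak_t``.

    The trough's gradient at the flank would otherwise drag the rendered
    positive peak away from the scheduled fiducial; the center is nudged
    toward the trough so the sum's derivative vanishes at ``peak_t``.
    """
    trough_grad = (
        trough_amp * (peak_t - mid_t) / trough_sigma**2
        * np.exp(-0.5 * ((peak_t - mid_t) / trough_sigma) ** 2)
    )

    def total_grad(center: float) -> float:
        lobe_grad = (
            -lobe_amp * (peak_t - center) / lobe_sigma**2
            * np.exp(-0.5 * ((peak_t - center) / lobe_sigma) ** 2)
        )
        return lobe_grad + trough_grad

    side = 1.0 if peak_t < mid_t else -1.0  # nudge toward the trough
    lo, hi = sorted((peak_t, peak_t + side * lobe_sigma))
    if total_grad(lo) * total_grad(hi) > 0:
        return peak_t  # trough influence negligible at this geometry
    return float(brentq(total_grad, lo, hi, xtol=1e-10))


def simulate_ftss_recording(
    cfg: SynthesisConfig, location: str, subject_id: str = "sim", trial_id: str = "t0"
):
    """Simulate one raw FTSS trial; returns ``(ImuRecording, FiducialSet)``.

    The recording is *raw*: run it through the preprocessing chain
    (calibrate/filter/trim) before segmenting.  Ground-truth fiducial times
    are on the recording's own time axis; see :func:`preprocessed_truth`
    for the post-trim frame.
    """
    if location not in ("torso", "thigh"):
        raise ParameterError(f"unknown sensor location {location!r}")
    rng = np.random.default_rng(cfg.seed)
    schedule = _schedule(cfg, rng)
    t_end = schedule[-1]["sit_end"] + cfg.pre_post_sit_s
    fs = cfg.sampling_rate_hz
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) / fs

    # Pulse trains are built (near) zero-mean per cycle so the 0.01 Hz
    # high-pass of the preprocessing chain does not shift baselines or
    # redistribute trough depths.
    primary = np.zeros(n)
    for c in schedule:
        if location == "torso":
            # sharp stand-start / sit-end bursts, broader shallow mid-stand
            # trough; widths chosen so positive and negative areas cancel
            # while the third moment (skewness) stays positive
            w_pos = 0.07 * c["duration"]
            w_neg = 0.187 * c["duration"]
            c_ss = _lobe_center(c["stand_start"], c["mid_stand"], c["amp_neg"],
                                w_neg, c["amp_pos1"], w_pos)
            c_se = _lobe_center(c["sit_end"], c["mid_stand"], c["amp_neg"],
                                w_neg, c["amp_pos2"], w_pos)
            primary += c["amp_pos1"] * _gauss(t, c_ss, w_pos)
            primary -= c["amp_neg"] * _gauss(t, c["mid_stand"], w_neg)
            primary += c["amp_pos2"] * _gauss(t, c_se, w_pos)
        else:
            # dominant negative trough spanning the rise and descent, with
            # positive seat-off / seat-contact deflections peaking exactly
            # at stand-start and sit-end
            rise = c["mid_stand"] - c["stand_start"]
            descent = c["sit_end"] - c["mid_stand"]
            spread = np.sqrt(2.0 * np.log(1.0 / 0.1))
            sig_l, sig_r = rise / spread, descent / spread
            left = t <= c["mid_stand"]
            primary -= c["amp_thigh"] * np.where(
                left, _gauss(t, c["mid_stand"], sig_l), _gauss(t, c["mid_stand"], sig_r)
            )
            lobe = 0.45 * c["amp_thigh"]
            w_lobe = 0.14 * c["duration"]
            c_l = _lobe_center(c["stand_start"], c["mid_stand"], c["amp_thigh"],
                               sig_l, lobe, w_lobe)
            c_r = _lobe_center(c["sit_end"], c["mid_stand"], c["amp_thigh"],
                               sig_r, lobe, w_lobe)
            primary += lobe * _gauss(t, c_l, w_lobe)
            primary += lobe * _gauss(t, c_r, w_lobe)

    artifact = dict(cfg.artifact) if cfg.artifact else None
    if artifact and artifact["type"] == "aborted_rise" and len(schedule) > 1:
        # a half-amplitude attempt in the pause after the first cycle
        c0, c1 = schedule[0], schedule[1]
        center = 0.5 * (c0["sit_end"] + c1["stand_start"])
        frac = artifact.get("magnitude", 0.5)
        if location == "torso":
            primary -= frac * abs(cfg.trough_accel) * _gauss(t, center, 0.15)
        else:
            primary -= frac * abs(cfg.thigh_trough_accel) * _gauss(t, center, 0.2)

    noise = _band_limited_noise(rng, n, fs, cfg.sway_noise_rms)
    primary = primary + noise

    jerk = np.gradient(primary, t)
    pitch = _GYRO_SCALE * jerk + _band_limited_noise(rng, n, fs, 2.0)

    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    if location == "torso":
        accel[:, 2] = primary
        accel[:, 0] = _band_limited_noise(rng, n, fs, 0.6 * cfg.sway_noise_rms + 0.01)
        accel[:, 1] = _band_limited_noise(rng, n, fs, 0.4 * cfg.sway_noise_rms + 0.01)
    else:
        accel[:, 1] = primary
        accel[:, 0] = _band_limited_noise(rng, n, fs, 0.6 * cfg.sway_noise_rms + 0.01)
        accel[:, 2] = _band_limited_noise(rng, n, fs, 0.4 * cfg.sway_noise_rms + 0.01)
    gyro[:, 0] = pitch
    gyro[:, 1] = _band_limited_noise(rng, n, fs, 1.5)
    gyro[:, 2] = _band_limited_noise(rng, n, fs, 1.0)

    if artifact and artifact["type"] == "spike":
        idx = int(round(fs * schedule[0]["mid_stand"])) + int(rng.integers(5, 20))
        accel[idx, 2 if location == "torso" else 1] += artifact.get("magnitude", 2.5)
    if artifact and artifact["type"] == "dropout":
        start = int(round(fs * (schedule[0]["sit_end"] + 0.1)))
        width = int(round(fs * artifact.get("magnitude", 0.5)))
        keep = np.ones(n, dtype=bool)
        keep[start:start + width] = False
        t, accel, gyro = t[keep], accel[keep], gyro[keep]

    rec = ImuRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        sensor_location=location,
        sampling_rate_hz=fs,
        time_s=t,
        accel=accel,
        gyro=gyro,
    )
    truth = FiducialSet(
        tuple(
            Cycle(c["stand_start"], c["mid_stand"], c["sit_end"]) for c in schedule
        ),
        location,
    )
    return rec, truth


def preprocessed_truth(raw: ImuRecording, truth: FiducialSet, trim_s: float = 1.0) -> FiducialSet:
    """Ground-truth fiducials re-referenced to the post-trim time axis."""
    kept = raw.time_s[raw.time_s >= raw.time_s[0] + trim_s]
    return truth.shift(-float(kept[0]))


# ---------------------------------------------------------------------------
# cohort level


@dataclass(frozen=True)
class CohortConfig:
    """Population and outcome-generating model for a simulated cohort.

    Outcome scores are generated from linear predictors on the subjects'
    *true* (scheduled, noise-free) kinematic characteristics, z-scored
    across the cohort: MMSE ~ min(30, Poisson(exp(log 28 + eta))),
    BBS ~ min(56, Poisson(exp(log 52.9 + eta))), faller ~
    Bernoulli(sigmoid(logit(0.48) + eta)).  Coefficient keys refer to the
    true-characteristic names: ``total_time``, ``sway``, ``cycle_sd``.
    """

    n_subjects: int = 168
    n_trials: int = 3
    sex_ratio: float = 0.5  # fraction male
    n_home: int = 40  # first sub-study arm size
    mmse_coefficients: dict = field(
        default_factory=lambda: {"total_time": -0.02, "sway": -0.01}
    )
    bbs_coefficients: dict = field(
        default_factory=lambda: {"total_time": -0.05, "sway": -0.02}
    )
    falls_coefficients: dict = field(
        default_factory=lambda: {"total_time": 0.5, "sway": 0.3}
    )
    mmse_base: float = 28.0
    bbs_base: float = 52.9
    faller_base_rate: float = 0.48
    #: skip rendering IMU recordings (cohort-level studies that only need
    #: demographics, true characteristics, and outcomes)
    render_recordings: bool = True
    seed: int = 0


@dataclass(frozen=True)
class SimulatedCohort:
    cohort: Cohort
    #: (subject_id, trial_id, location) -> raw ImuRecording
    recordings: dict
    #: (subject_id, trial_id, location) -> ground-truth FiducialSet
    truths: dict
    #: per-subject true kinematic characteristics (z-scored columns end in _z)
    true_features: pd.DataFrame
    coefficients: dict


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 1e-12 else np.zeros_like(x)


def simulate_cohort(cfg: CohortConfig) -> SimulatedCohort:
    """Simulate a full cohort: demographics, recordings, and generated outcomes."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    sex = np.where(rng.random(n) < cfg.sex_ratio, "male", "female")
    age = rng.uniform(60, 90, n)
    height = np.where(sex == "male", rng.normal(173, 7, n), rng.normal(161, 6, n))
    weight = np.where(sex == "male", rng.normal(78, 11, n), rng.normal(68, 10, n))

    # subject-level kinematics; slower, more variable, swayier with age
    age_z = _zscore(age)
    dur_mean = np.clip(rng.normal(2.2, 0.3, n) + 0.15 * age_z, 1.5, 3.4)
    dur_sd = np.clip(rng.normal(0.22, 0.06, n), 0.08, 0.45)
    sway = np.clip(rng.normal(0.05, 0.015, n) + 0.005 * age_z, 0.02, 0.12)
    pause_mean = np.clip(rng.normal(0.8, 0.1, n), 0.6, 1.2)

    total_time_true = 5 * dur_mean + 4 * pause_mean
    true = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "total_time": total_time_true,
        "sway": sway,
        "cycle_sd": dur_sd,
    })
    zcols = {}
    for name in ("total_time", "sway", "cycle_sd"):
        zcols[name] = _zscore(true[name].to_numpy())
        true[name + "_z"] = zcols[name]

    def eta(coefs: dict) -> np.ndarray:
        out = np.zeros(n)
        for name, c in coefs.items():
            if name not in zcols:
                raise ParameterError(f"unknown true-characteristic name {name!r}")
            out += c * zcols[name]
        return out

    mmse = np.minimum(30, rng.poisson(np.exp(np.log(cfg.mmse_base) + eta(cfg.mmse_coefficients))))
    bbs = np.minimum(56, rng.poisson(np.exp(np.log(cfg.bbs_base) + eta(cfg.bbs_coefficients))))
    logit_base = np.log(cfg.faller_base_rate / (1 - cfg.faller_base_rate))
    p_fall = 1.0 / (1.0 + np.exp(-(logit_base + eta(cfg.falls_coefficients))))
    faller = rng.random(n) < p_fall
    # falls history consistent with the faller definition
    falls_12mo = np.where(faller, 2 + rng.poisson(0.5, n), rng.integers(0, 2, n))
    injurious = np.zeros(n, dtype=bool)
    single_inj = faller & (rng.random(n) < 0.3)
    falls_12mo = np.where(single_inj, 1, falls_12mo)
    injurious |= single_inj

    subjects = [
        SubjectRecord(
            subject_id=f"S{i:03d}",
            age=float(age[i]),
            sex=str(sex[i]),
            height_cm=float(height[i]),
            weight_kg=float(weight[i]),
            mmse=int(mmse[i]),
            bbs=int(bbs[i]),
            falls_12mo=int(falls_12mo[i]),
            injurious_fall=bool(injurious[i]),
            arm="home" if i < cfg.n_home else "clinic",
        )
        for i in range(n)
    ]

    recordings, truths = {}, {}
    seeds = rng.integers(0, 2**31 - 1, size=(n, cfg.n_trials))
    for i in range(n if cfg.render_recordings else 0):
        for k in range(cfg.n_trials):
            trial_cfg = SynthesisConfig(
                cycle_duration_mean_s=float(dur_mean[i]),
                cycle_duration_sd_s=float(dur_sd[i]),
                sway_noise_rms=float(sway[i]),
                pause_mean_s=float(pause_mean[i]),
                seed=int(seeds[i, k]),
            )
            for loc in ("torso", "thigh"):
                rec, tr = simulate_ftss_recording(
                    trial_cfg, loc, subject_id=f"S{i:03d}", trial_id=f"t{k}"
                )
                recordings[(f"S{i:03d}", f"t{k}", loc)] = rec
                truths[(f"S{i:03d}", f"t{k}", loc)] = tr

    return SimulatedCohort(
        cohort=Cohort(subjects),
        recordings=recordings,
        truths=truths,
        true_features=true,
        coefficients={
            "mmse": dict(cfg.mmse_coefficients),
            "bbs": dict(cfg.bbs_coefficients),
            "falls": dict(cfg.falls_coefficients),
        },
    )


# ---------------------------------------------------------------------------
# feature-level generators for model validation


def _design_from_matrix(X: np.ndarray, names) -> DesignMatrix:
    ids = [f"S{i:03d}" for i in range(X.shape[0])]
    return DesignMatrix(frame=pd.DataFrame(X, index=pd.Index(ids, name="subject_id"),
                                           columns=list(names)))


def make_classification_problem(
    n: int, n_features: int, coefficients: dict | None = None, seed: int = 0
):
    """Design matrix with standard-normal columns and Bernoulli labels.

    ``coefficients`` maps column names to log-odds per SD; the first column
    is named ``total_time`` so the forced-inclusion constraint can be
    exercised.  Returns ``(DesignMatrix, y, true_coefficients)``.
    """
    rng = np.random.default_rng(seed)
    names = [FORCED_FEATURE] + [f"f{j:02d}" for j in range(1, n_features)]
    X = rng.standard_normal((n, n_features))
    beta = np.zeros(n_features)
    for name, c in (coefficients or {}).items():
        beta[names.index(name)] = c
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(float)
    return _design_from_matrix(X, names), y, dict(zip(names, beta))


def make_poisson_problem(
    n: int, n_features: int, coefficients: dict | None = None,
    intercept: float = np.log(20.0), seed: int = 0
):
    """Design matrix with standard-normal columns and Poisson counts.

    Returns ``(DesignMatrix, y, true_coefficients)``; coefficient units are
    log-rate per SD of the predictor.
    """
    rng = np.random.default_rng(seed)
    names = [FORCED_FEATURE] + [f"f{j:02d}" for j in range(1, n_features)]
    X = rng.standard_normal((n, n_features))
    beta = np.zeros(n_features)
    for name, c in (coefficients or {}).items():
        beta[names.index(name)] = c
    y = rng.poisson(np.exp(intercept + X @ beta)).astype(float)
    return _design_from_matrix(X, names), y, dict(zip(names, beta))
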