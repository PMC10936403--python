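"""Fiducial-point detection for the five-times sit-to-stand test.

Each sit-stand-sit (SSS) cycle is bounded by a *stand-start* and a *sit-end*
with a *mid-stand* in between.  Two detectors are provided:

* **torso** — adaptive peak detection on the Z-axis (anteroposterior)
  acceleration.  Positive peaks above ``0.4·αz_max`` mark stand-start /
  sit-end, negative peaks below ``0.5·αz_min`` mark mid-stand, where
  ``αz_max``/``αz_min`` are the trial's own extreme accelerations — the
  thresholds adapt to each trial, making detection invariant to overall
  signal scale.
* **thigh** — peak detection on the Y-axis (femoral) acceleration.  The
  global minimum ``αy_min`` sets the acceptance gate: only local minima
  with acceleration below ``0.8·αy_min`` count as successful mid-stands;
  stand-start and sit-end are the movement onset/offset around each
  mid-stand.

Both detectors refuse recordings that fail the signal-validity gate
(spikes, wrong mounting orientation, dropped samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as spstats

from .errors import ContractError, ParameterError, SegmentationError
from .signal_io import ImuRecording


@dataclass(frozen=True)
class Cycle:
    """One sit-stand-sit cycle, times in seconds on the recording's axis."""

    stand_start_s: float
    mid_stand_s: float
    sit_end_s: float

    def __post_init__(self):
        if not self.stand_start_s < self.mid_stand_s < self.sit_end_s:
            raise ParameterError(
                f"cycle fiducials out of order: {self.stand_start_s}, "
                f"{self.mid_stand_s}, {self.sit_end_s}"
            )


@dataclass(frozen=True)
class FiducialSet:
    """Ordered, non-overlapping SSS cycles detected in one trial."""

    cycles: tuple
    source: str

    def __post_init__(self):
        object.__setattr__(self, "cycles", tuple(self.cycles))
        for prev, cur in zip(self.cycles, self.cycles[1:]):
            if prev.sit_end_s > cur.stand_start_s + 1e-12:
                raise ParameterError("cycles overlap or are out of order")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def shift(self, dt: float) -> "FiducialSet":
        """Translate all fiducial times by ``dt`` (e.g. after trimming)."""
        return FiducialSet(
            tuple(
                Cycle(c.stand_start_s + dt, c.mid_stand_s + dt, c.sit_end_s + dt)
                for c in self.cycles
            ),
            self.source,
        )

    def times(self, which: str) -> np.ndarray:
        return np.array([getattr(c, which + "_s") for c in self.cycles])

    def to_json(self) -> str:
        return json.dumps(
            {
                "source": self.source,
                "n_cycles": self.n_cycles,
                "cycles": [
                    {
                        "stand_start_s": c.stand_start_s,
                        "mid_stand_s": c.mid_stand_s,
                        "sit_end_s": c.sit_end_s,
                    }
                    for c in self.cycles
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FiducialSet":
        d = json.loads(text)
        return cls(
            tuple(
                Cycle(c["stand_start_s"], c["mid_stand_s"], c["sit_end_s"])
                for c in d["cycles"]
            ),
            d["source"],
        )


@dataclass(frozen=True)
class ValidityReport:
    spike_pass: bool
    spike_count: int
    orientation_pass: bool
    skewness: float
    dropout_pass: bool
    max_gap_samples: float

    @property
    def overall(self) -> bool:
        return self.spike_pass and self.orientation_pass and self.dropout_pass


@dataclass(frozen=True)
class PeakDetectionParams:
    """Adaptive thresholds, as fractions of the trial's own extreme accelerations."""

    pos_threshold_frac: float = 0.4
    neg_threshold_frac: float = 0.5
    thigh_midstand_frac: float = 0.8
    #: refractory period between same-sign peaks; physiological lower bound
    #: on an SSS phase duration
    min_cycle_separation_s: float = 0.5
    #: thigh stand-start / sit-end flank peaks must exceed this fraction of |αy_min|
    thigh_flank_frac: float = 0.2

    def __post_init__(self):
        for name in ("pos_threshold_frac", "neg_threshold_frac", "thigh_midstand_frac", "thigh_flank_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.min_cycle_separation_s <= 0:
            raise ParameterError("min_cycle_separation_s must be positive")


# ---------------------------------------------------------------------------
# validity checks


def check_validity(rec: ImuRecording) -> ValidityReport:
    """Gate a preprocessed recording on spikes, mounting orientation, and dropouts.

    * spike check: samples of the primary channel whose residual against a
      5-sample median filter exceeds 10× the MAD of those residuals are
      movement artifacts (genuine sit-to-stand peaks are smooth at 102.4 Hz
      and survive the median filter; single-sample spikes do not).
    * orientation check: skewness of the primary channel must have the sign
      implied by correct mounting — positive for torso Z (stand/sit peaks
      dominate), negative for thigh Y (mid-stand troughs dominate).
    * dropout check: no inter-sample gap longer than 3 nominal intervals.
    """
    x = rec.primary_accel
    resid = x - ndimage.median_filter(x, size=5, mode="nearest")
    resid = resid - np.median(resid)
    mad = np.median(np.abs(resid))
    # amplitude floor: genuine movement is smooth at 102.4 Hz, so its
    # median-filter residual never approaches 5% of the signal range
    bound = max(10.0 * mad, 0.05 * np.ptp(x), 1e-12)
    spikes = int(np.sum(np.abs(resid) > bound))

    skew = float(spstats.skew(x))
    expected_positive = rec.sensor_location == "torso"
    orient_ok = skew > 0 if expected_positive else skew < 0

    gaps = np.diff(rec.time_s) * rec.sampling_rate_hz
    max_gap = float(gaps.max())

    return ValidityReport(
        spike_pass=spikes == 0,
        spike_count=spikes,
        orientation_pass=orient_ok,
        skewness=skew,
        dropout_pass=max_gap <= 3.0,
        max_gap_samples=max_gap,
    )


# ---------------------------------------------------------------------------
# peak primitives


def _threshold_peaks(x: np.ndarray, fs: float, threshold: float, min_sep_s: float) -> np.ndarray:
    """Indices of local maxima of ``x`` above ``threshold`` (threshold > 0).

    Each contiguous supra-threshold region contributes its extremum: from the
    threshold crossing the search steps back/forward to where the derivative
    changes sign, i.e. the region argmax (earliest sample on ties).  Peaks
    closer than ``min_sep_s`` are merged, keeping the larger.
    """
    above = x > threshold
    if not above.any():
        return np.array([], dtype=int)
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    regions = np.split(idx, splits + 1)
    peaks = [int(r[np.argmax(x[r])]) for r in regions]

    # refractory merge: keep the larger of any pair closer than min_sep_s
    min_sep = int(round(min_sep_s * fs))
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < min_sep:
            if x[p] > x[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return np.asarray(merged, dtype=int)


def _require_valid(rec: ImuRecording, expected_location: str) -> None:
    if rec.sensor_location != expected_location:
        raise ContractError(
            f"expected a {expected_location} recording, got {rec.sensor_location}"
        )
    report = check_validity(rec)
    if not report.overall:
        failed = [
            name
            for name, ok in (
                ("spike", report.spike_pass),
                ("orientation", report.orientation_pass),
                ("dropout", report.dropout_pass),
            )
            if not ok
        ]
        raise SegmentationError(
            f"recording refused: validity checks failed ({', '.join(failed)})"
        )


# ---------------------------------------------------------------------------
# torso detector


def segment_torso(
    rec: ImuRecording, params: PeakDetectionParams = PeakDetectionParams()
) -> FiducialSet:
    """Adaptive peak detection on torso Z-axis acceleration.

    Positive peaks above ``pos_threshold_frac·max(αz)`` are stand-start /
    sit-end candidates; negative peaks below ``neg_threshold_frac·min(αz)``
    are mid-stand candidates.  Alternation is enforced by keeping, between
    each adjacent pair of positive peaks, only the deepest negative peak;
    the positive peak immediately preceding a mid-stand is its stand-start
    and the one immediately following is its sit-end (a positive peak may be
    shared as sit-end of one cycle and stand-start of the next).
    """
    _require_valid(rec, "torso")
    z = rec.accel[:, 2]
    t = rec.time_s
    fs = rec.sampling_rate_hz
    z_max, z_min = float(z.max()), float(z.min())
    if z_max <= 0 or z_min >= 0:
        raise SegmentationError("no sit-to-stand transitions found (signal lacks both signs)")
    thr_pos = params.pos_threshold_frac * z_max
    thr_neg = params.neg_threshold_frac * z_min  # negative number

    pos = _threshold_peaks(z, fs, thr_pos, params.min_cycle_separation_s)
    neg = _threshold_peaks(-z, fs, -thr_neg, params.min_cycle_separation_s)
    if pos.size < 2 or neg.size == 0:
        raise SegmentationError("no sit-to-stand transitions found")

    cycles = []
    for a, b in zip(pos[:-1], pos[1:]):
        between = neg[(neg > a) & (neg < b)]
        if between.size == 0:
            continue
        mid = int(between[np.argmin(z[between])])  # deepest mid-stand candidate
        cycles.append(Cycle(float(t[a]), float(t[mid]), float(t[b])))
    if not cycles:
        raise SegmentationError("no sit-to-stand transitions found")
    return FiducialSet(tuple(cycles), "torso")


# ---------------------------------------------------------------------------
# thigh detector


def segment_thigh(
    rec: ImuRecording, params: PeakDetectionParams = PeakDetectionParams()
) -> FiducialSet:
    """Peak detection on thigh Y-axis (femoral) acceleration.

    The global minimum ``αy_min`` over the trial gates acceptance: local
    minima with acceleration below ``thigh_midstand_frac·αy_min`` are
    successful mid-stands; weaker dips (aborted or partial rises) are
    rejected.  Stand-start / sit-end are the positive seat-off /
    seat-contact deflections enclosing each mid-stand: the nearest positive
    peaks above ``thigh_flank_frac·|αy_min|`` before and after the trough
    (a band-passed femoral signal is near zero-mean, so these flank peaks
    are the robust movement boundaries).
    """
    _require_valid(rec, "thigh")
    y = rec.accel[:, 1]
    t = rec.time_s
    fs = rec.sampling_rate_hz
    y_min = float(y.min())
    if y_min >= 0:
        raise SegmentationError("no sit-to-stand transitions found (no negative trough)")
    gate = params.thigh_midstand_frac * y_min  # negative acceptance level
    mids = _threshold_peaks(-y, fs, -gate, params.min_cycle_separation_s)
    if mids.size == 0:
        raise SegmentationError("no sit-to-stand transitions found")

    flank_thr = params.thigh_flank_frac * abs(y_min)
    flanks = _threshold_peaks(y, fs, flank_thr, params.min_cycle_separation_s)

    cycles = []
    for mid in mids:
        before = flanks[flanks < mid]
        after = flanks[flanks > mid]
        if before.size == 0 or after.size == 0:
            continue  # movement runs off the edge of the recording
        start, end = int(before[-1]), int(after[0])
        cycles.append(Cycle(float(t[start]), float(t[mid]), float(t[end])))
    if not cycles:
        raise SegmentationError("no sit-to-stand transitions found")
    return FiducialSet(tuple(cycles), "thigh")


def segment(rec: ImuRecording, params: PeakDetectionParams = PeakDetectionParams()) -> FiducialSet:
    """Dispatch to the detector matching the recording's sensor location."""
    if rec.sensor_location == "torso":
        return segment_torso(rec, params)
    return segment_thigh(rec, params)
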