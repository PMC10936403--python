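import numpy as np
import pytest
from dataclasses import replace

from ftss import (
    Cycle,
    FiducialSet,
    ImuRecording,
    ParameterError,
    PeakDetectionParams,
    SegmentationError,
    SynthesisConfig,
    check_validity,
    preprocess,
    preprocessed_truth,
    segment,
    segment_thigh,
    segment_torso,
    simulate_ftss_recording,
)
from ftss.errors import ContractError


class TestValidity:
    @pytest.mark.parametrize("loc", ["torso", "thigh"])
    def test_clean_recording_passes(self, loc):
        raw, _ = simulate_ftss_recording(SynthesisConfig(seed=4), loc)
        assert check_validity(preprocess(raw)).overall

    def test_single_spike_flagged(self):
        cfg = SynthesisConfig(seed=4, artifact={"type": "spike", "magnitude": 2.5})
        raw, _ = simulate_ftss_recording(cfg, "torso")
        report = check_validity(raw)
        assert not report.spike_pass
        assert report.spike_count == 1

    def test_timestamp_gap_flagged(self):
        cfg = SynthesisConfig(seed=4, artifact={"type": "dropout", "magnitude": 0.5})
        raw, _ = simulate_ftss_recording(cfg, "torso")
        report = check_validity(raw)
        assert not report.dropout_pass
        assert report.max_gap_samples > 3

    @pytest.mark.parametrize("loc", ["torso", "thigh"])
    def test_inverted_mounting_fails_orientation(self, loc):
        raw, _ = simulate_ftss_recording(SynthesisConfig(seed=4), loc)
        rec = preprocess(raw)
        flipped = replace(rec, accel=-rec.accel)
        assert not check_validity(flipped).orientation_pass

    def test_overall_is_conjunction(self):
        raw, _ = simulate_ftss_recording(
            SynthesisConfig(seed=4, artifact={"type": "spike", "magnitude": 2.5}), "torso"
        )
        report = check_validity(raw)
        assert report.overall == (
            report.spike_pass and report.orientation_pass and report.dropout_pass
        )


class TestTorso:
    def test_five_clean_cycles_recovered(self, torso_trial):
        raw, rec, truth = torso_trial
        fid = segment_torso(rec)
        assert fid.n_cycles == truth.n_cycles == 5
        for which in ("stand_start", "mid_stand", "sit_end"):
            np.testing.assert_allclose(fid.times(which), truth.times(which), atol=0.10)

    def test_thresholds_are_fractions_of_trial_extremes(self, torso_segmented):
        rec, fid = torso_segmented
        z, t = rec.accel[:, 2], rec.time_s
        thr_pos, thr_neg = 0.4 * z.max(), 0.5 * z.min()
        for which in ("stand_start", "sit_end"):
            assert np.all(np.interp(fid.times(which), t, z) >= thr_pos)
        assert np.all(np.interp(fid.times("mid_stand"), t, z) <= thr_neg)

    def test_all_zero_signal_raises(self):
        t = np.arange(2048) / 102.4
        rec = ImuRecording("s", "t", "torso", 102.4, t, np.zeros((t.size, 3)),
                           np.zeros((t.size, 3)))
        with pytest.raises(SegmentationError):
            segment_torso(rec)

    def test_validity_failure_refused(self):
        cfg = SynthesisConfig(seed=4, artifact={"type": "spike", "magnitude": 2.5})
        raw, _ = simulate_ftss_recording(cfg, "torso")
        with pytest.raises(SegmentationError, match="validity"):
            segment_torso(raw)

    def test_wrong_sensor_refused(self, thigh_trial):
        _, rec, _ = thigh_trial
        with pytest.raises(ContractError):
            segment_torso(rec)


class TestThigh:
    def test_five_clean_cycles_recovered(self, thigh_trial):
        raw, rec, truth = thigh_trial
        fid = segment_thigh(rec)
        assert fid.n_cycles == truth.n_cycles == 5

    def test_midstand_acceptance_gate(self, thigh_segmented):
        rec, fid = thigh_segmented
        y, t = rec.accel[:, 1], rec.time_s
        gate = 0.8 * y.min()
        assert np.all(np.interp(fid.times("mid_stand"), t, y) < gate)

    def test_aborted_half_rise_rejected(self):
        cfg = SynthesisConfig(seed=4, n_cycles=5,
                              artifact={"type": "aborted_rise", "magnitude": 0.5})
        raw, truth = simulate_ftss_recording(cfg, "thigh")
        fid = segment_thigh(preprocess(raw))
        assert truth.n_cycles == 5
        assert fid.n_cycles == 5  # the 6th, half-amplitude attempt is rejected


class TestInvariances:
    @pytest.mark.parametrize("scale", [0.25, 3.0, 17.5])
    @pytest.mark.parametrize("loc", ["torso", "thigh"])
    def test_scale_invariance(self, loc, scale, torso_trial, thigh_trial):
        _, rec, _ = torso_trial if loc == "torso" else thigh_trial
        fid = segment(rec)
        scaled = replace(rec, accel=scale * rec.accel, gyro=scale * rec.gyro)
        fid2 = segment(scaled)
        assert fid2.n_cycles == fid.n_cycles
        for which in ("stand_start", "mid_stand", "sit_end"):
            np.testing.assert_array_equal(fid2.times(which), fid.times(which))

    @pytest.mark.parametrize("loc", ["torso", "thigh"])
    def test_time_shift_equivariance(self, loc, torso_trial, thigh_trial):
        _, rec, _ = torso_trial if loc == "torso" else thigh_trial
        fid = segment(rec)
        delta = 3.75
        shifted = replace(rec, time_s=rec.time_s + delta)
        fid2 = segment(shifted)
        for which in ("stand_start", "mid_stand", "sit_end"):
            np.testing.assert_allclose(fid2.times(which), fid.times(which) + delta,
                                       atol=1e-9)

    def test_cycles_ordered_and_non_overlapping(self):
        for seed in range(20, 40):
            cfg = SynthesisConfig(seed=seed, n_cycles=3 + seed % 6)
            for loc in ("torso", "thigh"):
                raw, _ = simulate_ftss_recording(cfg, loc)
                fid = segment(preprocess(raw))
                for c in fid.cycles:
                    assert c.stand_start_s < c.mid_stand_s < c.sit_end_s
                for a, b in zip(fid.cycles, fid.cycles[1:]):
                    assert a.sit_end_s <= b.stand_start_s


class TestNoiseRobustness:
    def test_recovery_under_sway_noise(self):
        """Cycle counts survive sway noise with amplitude up to 25% of the peak."""
        total = ok = 0
        for loc in ("torso", "thigh"):
            for frac in (0.05, 0.10, 0.15, 0.20, 0.25):
                rms = frac * 2.0 / 3  # noise amplitude ~ 3x RMS
                for seed in range(1, 11):
                    cfg = SynthesisConfig(seed=seed, n_cycles=3 + seed % 6,
                                          sway_noise_rms=rms)
                    raw, truth = simulate_ftss_recording(cfg, loc)
                    total += 1
                    try:
                        rec = preprocess(raw)
                        if check_validity(rec).overall and \
                                segment(rec).n_cycles == truth.n_cycles:
                            ok += 1
                    except SegmentationError:
                        pass
        assert ok / total >= 0.95


class TestDomainTypes:
    def test_cycle_ordering_enforced(self):
        with pytest.raises(ParameterError):
            Cycle(2.0, 1.0, 3.0)

    def test_overlapping_cycles_rejected(self):
        with pytest.raises(ParameterError):
            FiducialSet((Cycle(0, 1, 2), Cycle(1.5, 2.5, 3.5)), "torso")

    def test_fiducial_json_roundtrip(self, torso_segmented):
        _, fid = torso_segmented
        back = FiducialSet.from_json(fid.to_json())
        assert back == fid

    def test_threshold_fractions_validated(self):
        with pytest.raises(ParameterError):
            PeakDetectionParams(pos_threshold_frac=1.5)


def test_ground_truth_shift_matches_trim(torso_trial):
    raw, rec, truth = torso_trial
    # truth was shifted into the trimmed frame; all fiducials lie in-span
    assert truth.cycles[0].stand_start_s > 0
    assert truth.cycles[-1].sit_end_s < rec.time_s[-1]
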