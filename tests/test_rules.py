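"""ST/J measurement rules: fiducials, reference line, thresholds, episodes."""

import numpy as np
import pytest

from stholter.rules import (BeatFiducials, beats_from_mask, classify,
                            classify_series, deviations, episodes, irl,
                            st_offset_ms, st_point, ste_threshold_mv)
from stholter.synth import (CQRS, NOQRS, NQRS, ParameterError,
                            generate_clean_ecg, label_quality)


class TestBeatsFromMask:
    def test_two_runs_give_rr_heart_rate(self):
        mask = np.zeros(1200, dtype=int)
        mask[100:161] = CQRS
        mask[600:661] = CQRS
        beats = beats_from_mask(mask, fs=500)
        assert [b.q_onset for b in beats] == [100, 600]
        assert [b.j_point for b in beats] == [160, 660]
        assert beats[0].hr == pytest.approx(60.0)
        assert beats[1].hr is None

    def test_all_background_mask_yields_no_beats(self):
        assert beats_from_mask(np.zeros(500, dtype=int), fs=500) == []

    def test_majority_nqrs_run_is_nqrs(self):
        mask = np.zeros(300, dtype=int)
        mask[50:100] = CQRS
        mask[50:80] = NQRS  # 30/50 = 60% noisy
        beats = beats_from_mask(mask, fs=500)
        assert beats[0].quality == "NQRS"

    def test_sub_20ms_runs_discarded(self):
        mask = np.zeros(500, dtype=int)
        mask[100:105] = CQRS  # 10 ms at 500 Hz
        mask[300:350] = CQRS
        beats = beats_from_mask(mask, fs=500)
        assert [b.q_onset for b in beats] == [300]


class TestIsoelectricReference:
    def test_midpoint_of_two_onset_amplitudes(self):
        beats = [BeatFiducials(10, 50, "CQRS", 60.0),
                 BeatFiducials(500, 540, "CQRS", None)]
        sig = np.zeros(1000)
        sig[10], sig[500] = 0.02, 0.04
        assert irl(beats, 0, sig) == pytest.approx(0.03)

    def test_constant_baseline_recovered(self):
        beats = [BeatFiducials(10, 50, "CQRS", 60.0),
                 BeatFiducials(500, 540, "CQRS", None)]
        assert irl(beats, 0, np.full(1000, 0.07)) == pytest.approx(0.07)

    def test_last_beat_and_nqrs_neighbor_are_undefined(self):
        beats = [BeatFiducials(10, 50, "CQRS", 60.0),
                 BeatFiducials(500, 540, "NQRS", None)]
        sig = np.zeros(1000)
        assert np.isnan(irl(beats, 0, sig))
        assert np.isnan(irl(beats, 1, sig))

    def test_matches_generator_baseline_on_clean_record(self):
        rec, gt = generate_clean_ecg(n_beats=8, seed=4, baseline=0.05)
        _, mask = label_quality(gt, np.zeros(rec.n_samples), gt.fs)
        beats = beats_from_mask(mask, gt.fs)
        for i in range(len(beats) - 1):
            assert irl(beats, i, rec.lead("II")) == pytest.approx(0.05,
                                                                  abs=0.005)


class TestStPoint:
    @pytest.mark.parametrize("hr,offset_ms", [
        (70, 80), (99.99, 80),
        (100, 72), (105, 72), (109.9, 72),
        (110, 64), (119.9, 64),
        (120, 60), (180, 60),
    ])
    def test_hr_adjusted_offsets_with_boundary_inclusivity(self, hr, offset_ms):
        assert st_offset_ms(hr) == offset_ms

    def test_index_arithmetic_at_500hz(self):
        assert st_point(1000, 70, 500) == 1040
        assert st_point(1000, 105, 500) == 1036

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ParameterError):
            st_offset_ms(0)


class TestDeviations:
    def test_flat_signal_all_zero(self):
        beats = [BeatFiducials(100 + 400 * i, 140 + 400 * i, "CQRS",
                               75.0 if i < 3 else None) for i in range(4)]
        sig = np.zeros((2000, 2))
        series = deviations(beats, sig, ("II", "III"), fs=500)
        assert np.all(series.st_dev[series.valid] == 0.0)
        assert np.all(series.j_dev[series.valid] == 0.0)

    def test_recovers_injected_inferior_depression(self):
        inj = {"II": -0.08, "III": -0.08, "aVF": -0.08}
        rec, gt = generate_clean_ecg(n_beats=10, seed=6, st_injection=inj)
        _, mask = label_quality(gt, np.zeros(rec.n_samples), gt.fs)
        beats = beats_from_mask(mask, gt.fs)
        series = deviations(beats, rec.signal, rec.lead_names, gt.fs)
        assert series.valid.sum() >= 8
        for lead in ("II", "III", "aVF"):
            li = series.lead_names.index(lead)
            vals = series.st_dev[series.valid, li]
            np.testing.assert_allclose(vals, -0.08, atol=0.01)

    def test_nqrs_beats_are_culled(self):
        beats = [BeatFiducials(100, 140, "CQRS", 75.0),
                 BeatFiducials(500, 540, "NQRS", 75.0),
                 BeatFiducials(900, 940, "CQRS", None)]
        series = deviations(beats, np.zeros((2000, 1)), ("II",), fs=500)
        assert not series.valid[1]
        # neighbor of an NQRS beat has no valid reference either
        assert not series.valid[0]


class TestClassify:
    def test_demographic_ste_thresholds_in_v2_v3(self):
        assert ste_threshold_mv("V2", 30, "male") == 0.25
        assert ste_threshold_mv("V3", 45, "male") == 0.20
        assert ste_threshold_mv("V2", 70, "female") == 0.15
        assert ste_threshold_mv("II", 30, "male") == 0.10

    def test_v2_v3_elevation_flags_septal_for_older_male(self):
        flags = classify({}, {"V2": 0.21, "V3": 0.21}, age=45, sex="male")
        assert ("STE", "septal") in flags
        assert not classify({}, {"V2": 0.19, "V3": 0.19}, age=45, sex="male")

    def test_std_needs_two_contiguous_leads(self):
        assert ("STD", "inferior") in classify({"II": -0.06, "III": -0.06}, {},
                                               45, "male")
        assert ("STD", "inferior") not in classify({"II": -0.06}, {},
                                                   45, "male")

    def test_avr_group_triggers_on_its_single_lead(self):
        assert ("STD", "aVR") in classify({"aVR": -0.05}, {}, 45, "male")

    def test_j_elevation_excludes_v2_v3(self):
        flags = classify({}, {"I": 0.12, "aVL": 0.12}, 45, "male")
        assert ("J_ELEV", "lateral") in flags
        # V2 alone cannot contribute to J elevation; V1 alone is insufficient
        flags = classify({}, {"V1": 0.12, "V2": 0.12}, 45, "male")
        assert ("J_ELEV", "septal") not in flags

    def test_all_zero_deviations_flag_nothing(self):
        st0 = {l: 0.0 for l in ("I", "II", "III")}
        assert classify(st0, dict(st0), 45, "male") == set()

    def test_missing_demographics_rejected_when_v2_v3_needed(self):
        with pytest.raises(ParameterError):
            classify({}, {"V2": 0.3, "V3": 0.3})

    def test_monotone_in_deviation_magnitude(self):
        base_flags = classify({"II": -0.06, "III": -0.06}, {}, 45, "male")
        deeper = classify({"II": -0.30, "III": -0.30}, {}, 45, "male")
        assert base_flags <= deeper


class TestEpisodes:
    @staticmethod
    def _flag_train(duration_s, start=10.0, step=1.0,
                    key=("STD", "inferior")):
        return [(start + t, {key})
                for t in np.arange(0, duration_s + step / 2, step)]

    def test_continuous_65s_episode_reported(self):
        report = episodes(self._flag_train(65))
        assert len(report.episodes) == 1
        ep = report.episodes[0]
        assert ep.duration == pytest.approx(65.0)
        assert report.summary["STD"]["frequency"] == 1

    def test_45s_episode_discarded(self):
        assert episodes(self._flag_train(45)).episodes == []

    def test_threshold_sweep_recovers_one_minute_rule(self):
        reported = [d for d in range(50, 71)
                    if episodes(self._flag_train(d)).episodes]
        assert min(reported) == 60

    def test_gap_beyond_tolerance_splits_episodes(self):
        flags = self._flag_train(70) + self._flag_train(70, start=200.0)
        report = episodes(flags, gap_tolerance_s=10.0)
        assert len(report.episodes) == 2

    def test_flag_time_fully_accounted(self):
        # 70 s reported + 45 s discarded, separated by a >10 s gap
        flags = self._flag_train(70) + self._flag_train(45, start=300.0)
        report = episodes(flags)
        assert len(report.episodes) == 1
        assert report.episodes[0].n_beats == 71

    def test_classify_series_skips_invalid_beats(self):
        from stholter.rules import DeviationSeries
        series = DeviationSeries(
            lead_names=("II", "III"),
            irl=np.zeros((2, 2)),
            st_dev=np.array([[-0.2, -0.2], [-0.2, -0.2]]),
            j_dev=np.zeros((2, 2)),
            valid=np.array([True, False]),
            beat_times=np.array([1.0, 2.0]))
        flagged = classify_series(series, age=45, sex="male")
        assert len(flagged) == 1 and flagged[0][0] == 1.0
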