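"""Cleaning pipeline: alignment, segmentation, filters, label extraction,
baseline wander, audit bookkeeping."""

import numpy as np
import pytest

from bpbench import preprocess
from bpbench.errors import AlignmentError, DataError
from bpbench.preprocess import (CycleDetectionError, PipelineConfig, Segment,
                                align_signals, detect_cycles,
                                distortion_statistics, extract_bp_labels,
                                filter_abp_extreme, filter_distortion,
                                remove_baseline_wander, run_pipeline,
                                run_pipeline_on_segments, segment_record,
                                sqi_skewness)
from bpbench.synth import PulseSpec, generate_pulse_train

from conftest import make_cycles


class TestAlign:
    def test_identical_signals_shift_zero(self, clean_record):
        shift, _, _ = align_signals(clean_record.abp, clean_record.abp, 125.0)
        assert shift == 0

    def test_known_delay_recovered_vs_bruteforce(self, clean_record):
        abp = clean_record.abp
        ppg = np.roll(abp, 40)  # PPG lags by 40 samples
        shift, ppg_al, abp_al = align_signals(ppg, abp, 125.0)
        # brute-force oracle over all lags in +-125
        a0 = abp - abp.mean()
        p0 = ppg - ppg.mean()
        def corr(lag):
            if lag >= 0:
                return abs(np.dot(p0[lag:], a0[:len(a0) - lag]))
            return abs(np.dot(p0[:lag], a0[-lag:]))
        best = max(range(-125, 126), key=corr)
        assert shift == best          # implementation matches the oracle
        assert abs(shift - 40) <= 1   # periodic content allows +-1 sample

    def test_shift_capped_at_window(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(2000)
        ppg = np.roll(base, 188)  # true delay 1.5 s @ 125 Hz
        shift, _, _ = align_signals(ppg, base, 125.0, max_shift=1.0)
        assert -125 <= shift <= 125

    def test_constant_input_is_alignment_undefined(self):
        with pytest.raises(AlignmentError):
            align_signals(np.ones(1000), np.ones(1000), 125.0)


class TestSegmentRecord:
    def _record(self, n, fs=125.0):
        from bpbench.synth import SignalRecord
        return SignalRecord("s", "r", fs, np.arange(n, dtype=float),
                            abp=np.arange(n, dtype=float))

    def test_15s_gives_three_5s_segments(self):
        segs = segment_record(self._record(1875), 5.0)
        assert len(segs) == 3
        assert all(len(s.ppg) == 625 for s in segs)

    def test_trailing_remainder_dropped(self):
        segs = segment_record(self._record(1862), 5.0)  # 14.9 s
        assert len(segs) == 2

    def test_concatenation_recovers_prefix(self):
        rec = self._record(1875)
        segs = segment_record(rec, 5.0)
        np.testing.assert_array_equal(
            np.concatenate([s.ppg for s in segs]), rec.ppg[:1875])

    def test_too_short_record_yields_empty(self):
        assert segment_record(self._record(100), 5.0) == []


class TestDetectCycles:
    def test_five_seconds_at_60bpm(self):
        rec = generate_pulse_train(PulseSpec(heart_rate=60, ppg_delay=0.0),
                                   5.0, 125.0, seed=0)
        cyc = detect_cycles(rec.ppg, 125.0)
        assert 4 <= len(cyc) <= 5
        assert cyc.heart_rate == pytest.approx(60, abs=2)

    def test_tachycardia_fails_p2p(self):
        rec = generate_pulse_train(
            PulseSpec(heart_rate=150, notch_delay=0.11, ppg_delay=0.0),
            5.0, 125.0, seed=0)
        with pytest.raises(CycleDetectionError) as err:
            detect_cycles(rec.ppg, 125.0)
        assert err.value.reason == "p2p_bpm"

    def test_flatline_has_no_extrema(self):
        with pytest.raises(CycleDetectionError) as err:
            detect_cycles(np.ones(625), 125.0)
        assert err.value.reason == "no_extrema"

    def test_nan_raises_data_error(self):
        x = np.ones(625)
        x[5] = np.nan
        with pytest.raises(DataError):
            detect_cycles(x, 125.0)


class TestABPFilterAndLabels:
    def _segment(self, abp):
        return Segment("s", "r", 0, 125.0, ppg=np.full(len(abp), np.nan),
                       abp=np.asarray(abp, dtype=float))

    def test_amplitude_violation(self, clean_record):
        abp = clean_record.abp * 225 / clean_record.abp.max()
        assert "amplitude" in filter_abp_extreme(self._segment(abp))

    def test_low_pulse_pressure(self):
        rec = generate_pulse_train(PulseSpec(sbp=100, dbp=92), 6.0, 125.0)
        assert "pulse_pressure" in filter_abp_extreme(self._segment(rec.abp))

    def test_normal_segment_passes(self, clean_record):
        assert filter_abp_extreme(self._segment(clean_record.abp)) == []

    def test_ppg_side_never_read(self, clean_record):
        """ABP filter works with sentinel NaN PPG (separation contract)."""
        seg = self._segment(clean_record.abp)  # ppg is all-NaN sentinel
        assert filter_abp_extreme(seg) == []

    def test_constant_peak_valley_labels(self):
        abp = np.zeros(500) + 80.0
        peaks = np.array([50, 150, 250])
        onsets = np.array([10, 110, 210])
        offsets = np.array([110, 210, 310])
        abp[peaks] = 120.0
        cyc = make_cycles(onsets, peaks, offsets)
        assert extract_bp_labels(abp, cyc) == (120.0, 80.0)

    def test_even_count_median_averages_central_pair(self):
        abp = np.zeros(600) + 80.0
        peaks = np.array([50, 150, 250, 350])
        abp[peaks] = [118, 120, 122, 140]
        cyc = make_cycles([10, 110, 210, 310], peaks, [110, 210, 310, 410])
        sbp, _ = extract_bp_labels(abp, cyc)
        assert sbp == 121.0

    def test_generator_ground_truth_recovered(self):
        rec = generate_pulse_train(
            PulseSpec(sbp=135, dbp=65, ppg_delay=0.0), 6.0, 125.0)
        cyc = detect_cycles(rec.abp, 125.0)
        sbp, dbp = extract_bp_labels(rec.abp, cyc)
        assert sbp == pytest.approx(135, abs=1)
        assert dbp == pytest.approx(65, abs=1)

    def test_label_monotonicity_under_affine_map(self, clean_record):
        cyc = detect_cycles(clean_record.abp, 125.0)
        sbp, dbp = extract_bp_labels(clean_record.abp, cyc)
        c, d = 1.3, -7.0
        sbp2, dbp2 = extract_bp_labels(c * clean_record.abp + d, cyc)
        assert sbp2 == c * sbp + d
        assert dbp2 == c * dbp + d


class TestDistortion:
    def test_periodic_train_statistics_near_zero(self, clean_segment):
        cyc = detect_cycles(clean_segment.ppg, 125.0)
        stats = distortion_statistics(clean_segment, cyc)
        tol = 1.0 / 125.0 + 1e-6
        assert stats["sd_p2p"] < tol and stats["sd_v2v"] < tol
        assert stats["sd_peak_amp"] < 1e-3

    def test_perturbed_peak_matches_hand_computed_sd(self, clean_segment):
        cyc = detect_cycles(clean_segment.ppg, 125.0)
        seg = clean_segment.copy()
        seg.ppg[cyc.peaks[1]] *= 1.5
        stats = distortion_statistics(seg, cyc)
        expected = np.std(seg.ppg[cyc.peaks], ddof=1)
        assert stats["sd_peak_amp"] == pytest.approx(expected, rel=1e-12)

    def test_alternating_intervals_closed_form(self):
        fs = 125.0
        # peaks alternating 0.8 s / 1.2 s apart
        gaps = np.tile([100, 150], 4)
        peaks = np.cumsum(np.concatenate([[50], gaps]))
        onsets = peaks - 40
        offsets = np.append(peaks[1:] - 40, peaks[-1] + 60)
        seg = Segment("s", "r", 0, fs, ppg=np.zeros(peaks[-1] + 200))
        stats = distortion_statistics(seg, make_cycles(onsets, peaks,
                                                       offsets, fs))
        m = len(peaks) - 1
        expected = 0.2 * np.sqrt(m / (m - 1))
        assert stats["sd_p2p"] == pytest.approx(expected, rel=1e-9)

    def test_percentile_mode_flags_single_outlier(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        stats = pd.DataFrame({
            k: np.abs(rng.normal(0.01, 0.001, 100))
            for k in ("sd_p2p", "sd_v2v", "sd_peak_amp", "sd_valley_amp")})
        stats.loc[42, "sd_p2p"] = 1.0
        mask, thr = filter_distortion(stats, thresholds=None, percentile=97.5)
        assert not mask[42]
        # oracle: 97.5th percentile by sorting
        col = np.sort(stats["sd_p2p"].to_numpy())
        assert thr["sd_p2p"] == pytest.approx(
            np.percentile(col, 97.5), rel=1e-12)

    def test_infinite_thresholds_remove_nothing(self):
        import pandas as pd
        stats = pd.DataFrame({k: [0.5, 2.0] for k in
                              ("sd_p2p", "sd_v2v", "sd_peak_amp",
                               "sd_valley_amp")})
        mask, _ = filter_distortion(stats, thresholds={
            k: np.inf for k in stats.columns})
        assert mask.all()

    def test_zero_statistics_pass_any_positive_threshold(self):
        import pandas as pd
        stats = pd.DataFrame({k: np.zeros(10) for k in
                              ("sd_p2p", "sd_v2v", "sd_peak_amp",
                               "sd_valley_amp")})
        mask, _ = filter_distortion(stats, thresholds={
            k: 1e-9 for k in stats.columns})
        assert mask.all()


class TestBaselineWander:
    def test_zero_baseline_signal_unchanged_between_valleys(self, clean_segment):
        cyc = detect_cycles(clean_segment.ppg, 125.0)
        out = remove_baseline_wander(clean_segment, cyc)
        lo, hi = cyc.valleys[0], cyc.valleys[-1]
        base = clean_segment.ppg - clean_segment.ppg[cyc.valleys].mean()
        dev = np.abs(out.ppg[lo:hi] - base[lo:hi])
        assert dev.max() < 1e-2 * np.ptp(clean_segment.ppg)

    def test_drift_removed_vs_known_clean_oracle(self, clean_record):
        fs = 125.0
        t = np.arange(len(clean_record.ppg)) / fs
        drift = 0.3 * np.sin(2 * np.pi * 0.2 * t)
        seg = Segment("s", "r", 0, fs, ppg=clean_record.ppg + drift)
        cyc = detect_cycles(seg.ppg, fs)
        out = remove_baseline_wander(seg, cyc)
        lo, hi = cyc.valleys[0], cyc.valleys[-1]
        clean = clean_record.ppg - clean_record.ppg[cyc.valleys].mean()
        rmse_corr = np.sqrt(np.mean((out.ppg[lo:hi] - clean[lo:hi]) ** 2))
        rmse_drift = np.sqrt(np.mean(
            (seg.ppg[lo:hi] - clean[lo:hi]) ** 2))
        assert rmse_corr < rmse_drift / 5

    def test_corrected_valleys_at_zero(self, clean_segment):
        cyc = detect_cycles(clean_segment.ppg, 125.0)
        out = remove_baseline_wander(clean_segment, cyc)
        assert np.abs(out.ppg[cyc.valleys]).max() < 1e-9

    def test_spline_interpolates_knots_exactly(self):
        rng = np.random.default_rng(0)
        ppg = rng.standard_normal(400).cumsum() / 10
        seg = Segment("s", "r", 0, 125.0, ppg=ppg)
        cyc = make_cycles([20, 120, 220], [70, 170, 270], [120, 220, 320])
        out = remove_baseline_wander(seg, cyc)
        assert np.abs(out.ppg[cyc.valleys]).max() < 1e-9


class TestSkewness:
    def test_right_tail_sample_positive(self):
        assert sqi_skewness(np.array([0.0, 0, 0, 10])) > 0

    def test_mirror_is_antisymmetric(self, clean_segment):
        sk = sqi_skewness(clean_segment.ppg)
        mirrored = 2 * clean_segment.ppg.mean() - clean_segment.ppg
        assert sqi_skewness(mirrored) == pytest.approx(-sk, rel=1e-9)

    def test_matches_moment_formula(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        m = x - x.mean()
        oracle = np.mean(m ** 3) / np.mean(m ** 2) ** 1.5
        assert sqi_skewness(x) == pytest.approx(oracle, rel=1e-12)

    def test_constant_is_degenerate_nan(self):
        assert np.isnan(sqi_skewness(np.ones(100)))


class TestPipeline:
    def test_clean_cohort_fully_kept(self):
        from bpbench.synth import CohortSpec, generate_cohort
        cohort = generate_cohort(CohortSpec(
            n_subjects=8, segments_per_subject=3, artifact_fraction=0.0,
            noise_sd=0.0, bw_amplitude=0.0, seed=2))
        res = run_pipeline(cohort)
        assert len(res.kept) == len(cohort)

    def test_artifact_recall_and_false_removals(self, artifact_pipeline):
        segs = artifact_pipeline.segments
        tagged = [s for s in segs if s.meta.get("artifact")]
        clean = [s for s in segs if not s.meta.get("artifact")]
        assert tagged, "cohort should contain tagged artifacts"
        recall = np.mean([s.status == "removed" for s in tagged])
        false_rate = np.mean([s.status == "removed" for s in clean])
        assert recall == 1.0
        assert false_rate < 0.05

    def test_audit_conservation_exact(self, artifact_pipeline):
        df = artifact_pipeline.audit.to_frame()
        kept = df[df.step == 0]["kept_segments"].iloc[0]
        for step in sorted(df.step.unique()):
            if step == 0:
                continue
            sub = df[df.step == step]
            # deleted counts per criterion can overlap; the kept column is
            # the authoritative count after the step
            removed = sum(1 for s in artifact_pipeline.segments
                          if s.status == "removed" and s.removal_step == step)
            kept = kept - removed
            assert sub["kept_segments"].iloc[-1] == kept
        assert kept == len(artifact_pipeline.kept)

    def test_idempotent_on_kept_segments(self, artifact_pipeline):
        res2 = run_pipeline_on_segments(artifact_pipeline.kept)
        assert len(res2.kept) == len(artifact_pipeline.kept)

    def test_order_stability(self, artifact_cohort):
        res_fwd = run_pipeline(artifact_cohort)
        res_rev = run_pipeline(list(artifact_cohort)[::-1])
        kept_fwd = {(s.record_id, s.segment_index) for s in res_fwd.kept}
        kept_rev = {(s.record_id, s.segment_index) for s in res_rev.kept}
        assert kept_fwd == kept_rev

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig(segment_length=2.1, pp_min=12.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = PipelineConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.segment_length == 2.1
        assert back.pp_min == 12.0
        assert back.abp_bounds == (30.0, 220.0)
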