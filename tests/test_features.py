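"""Handcrafted feature catalog: derivatives, landmarks, times/areas,
widths, frequency, histograms, SDC, SQI and index features."""

import numpy as np
import pandas as pd
import pytest

from bpbench import preprocess
from bpbench.errors import FeatureFailure
from bpbench.features import (FEATURE_NAMES, PointsOfInterest, derivatives,
                              extract_features, frequency_features,
                              histogram_features, locate_points,
                              sdc_features, sqi_index_features,
                              width_features, i_sdoo)
from bpbench.synth import PulseSpec, generate_pulse_train


def _seg(ppg, fs=125.0):
    return preprocess.Segment("s", "r", 0, fs, ppg=np.asarray(ppg, float))


class TestDerivatives:
    def test_ramp_has_unit_slope_zero_curvature(self):
        t = np.arange(100) / 125.0
        vpg, apg = derivatives(t, 125.0)
        np.testing.assert_allclose(vpg[1:-1], 1.0, atol=1e-9)
        np.testing.assert_allclose(apg[2:-2], 0.0, atol=1e-6)

    def test_sine_matches_closed_form(self):
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        vpg, _ = derivatives(np.sin(2 * np.pi * t), fs)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.abs(vpg[1:-1] - expected[1:-1]).max() < 1e-3

    def test_constant_signal_zero_derivatives(self):
        vpg, apg = derivatives(np.full(50, 3.0), 125.0)
        assert np.all(vpg == 0) and np.all(apg == 0)

    def test_too_short_raises(self):
        with pytest.raises(FeatureFailure):
            derivatives(np.ones(4), 125.0)


class TestLocatePoints:
    @pytest.mark.parametrize("hr,nd", [(60, 0.30), (75, 0.22), (66, 0.25)])
    def test_notch_landmark_time_matches_spec(self, hr, nd):
        spec = PulseSpec(heart_rate=hr, sbp=120, dbp=80, notch_delay=nd,
                         notch_depth=0.35, ppg_delay=0.0)
        rec = generate_pulse_train(spec, 6.0, 125.0, seed=0)
        feats = extract_features(_seg(rec.ppg))
        assert feats["T_s_e"] == pytest.approx(nd, abs=0.02)

    def test_no_dicrotic_lobe_fails_landmark_chain(self):
        spec = PulseSpec(notch_depth=0.0, ppg_delay=0.0)
        rec = generate_pulse_train(spec, 6.0, 125.0, seed=0)
        with pytest.raises(FeatureFailure) as err:
            extract_features(_seg(rec.ppg))
        assert err.value.missing in {"c", "d", "e", "z"}

    def test_w_precedes_peak_in_every_cycle(self):
        spec = PulseSpec(heart_rate=70, notch_delay=0.25, ppg_delay=0.0)
        rec = generate_pulse_train(spec, 6.0, 125.0, seed=0)
        cyc = preprocess.detect_cycles(rec.ppg, 125.0)
        vpg, apg = derivatives(rec.ppg, 125.0)
        poi = locate_points(_seg(rec.ppg), cyc, vpg, apg)
        for pts in poi.cycles:
            assert pts["o"] < pts["w"] < pts["s"] < pts["e"] < pts["f"]
            assert pts["a"] < pts["b"]


class TestTimesAreas:
    def test_area_additivity_exact(self, clean_segment):
        feats = extract_features(clean_segment)
        assert feats["A_sys"] + feats["A_dia"] == pytest.approx(
            feats["A1"] + feats["A2"] + feats["A3"] + feats["A4"], rel=1e-12)

    def test_all_elapsed_times_nonnegative(self, clean_segment):
        feats = extract_features(clean_segment)
        tcols = [n for n in FEATURE_NAMES if n.startswith("T_")]
        assert (feats[tcols] >= 0).all()

    def test_rectangle_pulse_total_area(self):
        # unit-height rectangle of width 1 s: trapezoid area ~ 1
        fs = 125.0
        ppg = np.zeros(500)
        ppg[100:226] = 1.0
        area = np.trapezoid(ppg, dx=1 / fs)
        assert area == pytest.approx(1.0, abs=2 / fs)


class TestWidths:
    def _triangle(self, half=100):
        ppg = np.concatenate([np.linspace(0, 1, half + 1),
                              np.linspace(1, 0, half + 1)[1:]])
        pts = {"o": 0, "s": half, "f": 2 * half}
        return ppg, pts

    def test_symmetric_triangle_closed_form(self):
        fs = 125.0
        ppg, pts = self._triangle()
        row = width_features(ppg, pts, fs)
        T = 100 / fs
        for p in (25, 50, 75):
            expected = (1 - p / 100) * T
            assert row[f"SW_{p}"] == pytest.approx(expected, abs=1.5 / fs)
            assert row[f"DW_{p}"] == pytest.approx(expected, abs=1.5 / fs)
            assert row[f"DW_over_SW_{p}"] == pytest.approx(1.0, abs=0.05)
        assert row["SW_25"] / row["SW_75"] == pytest.approx(3.0, rel=0.05)

    def test_elevation_monotonicity(self, clean_segment):
        feats = extract_features(clean_segment)
        assert feats["SW_25"] >= feats["SW_50"] >= feats["SW_75"]
        assert feats["DW_25"] >= feats["DW_50"] >= feats["DW_75"]

    def test_skewed_pulse_diastole_longer(self, clean_segment):
        feats = extract_features(clean_segment)
        assert feats["DW_over_SW_50"] > 1.0


class TestFrequency:
    def test_single_tone(self):
        fs = 125.0
        t = np.arange(int(10 * fs)) / fs
        out = frequency_features(np.sin(2 * np.pi * 1.2 * t), fs)
        assert out["f_dom"] == pytest.approx(1.2, abs=0.1)

    def test_two_tone_dominance(self):
        fs = 125.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        out = frequency_features(x, fs)
        assert out["f_dom"] == pytest.approx(1.0, abs=0.1)

    def test_noise_has_flatter_spectrum_than_tone(self):
        fs = 125.0
        rng = np.random.default_rng(0)
        t = np.arange(int(10 * fs)) / fs
        tone = frequency_features(np.sin(2 * np.pi * 1.2 * t), fs)
        noise = frequency_features(rng.standard_normal(len(t)), fs)
        assert (noise["mag_near"] / noise["mag_dom"]
                > tone["mag_near"] / tone["mag_dom"])


class TestHistograms:
    def test_linear_ramp_uniform_density(self):
        dens = histogram_features(np.linspace(0, 1, 1000), 5)
        np.testing.assert_allclose(dens, 0.2, atol=0.002)

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            dens = histogram_features(rng.standard_normal(77), 10)
            assert abs(dens.sum() - 1.0) < 1e-12

    def test_two_level_phase(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        np.testing.assert_allclose(histogram_features(x, 5),
                                   [0.5, 0, 0, 0, 0.5])

    def test_constant_phase_degenerates(self):
        np.testing.assert_allclose(histogram_features(np.ones(10), 5),
                                   [1, 0, 0, 0, 0])


class TestSDC:
    def test_triangle_phases_have_zero_deviation(self):
        ppg = np.concatenate([np.linspace(0, 1, 101),
                              np.linspace(1, 0, 101)[1:]])
        out = sdc_features(ppg, {"o": 0, "s": 100, "f": 200})
        assert out["SDC_sys"] == pytest.approx(0, abs=1e-12)
        assert out["SDC_dia"] == pytest.approx(0, abs=1e-12)

    def test_quadratic_upstroke_one_sixth(self):
        x = np.linspace(0, 1, 2001)
        ppg = np.concatenate([x ** 2, np.linspace(1, 0, 2001)[1:]])
        out = sdc_features(ppg, {"o": 0, "s": 2000, "f": 4000})
        assert out["SDC_sys"] == pytest.approx(1 / 6, abs=1e-3)

    def test_amplitude_scale_invariance(self, clean_segment):
        cyc = preprocess.detect_cycles(clean_segment.ppg, 125.0)
        pts = {"o": int(cyc.onsets[0]), "s": int(cyc.peaks[0]),
               "f": int(cyc.offsets[0])}
        a = sdc_features(clean_segment.ppg, pts)
        b = sdc_features(10 * clean_segment.ppg, pts)
        assert a["SDC_sys"] == pytest.approx(b["SDC_sys"], rel=1e-12)


class TestSQIIndices:
    def _poi_with_apg(self, amps):
        apg = np.zeros(200)
        pts = {"o": 0, "w": 5, "s": 60, "y": 80, "z": 110,
               "a": 10, "b": 30, "c": 40, "d": 50, "e": 90, "f": 180}
        for k, v in amps.items():
            apg[pts[k]] = v
        ppg = np.sin(np.linspace(0, np.pi, 200))
        return ppg, pts, PointsOfInterest([pts], ppg, np.zeros(200), apg,
                                          125.0)

    def test_aging_index_hand_arithmetic(self):
        ppg, pts, poi = self._poi_with_apg(
            {"a": 2, "b": -1, "c": 0.2, "d": -0.4, "e": 0.6})
        out = sqi_index_features(ppg, pts, poi, 125.0)
        assert out["AI"] == pytest.approx(-0.7)
        assert out["I_bd"] == pytest.approx(2.5)
        assert out["I_bcda"] == pytest.approx((-1 - 0.2 + 0.4) / 2)

    def test_sdoo_duration_ratio(self):
        assert i_sdoo({"o": 0, "s": 50, "f": 200}, 125.0) == 3.0

    def test_symmetric_cycle_zero_skewness(self):
        ppg, pts, poi = self._poi_with_apg({"a": 1, "b": -1, "c": 0.1,
                                            "d": -0.1, "e": 0.2})
        out = sqi_index_features(ppg, pts, poi, 125.0)
        # samples of half sine: skewness is small and negative-ish; just
        # check it matches scipy directly
        from scipy.stats import skew
        assert out["skewness"] == pytest.approx(
            float(skew(ppg[0:181])), abs=1e-12)


class TestExtractFeatures:
    def test_schema_stable_across_inputs(self, clean_segment):
        f1 = extract_features(clean_segment)
        rec = generate_pulse_train(
            PulseSpec(heart_rate=80, sbp=110, dbp=70, notch_delay=0.22,
                      ppg_delay=0.0), 6.0, 125.0, seed=5)
        f2 = extract_features(_seg(rec.ppg))
        assert list(f1.index) == list(f2.index) == list(FEATURE_NAMES)
        assert not f1.isna().any() and not f2.isna().any()

    def test_heart_rate_sweep_shrinks_cycle_times(self):
        vals = []
        for hr in (55, 70, 85):
            rec = generate_pulse_train(
                PulseSpec(heart_rate=hr, notch_delay=0.25 * 60 / hr,
                          ppg_delay=0.0), 6.0, 125.0, seed=0)
            vals.append(extract_features(_seg(rec.ppg))["T_o_f"])
        assert vals[0] > vals[1] > vals[2]

    def test_amplitude_scaling_behavior(self, clean_segment):
        f1 = extract_features(clean_segment)
        scaled = clean_segment.copy()
        scaled.ppg = 10.0 * scaled.ppg
        f2 = extract_features(scaled)
        # times and widths invariant
        for col in ("T_s_e", "T_o_f", "SW_50", "DW_50"):
            assert f2[col] == pytest.approx(f1[col], abs=1e-9)
        # PPG amplitudes and areas scale linearly
        for col in ("ppg_s", "A_sys", "A_dia"):
            assert f2[col] == pytest.approx(10 * f1[col], rel=1e-6)
        # normalized/statistical features invariant
        for col in ("SDC_sys", "skewness", "kurtosis", "AI", "I_bd",
                    "ppg_sys_hist_1", "ppg_dia_hist_3"):
            assert f2[col] == pytest.approx(f1[col], rel=1e-6, abs=1e-9)

    def test_whole_cycle_shift_invariance(self, clean_record):
        fs = 125.0
        period = int(round(fs * 60 / 60))
        f1 = extract_features(_seg(clean_record.ppg))
        f2 = extract_features(_seg(np.roll(clean_record.ppg, period)))
        tcols = [n for n in FEATURE_NAMES if n.startswith("T_")]
        for col in tcols + ["A_sys", "A_dia", "SW_50"]:
            assert f2[col] == pytest.approx(f1[col], abs=2.5 / fs)
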