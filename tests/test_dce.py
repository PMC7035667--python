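"""Perfusion-parameter formulas against hand-computed and oracle values."""

import numpy as np
import pytest

from synovaquant.dce import (
    TimeIntensityCurve,
    baseline_s0,
    extract_tic,
    iauc,
    iauc_map,
    peak_enhancement,
    perfusion_params,
    summarize_patient,
    time_to_peak,
    window_slope,
)

DT = 9.8


def curve(signals, dt=DT, **kw):
    signals = np.asarray(signals, dtype=float)
    return TimeIntensityCurve(np.arange(signals.size) * dt, signals, **kw)


def ols_slope_oracle(t, y):
    """Independent normal-equations OLS slope."""
    t, y = np.asarray(t, float), np.asarray(y, float)
    tc, yc = t - t.mean(), y - y.mean()
    return float((tc * yc).sum() / (tc * tc).sum())


class TestCurveValidation:
    def test_rejects_short_unsorted_negative(self):
        with pytest.raises(ValueError):
            TimeIntensityCurve([0.0], [1.0])
        with pytest.raises(ValueError):
            TimeIntensityCurve([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            TimeIntensityCurve([0.0, 9.8], [1.0, -1.0])
        with pytest.raises(ValueError):
            TimeIntensityCurve([0.0, 9.8], [1.0, 2.0], roi_name="synovium")


class TestExtractTic:
    def test_mean_over_voxels(self):
        vol = np.zeros((2, 1, 1, 2))
        vol[0, 0, 0] = [10, 11]
        vol[1, 0, 0] = [30, 31]
        mask = np.ones((2, 1, 1), dtype=bool)
        tic = extract_tic(vol, mask, [0.0, DT])
        assert tic.signals[0] == 20.0
        assert tic.signals[1] == 21.0

    def test_constant_volume_gives_constant_curve(self):
        vol = np.full((3, 3, 2, 4), 7.0)
        tic = extract_tic(vol, np.ones((3, 3, 2)), np.arange(4) * DT)
        assert np.all(tic.signals == 7.0)

    def test_empty_mask_and_shape_mismatch(self):
        vol = np.zeros((2, 2, 2, 3))
        with pytest.raises(ValueError, match="empty"):
            extract_tic(vol, np.zeros((2, 2, 2)), np.arange(3) * DT)
        with pytest.raises(ValueError, match="shape"):
            extract_tic(vol, np.ones((2, 2, 3)), np.arange(3) * DT)
        with pytest.raises(ValueError, match="frame"):
            extract_tic(vol, np.ones((2, 2, 2)), np.arange(4) * DT)


class TestBaseline:
    @pytest.mark.parametrize(
        "signals,n,expected",
        [([100, 120, 130], 1, 100.0), ([100, 102, 130], 2, 101.0)],
    )
    def test_baseline_window_mean(self, signals, n, expected):
        assert baseline_s0(curve(signals), n) == expected

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            baseline_s0(curve([1, 2, 3]), 0)
        with pytest.raises(ValueError):
            baseline_s0(curve([1, 2, 3]), 3)


class TestWindowSlope:
    def test_collinear_initial_window(self):
        tic = curve([100, 110, 120, 130])
        assert window_slope(tic, "initial") == pytest.approx(10 / 9.8 * 60)

    def test_constant_curve_zero_slope(self):
        tic = curve([50] * 6)
        assert window_slope(tic, "initial") == 0.0
        assert window_slope(tic, "final") == 0.0

    def test_hand_normal_equations_value(self):
        # 4 samples at 9.8 s spacing; slope 514.5/480.2 a.u./s
        tic = curve([100, 105, 120, 130])
        assert window_slope(tic, "initial") == pytest.approx(
            514.5 / 480.2 * 60
        )

    def test_final_window_uses_curve_tail(self):
        sig = np.concatenate([np.full(18, 100.0),
                              100 + np.arange(4) * 5.0])
        tic = curve(sig)
        assert window_slope(tic, "final") == pytest.approx(5 / 9.8 * 60)

    def test_endpoint_method(self):
        tic = curve([100, 105, 120, 130])
        assert window_slope(tic, "initial", method="endpoint") == pytest.approx(
            30 / 29.4 * 60
        )

    def test_too_few_samples_names_window(self):
        tic = curve([100, 110, 120], dt=40.0)
        with pytest.raises(ValueError, match="initial"):
            window_slope(tic, "initial")

    def test_ols_matches_oracle_on_random_curves(self, rng):
        """OLS slope equals an independent normal-equations fit (100 curves)."""
        for _ in range(100):
            n = rng.integers(4, 23)
            t = np.arange(n) * DT
            y = np.abs(rng.normal(100, 30, n))
            tic = TimeIntensityCurve(t, y)
            sel = t <= t[0] + 30.0
            expected = ols_slope_oracle(t[sel], y[sel]) * 60
            assert window_slope(tic, "initial") == pytest.approx(expected)


class TestTimeToPeak:
    def test_monotone_curve_peaks_at_last_frame(self):
        tic = curve(np.linspace(100, 300, 22))
        assert time_to_peak(tic) == pytest.approx(21 * 9.8)

    def test_plateau_tie_breaks_to_earliest(self):
        sig = np.array([100, 110, 120, 130, 140, 140, 140, 130.0])
        assert time_to_peak(curve(sig)) == pytest.approx(4 * 9.8)

    def test_phantom_synovium_peak(self, noiseless_phantom):
        config, signal, labels, truth = noiseless_phantom
        tic = extract_tic(signal, labels, config.frame_times, roi_label=1)
        assert time_to_peak(tic) == pytest.approx(39.2)


class TestPeakEnhancement:
    def test_ratio(self):
        assert peak_enhancement(curve([100, 120, 130]), 100.0) == pytest.approx(0.30)

    def test_constant_curve_zero(self):
        tic = curve([100] * 4)
        assert peak_enhancement(tic, baseline_s0(tic)) == 0.0

    def test_large_ratio(self):
        assert peak_enhancement(curve([100, 355]), 100.0) == pytest.approx(2.55)

    def test_nonpositive_s0_rejected(self):
        with pytest.raises(ValueError):
            peak_enhancement(curve([0, 1]), 0.0)


class TestIauc:
    def test_constant_curve_zero(self):
        tic = curve([100] * 8)
        assert iauc(tic, 100.0) == 0.0

    def test_hand_trapezoid(self):
        # (0+100)/2 * 9.8 + 5 * 100 * 9.8 = 5390 a.u.s = 89.8333 a.u.min
        tic = curve([100, 200, 200, 200, 200, 200, 200])
        assert iauc(tic, 100.0) == pytest.approx(5390 / 60)

    def test_linearity_in_enhancement(self, rng):
        y = np.abs(rng.normal(100, 20, 10))
        s0 = 100.0
        doubled = curve(s0 + 2 * (y - s0) + 500)  # shift keeps signals positive
        assert iauc(doubled, s0 + 500) == pytest.approx(2 * iauc(curve(y), s0))

    def test_negative_excursions_kept_by_default(self):
        tic = curve([100, 80, 80, 80, 80, 80, 80])
        assert iauc(tic, 100.0) < 0
        assert iauc(tic, 100.0, clip_negative=True) == 0.0

    def test_no_extrapolation_beyond_window(self):
        # samples at 9.8 s spacing never land on 60 s; last in-window is 58.8 s
        tic = curve(np.full(22, 100.0) + np.arange(22))
        with_window = iauc(tic, 100.0, window_len_s=60.0)
        truncated = iauc(curve(100.0 + np.arange(7)), 100.0, window_len_s=60.0)
        assert with_window == pytest.approx(truncated)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            iauc(curve([1, 2], dt=100.0), 1.0)


class TestIaucMap:
    def test_constant_volume_all_zero(self):
        vol = np.full((4, 4, 2, 8), 50.0)
        m = iauc_map(vol, np.arange(8) * DT)
        assert np.all(m == 0.0)

    def test_compartments_match_truth(self, noiseless_phantom):
        config, signal, labels, truth = noiseless_phantom
        m = iauc_map(signal, config.frame_times)
        for comp in config.compartments:
            vals = m[labels == comp.label]
            assert np.allclose(vals, truth.params[comp.name].iauc)

    def test_masked_voxels_are_nan(self):
        vol = np.full((4, 4, 2, 8), 50.0)
        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[0, 0, 0] = True
        m = iauc_map(vol, np.arange(8) * DT, mask=mask)
        assert np.isnan(m[~mask]).all()
        assert m[0, 0, 0] == 0.0


class TestPerfusionParams:
    def test_constant_curve_all_parameters_null(self):
        p = perfusion_params(curve([100.0] * 22))
        assert (p.wash_in, p.wash_out, p.pe, p.iauc) == (0, 0, 0, 0)
        assert p.ttp == 0.0

    def test_pe_identity_from_stored_fields(self, noiseless_phantom):
        config, signal, labels, _ = noiseless_phantom
        tic = extract_tic(signal, labels, config.frame_times, roi_label=1)
        p = perfusion_params(tic)
        assert p.pe == (p.s_max - p.s0) / p.s0


class TestSummarizePatient:
    def _params(self, wash_in):
        tic = curve([100, 100 + wash_in, 100 + 2 * wash_in, 100 + 3 * wash_in])
        return perfusion_params(tic)

    def test_single_roi_sd_missing(self):
        s = summarize_patient("P1", {"infrapatellar": self._params(5)})
        assert s.means["wash_in"] == pytest.approx(
            self._params(5).wash_in)
        assert np.isnan(s.sds["wash_in"])

    def test_mean_and_sample_sd(self):
        roi_params = {
            "infrapatellar": self._params(1),
            "intercondylar": self._params(2),
            "prefemoral": self._params(3),
        }
        scale = self._params(1).wash_in  # a.u./min per unit step
        s = summarize_patient("P1", roi_params)
        assert s.means["wash_in"] == pytest.approx(2 * scale)
        assert s.sds["wash_in"] == pytest.approx(1 * scale)

    def test_identical_rois_zero_sd(self):
        roi_params = {name: self._params(2) for name in
                      ("infrapatellar", "intercondylar", "prefemoral")}
        s = summarize_patient("P1", roi_params)
        assert s.sds["pe"] == 0.0

    def test_unknown_inclusion_name(self):
        with pytest.raises(ValueError, match="roi_inclusion"):
            summarize_patient("P1", {"infrapatellar": self._params(1)},
                              roi_inclusion=("popliteal_artery",))
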