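"""Tests for SEP/mCherry surface-fraction quantification."""

import numpy as np
import pandas as pd
import pytest

from glrkit.dualreporter import (
    ChannelImage,
    Roi,
    ThresholdSet,
    calibrate_thresholds,
    estimate_surface_fraction,
    integrated_density,
    normalize_to_control,
    quantify_pair,
    soma_total,
)
from glrkit.errors import CalibrationError, ConfigurationError, NonIdentifiableError
from glrkit.synthdata import ReporterTruth, gen_dual_channel


def img(arr, channel="SEP"):
    return ChannelImage(np.asarray(arr, float), channel)


def full_roi(shape):
    return Roi(rect=(0, shape[0], 0, shape[1]))


class TestCalibration:
    def test_identical_controls(self, rng):
        base = np.clip(rng.normal(100, 5, (30, 30)), 0, None)
        pairs = [(img(base, "SEP"), img(base, "mCherry"))] * 3
        ts = calibrate_thresholds(pairs)
        assert ts.t_sep == pytest.approx(ts.t_mcherry)
        single = calibrate_thresholds([pairs[0]] * 3)
        assert ts.t_sep == pytest.approx(single.t_sep)

    def test_mean_of_noiseless_backgrounds(self):
        pairs = [(img(np.full((10, 10), v), "SEP"), img(np.full((10, 10), v), "mCherry"))
                 for v in (100.0, 200.0, 150.0)]
        ts = calibrate_thresholds(pairs)
        assert ts.t_sep == pytest.approx(150.0)

    def test_matches_truth_rule(self, rng):
        """Threshold from synthetic backgrounds within 2% of bg + 4 sd."""
        pairs = []
        for s in range(4):
            r = np.random.default_rng(s)
            sep = np.clip(r.normal(100, 5, (40, 40)), 0, None)
            mch = np.clip(r.normal(120, 6, (40, 40)), 0, None)
            pairs.append((img(sep, "SEP"), img(mch, "mCherry")))
        ts = calibrate_thresholds(pairs)
        assert abs(ts.t_sep - (100 + 4 * 5)) / (100 + 4 * 5) < 0.02
        assert abs(ts.t_mcherry - (120 + 4 * 6)) / (120 + 4 * 6) < 0.02

    def test_too_few_pairs(self):
        pairs = [(img(np.ones((5, 5)), "SEP"), img(np.ones((5, 5)), "mCherry"))] * 2
        with pytest.raises(CalibrationError):
            calibrate_thresholds(pairs)


class TestIntegratedDensity:
    def test_uniform(self):
        i = img(np.full((10, 10), 10.0))
        assert integrated_density(i, Roi(rect=(0, 5, 0, 10)), 5.0) == 500.0

    def test_threshold_above_max(self):
        i = img(np.full((10, 10), 10.0))
        assert integrated_density(i, full_roi((10, 10)), 11.0) == 0.0

    def test_matches_brute_force(self, rng):
        arr = rng.uniform(0, 100, (30, 30))
        roi = Roi(rect=(5, 25, 5, 25))
        t = 40.0
        expected = 0.0
        for r in range(5, 25):
            for c in range(5, 25):
                if arr[r, c] > t:
                    expected += arr[r, c]
        assert integrated_density(img(arr), roi, t) == pytest.approx(expected)

    def test_empty_roi_errors(self):
        with pytest.raises(ConfigurationError):
            integrated_density(img(np.ones((5, 5))), Roi(rect=(0, 0, 0, 5)), 0.0)


class TestQuantifyPair:
    def test_simple_ratio(self):
        sep = img(np.full((10, 10), 4.0), "SEP")
        mch = img(np.full((10, 10), 8.0), "mCherry")
        q = quantify_pair(sep, mch, full_roi((10, 10)), ThresholdSet(0.0, 0.0))
        assert q.ratio == pytest.approx(0.5)

    def test_identical_images_ratio_one(self, rng):
        arr = rng.uniform(10, 100, (20, 20))
        q = quantify_pair(img(arr, "SEP"), img(arr, "mCherry"),
                          full_roi((20, 20)), ThresholdSet(5.0, 5.0))
        assert q.ratio == pytest.approx(1.0)

    def test_forward_model_identity(self):
        truth = ReporterTruth(f_surf=0.6, q=1.0, noise_sd=0.0)
        sep, mch = gen_dual_channel(truth)
        q = quantify_pair(img(sep, "SEP"), img(mch, "mCherry"),
                          full_roi(truth.roi_shape), ThresholdSet(1.0, 1.0))
        assert q.ratio == pytest.approx(0.6, abs=1e-6)

    def test_zero_mcherry_flags_undefined(self):
        sep = img(np.full((5, 5), 4.0), "SEP")
        mch = img(np.zeros((5, 5)), "mCherry")
        q = quantify_pair(sep, mch, full_roi((5, 5)), ThresholdSet(0.0, 0.0))
        assert not q.ratio_defined

    def test_gain_invariance(self, rng):
        """Common gain on both channels (thresholds rescaled) leaves ratio fixed."""
        truth = ReporterTruth(f_surf=0.4, q=0.9, noise_sd=3.0, seed=5)
        sep, mch = gen_dual_channel(truth)
        roi = full_roi(truth.roi_shape)
        q1 = quantify_pair(img(sep, "SEP"), img(mch, "mCherry"), roi,
                           ThresholdSet(10.0, 10.0))
        q2 = quantify_pair(img(sep * 7, "SEP"), img(mch * 7, "mCherry"), roi,
                           ThresholdSet(70.0, 70.0))
        assert q1.ratio == pytest.approx(q2.ratio, rel=1e-12)


class TestNormalizeToControl:
    def test_division(self):
        df = pd.DataFrame({"genotype": ["WT", "WT", "mut"],
                           "ratio": [0.4, 0.6, 0.435]})
        out = normalize_to_control(df, "WT")
        assert out.loc[2, "ratio_norm"] == pytest.approx(0.87)
        assert out.loc[out.genotype == "WT", "ratio_norm"].mean() == pytest.approx(1.0)

    def test_identical_samples(self):
        df = pd.DataFrame({"genotype": ["WT", "WT", "mut"], "ratio": [0.5] * 3})
        out = normalize_to_control(df, "WT")
        assert (out["ratio_norm"] == 1.0).all()

    def test_by_day_batches(self):
        df = pd.DataFrame({
            "genotype": ["WT", "mut", "WT", "mut"],
            "ratio": [0.5, 0.25, 1.0, 0.5],
            "day": ["d1", "d1", "d2", "d2"],
        })
        out = normalize_to_control(df, "WT", by_day=True)
        assert out.loc[out.genotype == "mut", "ratio_norm"].tolist() == [0.5, 0.5]

    def test_control_mean_is_one_any_input(self, rng):
        df = pd.DataFrame({"genotype": ["WT"] * 10 + ["mut"] * 10,
                           "ratio": rng.uniform(0.1, 1.0, 20)})
        out = normalize_to_control(df, "WT")
        assert out.loc[out.genotype == "WT", "ratio_norm"].mean() == pytest.approx(1.0)

    def test_missing_control(self):
        df = pd.DataFrame({"genotype": ["a", "b"], "ratio": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            normalize_to_control(df, "WT")

    def test_two_genotype_recovery(self):
        """Mean mutant normalized ratio tracks the true surface-fraction ratio."""
        rows = []
        for i in range(25):
            for gi, (genotype, f) in enumerate((("WT", 0.5), ("mut", 0.35))):
                truth = ReporterTruth(f_surf=f, q=1.0, noise_sd=4.0, seed=1000 * i + gi)
                sep, mch = gen_dual_channel(truth)
                roi = full_roi(truth.roi_shape)
                q = quantify_pair(img(sep, "SEP"), img(mch, "mCherry"), roi,
                                  ThresholdSet(10.0, 10.0))
                rows.append({"genotype": genotype, "ratio": q.ratio})
        out = normalize_to_control(pd.DataFrame(rows), "WT")
        mut_mean = out.loc[out.genotype == "mut", "ratio_norm"].mean()
        assert abs(mut_mean - 0.70) < 0.02


class TestSurfaceFraction:
    def test_identity_cases(self):
        assert estimate_surface_fraction(1.0, q=1.0) == (1.0, False)
        f, clamped = estimate_surface_fraction(0.55, q=0.9)
        assert f == pytest.approx(0.5) and not clamped

    def test_inversion_is_identity_on_grid(self):
        for q in (0.5, 0.9, 1.0):
            for f in np.linspace(0, 1, 11):
                ratio = f + (1 - f) * (1 - q)
                f_hat, _ = estimate_surface_fraction(ratio, q=q)
                assert abs(f_hat - f) < 1e-9

    def test_clamping_flag(self):
        f, clamped = estimate_surface_fraction(1.1, q=1.0)
        assert f == 1.0 and clamped

    def test_q_zero_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            estimate_surface_fraction(0.5, q=0.0)

    def test_recovery_under_noise(self):
        """Sweep of true f with 2% noise recovers f within 0.02 on average."""
        errs = []
        for i, f in enumerate(np.arange(0.1, 0.95, 0.1)):
            truth = ReporterTruth(f_surf=float(f), q=0.95, total_per_pixel=200.0,
                                  noise_sd=4.0, seed=i)
            sep, mch = gen_dual_channel(truth)
            q = quantify_pair(img(sep, "SEP"), img(mch, "mCherry"),
                              full_roi(truth.roi_shape), ThresholdSet(10.0, 10.0))
            f_hat, _ = estimate_surface_fraction(q.ratio, q=0.95)
            errs.append(abs(f_hat - f))
        assert np.mean(errs) < 0.02

    def test_ratio_monotone_in_f(self):
        for q in (0.5, 0.9, 1.0):
            ratios = [f + (1 - f) * (1 - q) for f in np.linspace(0, 1, 11)]
            assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestSomaTotal:
    def test_uniform(self):
        area, intden = soma_total(img(np.full((10, 10), 10.0), "mCherry"),
                                  Roi(rect=(0, 10, 0, 10)))
        assert (area, intden) == (100, 1000.0)

    def test_zero_image(self):
        area, intden = soma_total(img(np.zeros((8, 8)), "mCherry"),
                                  Roi(rect=(2, 6, 2, 6)))
        assert (area, intden) == (16, 0.0)

    def test_matches_brute_force(self, rng):
        arr = rng.uniform(0, 50, (20, 20))
        mask = rng.random((20, 20)) > 0.5
        area, intden = soma_total(img(arr, "mCherry"), Roi(mask_pixels=mask))
        assert area == int(mask.sum())
        assert intden == pytest.approx(float(arr[mask].sum()))
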