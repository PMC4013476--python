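"""Classification-image estimators: whitening, the four-class detection
estimator, the response-aligned localization estimator, smoothing, and
radial frequency profiles."""

import numpy as np
import pandas as pd
import pytest

import freeloc as fl
from freeloc import classify
from freeloc.records import TrialSet
from freeloc.stimulus import NoiseSpec, TargetSpec
from freeloc.synthetic import LinearObserver, io_template, mismatched_template


def template_correlation(ci_weights, template):
    """Pixelwise correlation between a CI and the generating template after
    the display low-pass (raw whitened-noise CIs are dominated by
    high-frequency estimation error, which the smoothing removes)."""
    n = template.shape

    def smooth(w):
        ci = classify.ClassificationImage(weights=w, task="detection",
                                          beta=template.beta, n_trials_used=1)
        return classify.butterworth_smooth(ci).weights

    a = smooth(ci_weights)
    b = smooth(np.roll(template.spatial_weights, (n // 2, n // 2),
                       axis=(0, 1)))
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


class TestWhiten:
    def test_white_noise_is_identity_up_to_scale(self):
        sp = fl.build_spectrum(NoiseSpec(beta=0.0, shape=32))
        x = fl.sample_noise(sp, 3)
        q = classify.whiten_noise(x, sp)
        assert np.allclose(q * sp.values[0, 0], x, atol=1e-9)

    def test_linearity(self, spectrum_b1):
        a = fl.sample_noise(spectrum_b1, 1)
        b = fl.sample_noise(spectrum_b1, 2)
        assert np.allclose(classify.whiten_noise(a + b, spectrum_b1),
                           classify.whiten_noise(a, spectrum_b1)
                           + classify.whiten_noise(b, spectrum_b1))

    def test_whitened_power_spectrum_is_inverse(self, spectrum_b1):
        n = spectrum_b1.shape
        fields = np.stack([fl.sample_noise(spectrum_b1, s) for s in range(500)])
        q = classify.whiten_noise(fields, spectrum_b1)
        p = np.mean(np.abs(np.fft.fft2(q, axes=(-2, -1))) ** 2, axis=0) / n**2
        expect = 1.0 / spectrum_b1.values
        m = fl.stimulus.radial_frequency_grid(n) > 0
        ratio = p[m] / expect[m]
        assert abs(np.median(ratio) - 1.0) < 0.1


def run_detection_trials(model, noise, contrast, n, seed):
    from freeloc.synthetic import run_experiment
    return run_experiment("detection", model, noise, 3.0, [contrast], n,
                          seed=seed)


class TestDetectionCI:
    @pytest.fixture(scope="class")
    def trials(self):
        noise = NoiseSpec(beta=1.0, shape=64)
        model = LinearObserver(template=io_template(noise, TargetSpec(3.0)),
                               internal_noise_sd=0.5)
        return run_detection_trials(model, noise, 0.10, 2000, seed=8), model

    def test_recovers_linear_template(self, trials):
        # agreement bar calibrated by simulation at this trial count and
        # internal-noise level
        ts, model = trials
        ci = classify.detection_ci(ts)
        assert template_correlation(ci.weights, model.template) > 0.25

    def test_correlation_grows_with_trials(self, trials):
        ts, model = trials
        sub = TrialSet(frame=ts.frame.iloc[:500].copy(),
                       noise=ts.noise[:500], spectrum=ts.spectrum)
        r_small = template_correlation(classify.detection_ci(sub).weights,
                                       model.template)
        r_full = template_correlation(classify.detection_ci(ts).weights,
                                      model.template)
        assert r_full > r_small

    def test_shuffled_responses_give_null_image(self, trials):
        ts, model = trials
        rng = np.random.default_rng(0)
        f = ts.frame.copy()
        f["detected"] = rng.permutation(f["detected"].to_numpy())
        f["present"] = rng.permutation(f["present"].to_numpy())
        null = classify.detection_ci(
            TrialSet(frame=f, noise=ts.noise, spectrum=ts.spectrum))
        assert abs(template_correlation(null.weights, model.template)) < 0.1

    def test_empty_class_reports_counts(self, trials):
        ts, _ = trials
        f = ts.frame.copy()
        f["detected"] = True  # no TN/FN
        with pytest.raises(ValueError, match="counts"):
            classify.detection_ci(
                TrialSet(frame=f, noise=ts.noise, spectrum=ts.spectrum))

    def test_missing_spectrum_is_error(self, trials):
        ts, _ = trials
        broken = TrialSet(frame=ts.frame, noise=ts.noise, spectrum=None)
        with pytest.raises(ValueError, match="spectrum"):
            classify.detection_ci(broken)


class TestLocalizationCI:
    def test_mismatched_template_peak_recovered(self):
        """The response-aligned estimator recovers the peak frequency of a
        deliberately distorted template within one radial bin."""
        noise = NoiseSpec(beta=1.0, shape=64)
        model = LinearObserver(
            template=mismatched_template(noise, TargetSpec(3.0),
                                         "low-suppressed", strength=2.0))
        from freeloc.synthetic import run_experiment
        ts = run_experiment("localization", model, noise, 3.0, [0.18], 2000,
                            seed=13)
        pc = ts.frame["correct"].mean()
        assert 0.3 < pc < 0.95
        ci = classify.localization_ci(ts)
        prof = classify.radial_profile(ci)
        # reference: radial profile of the true template's frequency weights
        w = np.abs(model.template.freq_weights)
        k, centers = classify._radial_bins(64, fl.PIXEL_ANGLE_DEG)
        ref = np.bincount(k.ravel(), weights=w.ravel()) / np.bincount(k.ravel())
        ref_peak = centers[int(np.argmax(ref))]
        bin_width = centers[2] - centers[1]
        assert abs(prof.peak_frequency - ref_peak) <= 1.5 * bin_width

    def test_random_responses_give_null_image(self):
        noise = NoiseSpec(beta=1.0, shape=64)
        sp = fl.build_spectrum(noise)
        rng = np.random.default_rng(2)
        n_tr = 400
        fields = np.stack([fl.sample_noise(sp, 1000 + i) for i in range(n_tr)])
        lo, hi = fl.stimulus.search_bounds(64)
        f = pd.DataFrame({
            "trial_id": np.arange(n_tr), "task": "localization", "beta": 1.0,
            "contrast": 0.2, "present": True,
            "loc_x": rng.integers(lo, hi, n_tr),
            "loc_y": rng.integers(lo, hi, n_tr),
            "response_x": rng.integers(lo, hi, n_tr).astype(float),
            "response_y": rng.integers(lo, hi, n_tr).astype(float),
            "detected": True, "correct": False, "statistic": 0.0,
            "session": 0, "seed": 0, "processed": False,
        })
        ci = classify.localization_ci(TrialSet(frame=f, noise=fields,
                                               spectrum=sp))
        # responses carry no stimulus information: the mean aligned field is
        # noise of order sd/sqrt(n)
        q = classify.whiten_noise(fields, sp)
        assert np.abs(ci.weights).max() < 6 * q.std() / np.sqrt(n_tr)

    def test_no_incorrect_trials_is_error(self):
        noise = NoiseSpec(beta=1.0, shape=32)
        sp = fl.build_spectrum(noise)
        f = pd.DataFrame({
            "trial_id": [0], "task": "localization", "beta": 1.0,
            "contrast": 0.2, "present": True, "loc_x": [10], "loc_y": [10],
            "response_x": [10.0], "response_y": [10.0], "detected": True,
            "correct": True, "statistic": 0.0, "session": 0, "seed": 0,
            "processed": False,
        })
        with pytest.raises(ValueError):
            classify.localization_ci(TrialSet(
                frame=f, noise=np.zeros((1, 32, 32)), spectrum=sp))


class TestButterworth:
    def test_dc_gain_unity_and_half_power_at_cutoff(self):
        n = 64
        ci = classify.ClassificationImage(
            weights=np.zeros((n, n)), task="detection", beta=0.0,
            n_trials_used=1)
        f = fl.stimulus.radial_frequency_grid(n) / ci.pixel_angle_deg
        gain = 1.0 / np.sqrt(1.0 + (f / 5.6) ** 8)
        assert gain[0, 0] == 1.0
        idx = np.unravel_index(np.argmin(np.abs(f - 5.6)), f.shape)
        assert gain[idx] == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_cutoff_conversion_to_cycles_per_pixel(self):
        assert 5.6 * fl.PIXEL_ANGLE_DEG == pytest.approx(0.29, abs=0.005)

    def test_smoothing_preserves_mean(self):
        rng = np.random.default_rng(4)
        ci = classify.ClassificationImage(weights=rng.standard_normal((64, 64)),
                                          task="detection", beta=0.0,
                                          n_trials_used=1)
        sm = classify.butterworth_smooth(ci)
        assert sm.weights.mean() == pytest.approx(ci.weights.mean(), abs=1e-9)
        assert sm.weights.std() < ci.weights.std()


class TestRadialProfile:
    def test_pure_cosine_peaks_at_its_frequency(self):
        n = 64
        k0 = 6  # cycles per image
        x = np.arange(n)
        img = np.outer(np.cos(2 * np.pi * k0 * (x - n // 2) / n), np.ones(n))
        ci = classify.ClassificationImage(weights=img, task="detection",
                                          beta=0.0, n_trials_used=1)
        prof = classify.radial_profile(ci, window_cutoff_deg=1e9)
        f0 = (k0 / n) / ci.pixel_angle_deg
        bin_width = prof.freq_cyc_deg[2] - prof.freq_cyc_deg[1]
        assert abs(prof.peak_frequency - f0) <= bin_width

    def test_normalized_to_unit_peak(self, spectrum_b1):
        ci = classify.ClassificationImage(
            weights=fl.sample_noise(spectrum_b1, 5), task="detection",
            beta=1.0, n_trials_used=1)
        prof = classify.radial_profile(ci)
        assert np.abs(prof.weights).max() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_image_rejected(self):
        ci = classify.ClassificationImage(weights=np.zeros((32, 32)),
                                          task="detection", beta=0.0,
                                          n_trials_used=1)
        with pytest.raises(ValueError):
            classify.radial_profile(ci)


class TestIOFrequencyWeights:
    def test_white_noise_profile_is_lowpass(self):
        prof = classify.io_frequency_weights(0.0)
        assert prof.peak_frequency == 0.0
        assert np.all(np.diff(prof.weights) <= 1e-12)

    @pytest.mark.parametrize("beta", [1.0, 2.0, 3.0])
    def test_peak_matches_analytic_formula(self, beta):
        prof = classify.io_frequency_weights(beta)
        analytic = classify.analytic_io_peak(beta)
        bin_width = prof.freq_cyc_deg[2] - prof.freq_cyc_deg[1]
        assert abs(prof.peak_frequency - analytic) <= bin_width
        # dense continuous grid search confirms sqrt(beta)/(2 pi sigma)
        sigma_deg = 3.0 * fl.PIXEL_ANGLE_DEG
        f = np.linspace(0.01, 5, 20000)
        w = f**beta * np.exp(-2 * np.pi**2 * sigma_deg**2 * f**2)
        assert f[np.argmax(w)] == pytest.approx(analytic, rel=1e-3)

    def test_peak_migration_zero_to_1p7(self):
        peaks = [classify.io_frequency_weights(b).peak_frequency
                 for b in (0.0, 1.0, 2.0, 3.0)]
        assert peaks[0] == 0.0
        assert all(np.diff(peaks) > 0)
        assert peaks[-1] == pytest.approx(1.7, rel=0.05)
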