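"""Synthetic model-human observers: degenerate equivalence with the ideal
observer, internal-noise effects, closed-form efficiency, and experiment
bookkeeping."""

import numpy as np
import pytest

import freeloc as fl
from freeloc import observer as obs
from freeloc.stimulus import NoiseSpec, TargetSpec, make_trial
from freeloc.synthetic import (
    EquivalentInputNoiseObserver,
    LinearObserver,
    analytic_linear_efficiency,
    io_template,
    mismatched_template,
    respond_detection,
    respond_dandl,
    respond_localization,
    run_experiment,
)


class TestRespondDetection:
    def test_degenerate_model_equals_ideal_observer(self, noise_b1, target3,
                                                    spectrum_b1):
        tmpl = obs.build_template(target3, spectrum_b1)
        model = LinearObserver(template=tmpl, criterion=1.25)
        for seed in range(20):
            stim = make_trial("detection", noise_b1,
                              TargetSpec(3.0, contrast=0.08), seed)
            row = respond_detection(stim, model, seed)
            dec = obs.detect(stim, tmpl, 1.25)
            assert row["detected"] == dec.detected
            assert row["statistic"] == pytest.approx(dec.statistic)

    def test_large_internal_noise_drives_pc_to_chance(self, noise_b1, target3):
        tmpl = io_template(noise_b1, target3)
        sep = 0.3 * 100.0 * tmpl.whitened_energy
        noisy = LinearObserver(template=tmpl, internal_noise_sd=200.0,
                               criterion=sep / 2)
        ts = run_experiment("detection", noisy, noise_b1, 3.0, [0.3], 600,
                            seed=2, store_noise=False)
        assert abs(ts.frame["correct"].mean() - 0.5) < 3 * 0.5 / np.sqrt(600)

    def test_efficiency_matches_closed_form(self, noise_b1, target3):
        """Measured detection efficiency equals the analytic linear-observer
        value within 3 s.e. for a grid of templates and noise levels."""
        from freeloc.performance import match_detection_criterion
        grid = [
            (io_template(noise_b1, target3), 0.0, 1.0),
            (io_template(noise_b1, target3), 1.0, None),
            (mismatched_template(noise_b1, target3, "low-suppressed"), 0.5, None),
        ]
        c_obs = 0.12
        sp = fl.build_spectrum(noise_b1)
        for i, (tmpl, s_int, expect) in enumerate(grid):
            model = LinearObserver(
                template=tmpl, internal_noise_sd=s_int,
                criterion=0.5 * c_obs * 100.0 * tmpl.whitened_energy)
            eta_star = analytic_linear_efficiency(model)
            if expect is not None:
                assert eta_star == pytest.approx(expect, rel=1e-9)
            ts = run_experiment("detection", model, noise_b1, 3.0, [c_obs],
                                2000, seed=40 + i, store_noise=False)
            f = ts.frame
            pres = f["present"].astype(bool)
            hit = float(f.loc[pres, "detected"].mean())
            fa = float(f.loc[~pres, "detected"].mean())
            c_io, _ = match_detection_criterion(hit, fa, target3, sp)
            eta = (c_io / c_obs) ** 2
            # delta-method s.e. of eta through z(hit)-z(fa)
            from scipy import stats
            n_half = pres.sum()
            var_d = (hit * (1 - hit) / n_half / stats.norm.pdf(stats.norm.ppf(hit)) ** 2
                     + fa * (1 - fa) / n_half / stats.norm.pdf(stats.norm.ppf(fa)) ** 2)
            d = stats.norm.ppf(hit) - stats.norm.ppf(fa)
            se_eta = eta * 2 * np.sqrt(var_d) / d
            assert abs(eta - eta_star) < 3 * se_eta


class TestRespondLocalization:
    def test_huge_motor_jitter_destroys_performance(self, noise_b1, target3):
        tmpl = io_template(noise_b1, target3)
        model = LinearObserver(template=tmpl, motor_jitter_sd=50.0)
        ts = run_experiment("localization", model, noise_b1, 3.0, [0.6], 300,
                            seed=3, store_noise=False)
        assert ts.frame["correct"].mean() < 0.25

    def test_template_distortion_lowers_efficiency_monotonically(
            self, noise_b1, target3, lut_b1):
        etas = []
        for strength in (0.0, 1.5, 4.0):
            if strength == 0.0:
                tmpl = io_template(noise_b1, target3)
            else:
                tmpl = mismatched_template(noise_b1, target3,
                                           "low-suppressed", strength=strength)
            model = LinearObserver(template=tmpl)
            ts = run_experiment("localization", model, noise_b1, 3.0, [0.32],
                                1200, seed=int(50 + strength), store_noise=False)
            pc = float(ts.frame["correct"].mean())
            c_io = lut_b1.invert(pc)
            etas.append((c_io / 0.32) ** 2)
        assert etas[0] > etas[1] > etas[2]

    def test_responses_stay_in_search_region(self, noise_b1, target3):
        model = LinearObserver(template=io_template(noise_b1, target3),
                               motor_jitter_sd=8.0)
        lo, hi = fl.stimulus.search_bounds(64)
        for seed in range(30):
            stim = make_trial("localization", noise_b1,
                              TargetSpec(3.0, contrast=0.2), seed)
            row = respond_localization(stim, model, seed)
            assert lo <= row["response_y"] < hi
            assert lo <= row["response_x"] < hi


class TestRespondDandl:
    def test_low_criterion_reduces_to_localization(self, noise_b1, target3):
        model = LinearObserver(template=io_template(noise_b1, target3),
                               criterion=-np.inf)
        for seed in range(10):
            stim = make_trial("dandl", noise_b1,
                              TargetSpec(3.0, contrast=0.3), seed)
            row = respond_dandl(stim, model, seed)
            assert row["detected"]
            if stim.truth_present:
                row_loc = respond_localization(stim, model, seed)
                assert (row["response_y"], row["response_x"]) == \
                    (row_loc["response_y"], row_loc["response_x"])

    def test_fp_rate_monotone_in_criterion(self, noise_b1, target3):
        tmpl = io_template(noise_b1, target3)
        sd = LinearObserver(template=tmpl).response_sd
        fps = []
        for crit in (0.0, 2.0 * sd, 4.0 * sd):
            model = LinearObserver(template=tmpl, criterion=crit)
            ts = run_experiment("dandl", model, noise_b1, 3.0, [0.25], 400,
                                seed=7, store_noise=False)
            absent = ~ts.frame["present"].astype(bool)
            fps.append(ts.frame.loc[absent, "detected"].mean())
        assert fps[0] > fps[1] > fps[2]

    def test_criterion_jitter_lowers_pc_at_matched_mean(self, noise_b1,
                                                        target3):
        tmpl = io_template(noise_b1, target3)
        sd = LinearObserver(template=tmpl).response_sd
        crit = 3.0 * sd
        pcs = {}
        for jit in (0.0, 2.0):
            model = LinearObserver(template=tmpl, criterion=crit,
                                   criterion_jitter_sd=jit)
            ts = run_experiment("dandl", model, noise_b1, 3.0, [0.3], 2000,
                                seed=9, store_noise=False)
            pcs[jit] = float(ts.frame["correct"].mean())
        assert pcs[0.0] - pcs[2.0] > 2 * np.sqrt(2 * 0.25 / 2000)


class TestEquivalentInputNoise:
    def test_gamma_zero_is_the_ideal_observer(self, noise_b1, target3,
                                              spectrum_b1):
        ein = EquivalentInputNoiseObserver(spectrum=spectrum_b1,
                                           target=target3, gamma=0.0)
        tmpl = obs.build_template(target3, spectrum_b1)
        assert ein.efficiency == 1.0
        stim = make_trial("localization", noise_b1,
                          TargetSpec(3.0, contrast=0.3), 11)
        row = ein.respond_localization(stim, 0)
        dec = obs.localize(obs.localization_score(stim, tmpl))
        assert (row["response_y"], row["response_x"]) == dec.location

    def test_efficiency_recovery_within_3se(self, noise_b1, target3, lut_b1):
        """Full pipeline (simulate -> PC -> LUT inversion -> eta) recovers
        the exact 1/(1+gamma^2) efficiency of the degraded observer."""
        gamma = 1.0
        ein = EquivalentInputNoiseObserver(
            spectrum=fl.build_spectrum(noise_b1), target=target3, gamma=gamma)
        c_obs = lut_b1.invert(0.8) * np.sqrt(1 + gamma**2)
        ts = run_experiment("localization", ein, noise_b1, 3.0, [c_obs],
                            1500, seed=21, store_noise=False)
        est = fl.EfficiencyModel(ts.frame, lut=lut_b1).fit()
        assert abs(est.eta - ein.efficiency) < 3 * est.se


class TestRunExperiment:
    def test_design_counts_and_sessions(self, noise_b1, target3):
        model = LinearObserver(template=io_template(noise_b1, target3))
        ts = run_experiment("localization", model, noise_b1, 3.0,
                            [0.1, 0.3], 100, seed=5, block_size=50,
                            store_noise=False)
        assert len(ts) == 200
        counts = ts.frame.groupby(["contrast", "session"]).size()
        assert set(counts) == {50}
        assert ts.frame.groupby("contrast").size().tolist() == [100, 100]

    def test_reproducible_from_seed(self, noise_b1, target3):
        model = LinearObserver(template=io_template(noise_b1, target3))
        a = run_experiment("localization", model, noise_b1, 3.0, [0.2], 30,
                           seed=6)
        b = run_experiment("localization", model, noise_b1, 3.0, [0.2], 30,
                           seed=6)
        assert a.frame.equals(b.frame)
        assert np.array_equal(a.noise, b.noise)

    def test_two_seeds_compatible_estimates(self, noise_b1, target3):
        model = LinearObserver(template=io_template(noise_b1, target3))
        pcs = [run_experiment("localization", model, noise_b1, 3.0, [0.3],
                              600, seed=s, store_noise=False
                              ).frame["correct"].mean() for s in (1, 2)]
        assert abs(pcs[0] - pcs[1]) < 3 * np.sqrt(2 * 0.25 / 600)


class TestFixedTemplateSignature:
    def test_nonadapting_observer_efficiency_peaks_at_beta2(self, target3):
        """A fixed beta=2-tuned template yields highest efficiency in the
        beta=2 background and lowest in white noise (ordering check)."""
        etas = {}
        for beta in (0.0, 2.0, 3.0):
            noise = NoiseSpec(beta=beta, shape=64)
            model = LinearObserver(template=mismatched_template(
                noise, target3, "fixed-beta", fixed_beta=2.0))
            etas[beta] = analytic_linear_efficiency(model)
        assert etas[2.0] == pytest.approx(1.0, rel=1e-9)
        assert etas[2.0] > etas[3.0] > etas[0.0]
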