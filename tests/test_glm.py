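"""First-level GLM: HRF, DVARS scrubbing, OLS fitting, contrast maps."""

import numpy as np
import pandas as pd
import pytest

from columnscope import glm
from columnscope import synthetic as syn


class TestCanonicalHrf:
    def test_vanishes_at_zero(self):
        assert glm.canonical_hrf(0.1)[0] == 0.0

    def test_peaks_between_5_and_6_seconds(self):
        dt = 0.1
        hrf = glm.canonical_hrf(dt)
        assert 5.0 <= np.argmax(hrf) * dt <= 6.0
        assert hrf.max() == 1.0

    def test_refinement_stability(self):
        coarse = glm.canonical_hrf(1.0)
        fine = glm.canonical_hrf(0.1)
        np.testing.assert_allclose(coarse, fine[::10], atol=1e-3)


class TestDvars:
    def test_constant_series_has_zero_dvars(self):
        qc = glm.dvars_outliers(np.ones((10, 4)))
        np.testing.assert_allclose(qc.dvars[1:], 0.0)
        assert not qc.flags.any()
        assert np.isnan(qc.dvars[0])

    def test_hand_computed_rms_differences(self):
        series = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        qc = glm.dvars_outliers(series)
        np.testing.assert_allclose(qc.dvars[1:], [0.0, 10.0, 10.0])

    def test_isolated_spike_flags_its_two_transitions(self):
        series = np.zeros((20, 5))
        series[10] = 50.0
        qc = glm.dvars_outliers(series)
        assert list(np.flatnonzero(qc.flags)) == [10, 11]

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            glm.dvars_outliers(np.ones((1, 3)))


class TestFitGlm:
    def test_closed_form_two_regressor_ols(self):
        x = glm.DesignMatrix(
            matrix=np.column_stack([np.ones(3), [0.0, 1.0, 2.0]]),
            names=["intercept", "slope"], condition_names=[])
        fit = glm.fit_glm(np.array([[1.0], [2.0], [3.0]]), x)
        np.testing.assert_allclose(fit.betas.ravel(), [1.0, 1.0], atol=1e-12)

    def test_noise_free_amplitude_recovery(self, small_labels):
        events, n_tp = syn.block_design(seed=3)
        amps = {"approach": {"PA": 2.0, "PW": 0.5},
                "withdrawal": {"PA": 0.5, "PW": 2.0}}
        run = syn.simulate_bold_run(small_labels, events, n_tp, amps,
                                    noise_sd=0.0)
        design = glm.build_design_matrix(run.events, n_tp, run.tr)
        fit = glm.fit_glm(run.flat_series(), design)
        pa = small_labels.mask("PA").ravel()
        i_app = design.column("cond:approach")
        i_wdr = design.column("cond:withdrawal")
        np.testing.assert_allclose(fit.betas[i_app, pa], 2.0, atol=1e-8)
        np.testing.assert_allclose(fit.betas[i_wdr, pa], 0.5, atol=1e-8)

    def test_spike_regressor_equals_timepoint_deletion(self, rng):
        n, k_spike = 40, 17
        x_base = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (x_base @ np.array([1.0, 2.0]) + rng.standard_normal(n))
        y = y.reshape(-1, 1)
        flags = np.zeros(n, bool)
        flags[k_spike] = True
        spike = np.zeros((n, 1))
        spike[k_spike] = 1.0
        design = glm.DesignMatrix(np.hstack([x_base, spike]),
                                  ["b0", "b1", "spike"], [])
        fit = glm.fit_glm(y, design)
        keep = ~flags
        deleted = np.linalg.lstsq(x_base[keep], y[keep], rcond=None)[0]
        np.testing.assert_allclose(fit.betas[:2], deleted, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, small_labels, rng):
        events, n_tp = syn.block_design(seed=1)
        run = syn.simulate_bold_run(small_labels, events, n_tp,
                                    {"approach": {"PA": 1.0}},
                                    noise_sd=1.0, seed=5)
        design = glm.build_design_matrix(run.events, n_tp, run.tr,
                                         motion=run.motion)
        fit = glm.fit_glm(run.flat_series(), design)
        resid = run.flat_series() - design.matrix @ fit.betas
        gram = design.matrix.T @ resid
        assert np.abs(gram).max() < 1e-6

    def test_rank_deficiency_names_columns(self):
        x = np.column_stack([np.ones(5), np.ones(5)])
        design = glm.DesignMatrix(x, ["a", "a_copy"], [])
        with pytest.raises(ValueError, match="a_copy"):
            glm.fit_glm(np.random.default_rng(0).standard_normal((5, 2)),
                        design)


class TestContrastMap:
    @pytest.fixture(scope="class")
    def fitted(self):
        labels = syn.plant_columns(syn.make_sheet(32, 32, 0.5),
                                   {"PA": 0.8, "PW": 0.8}, seed=2)
        events, n_tp = syn.block_design(seed=2)
        # amplitude difference 1.5, noise 0.15: 20 dB amplitude SNR
        amps = {"approach": {"PA": 2.0, "PW": 0.5},
                "withdrawal": {"PA": 0.5, "PW": 2.0}}
        run = syn.simulate_bold_run(labels, events, n_tp, amps,
                                    noise_sd=0.15, seed=8)
        design = glm.build_design_matrix(run.events, n_tp, run.tr)
        return labels, design, glm.fit_glm(run.flat_series(), design)

    def test_self_contrast_is_zero(self, fitted):
        _, design, fit = fitted
        c = design.condition_contrast("approach", "approach")
        cmap = glm.contrast_map(fit, c)
        np.testing.assert_allclose(cmap.t, 0.0)
        np.testing.assert_allclose(cmap.signed_logp, 0.0)

    def test_antisymmetric_under_sign_swap(self, fitted):
        _, design, fit = fitted
        fwd = glm.contrast_map(fit, design.condition_contrast(
            "approach", "withdrawal"))
        rev = glm.contrast_map(fit, design.condition_contrast(
            "withdrawal", "approach"))
        np.testing.assert_allclose(fwd.signed_logp, -rev.signed_logp)
        np.testing.assert_allclose(fwd.t, -rev.t)

    def test_signed_map_magnitude_is_neg_log10_p(self, fitted):
        _, design, fit = fitted
        cmap = glm.contrast_map(fit, design.condition_contrast(
            "approach", "withdrawal"))
        np.testing.assert_allclose(np.abs(cmap.signed_logp),
                                   -np.log10(cmap.p))
        assert np.all(np.sign(cmap.signed_logp[cmap.beta != 0])
                      == np.sign(cmap.beta[cmap.beta != 0]))

    def test_sign_classification_recovers_ground_truth(self, fitted):
        labels, design, fit = fitted
        cmap = glm.contrast_map(fit, design.condition_contrast(
            "approach", "withdrawal")).reshape(labels.shape)
        pa, pw = labels.mask("PA"), labels.mask("PW")
        correct = ((cmap.signed_logp[pa] > 0).sum()
                   + (cmap.signed_logp[pw] < 0).sum())
        assert correct / (pa.sum() + pw.sum()) >= 0.95

    def test_wrong_contrast_length_rejected(self, fitted):
        _, _, fit = fitted
        with pytest.raises(ValueError):
            glm.contrast_map(fit, np.ones(2))
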