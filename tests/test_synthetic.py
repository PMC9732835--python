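"""Ground-truth generator: column planting, rendering, BOLD runs, behavior."""

import numpy as np
import pandas as pd
import pytest

from columnscope import columnarity, glm
from columnscope import synthetic as syn


class TestPlantColumns:
    def test_same_seed_gives_identical_maps(self, small_sheet):
        a = syn.plant_columns(small_sheet, 0.7, seed=42)
        b = syn.plant_columns(small_sheet, 0.7, seed=42)
        assert np.array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.centers, b.centers)

    def test_label_masks_are_pairwise_disjoint(self, small_labels):
        masks = [small_labels.mask(lab) for lab in syn.COLUMN_LABELS]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert not np.any(masks[i] & masks[j])
        for lab in syn.COLUMN_LABELS:
            assert small_labels.mask(lab).any()

    def test_zero_density_family_absent(self, small_sheet):
        labels = syn.plant_columns(small_sheet, {"PA": 0.8, "PW": 0.8},
                                   seed=1)
        assert labels.mask("PA").any() and labels.mask("PW").any()
        assert not labels.mask("DN").any() and not labels.mask("DF").any()

    def test_infeasible_packing_raises(self, small_sheet):
        with pytest.raises(RuntimeError, match="pack"):
            syn.plant_columns(small_sheet, 20.0, (3.0, 4.0), seed=0,
                              max_tries_per_column=50)

    def test_radius_must_exceed_spacing(self, small_sheet):
        with pytest.raises(ValueError):
            syn.plant_columns(small_sheet, 0.5, (0.2, 0.3), seed=0)


class TestRenderVolume:
    def test_radial_uniformity_noiseless(self, small_sheet, small_labels):
        vol = syn.render_volume(small_labels, small_sheet,
                                {"PA": 1.0, "PW": -1.0}, noise_sd=0.0)
        shallow = columnarity.sample_depth_map(vol, frac=0.1)
        deep = columnarity.sample_depth_map(vol, frac=0.9)
        np.testing.assert_allclose(shallow, deep)

    def test_above_pia_carries_only_vessel_pattern(self, small_sheet,
                                                   small_labels):
        vessel = syn.make_vessel_layer(small_sheet, seed=3)
        vol = syn.render_volume(small_labels, small_sheet, {"PA": 1.0},
                                vessel=vessel, noise_sd=0.0)
        above = columnarity.sample_depth_map(vol, mm=-1.9)
        np.testing.assert_allclose(above, vessel.pattern)

    def test_noise_sd_recovered(self, small_sheet, small_labels):
        vol = syn.render_volume(small_labels, small_sheet, {}, noise_sd=1.0,
                                seed=0)
        assert vol.data.std() == pytest.approx(1.0, rel=0.02)

    def test_vessel_decorrelated_from_columns(self, small_sheet, small_labels):
        p_pattern = (small_labels.mask("PA").astype(float)
                     - small_labels.mask("PW").astype(float))
        for seed in range(5):
            vessel = syn.make_vessel_layer(small_sheet,
                                           decorrelate_from=p_pattern,
                                           seed=seed)
            r = np.corrcoef(vessel.pattern.ravel(), p_pattern.ravel())[0, 1]
            assert abs(r) < 1e-10


class TestBoldRun:
    def test_silent_run_is_constant_baseline(self, small_labels):
        events, n_tp = syn.block_design(seed=0)
        run = syn.simulate_bold_run(small_labels, events, n_tp,
                                    amplitudes={}, noise_sd=0.0,
                                    baseline=100.0)
        np.testing.assert_allclose(run.series, 100.0)

    def test_single_event_equals_scaled_shifted_hrf(self, small_labels):
        tr = 3.0
        events = pd.DataFrame({"onset": [9.0], "duration": [3.0],
                               "condition": ["a"]})
        n_tp = 30
        amp = 2.5
        run = syn.simulate_bold_run(
            small_labels, events, n_tp,
            {"a": {lab: amp for lab in syn.COLUMN_LABELS}},
            noise_sd=0.0, baseline=0.0)
        hrf = glm.canonical_hrf(tr)
        boxcar = np.zeros(n_tp)
        boxcar[3:4] = 1.0
        expected = amp * np.convolve(boxcar, hrf)[:n_tp]
        vert = run.series[:, small_labels.mask("PA")][:, 0]
        np.testing.assert_allclose(vert, expected)

    def test_design_overrun_raises(self, small_labels):
        events = pd.DataFrame({"onset": [260.0], "duration": [15.0],
                               "condition": ["a"]})
        with pytest.raises(ValueError, match="overrun"):
            syn.simulate_bold_run(small_labels, events, 90, {})

    def test_block_design_bookkeeping(self):
        events, n_tp = syn.block_design(seed=5)
        assert n_tp == 90
        # segments tile the run: leading blank + 16 blocks + trailing blank
        assert len(events) == 16
        total = events["duration"].sum() + 2 * 15.0
        assert total == n_tp * 3.0
        assert (events["onset"] + events["duration"] <= n_tp * 3.0).all()

    def test_disparity_design_pads_final_blank(self):
        events, n_tp = syn.disparity_block_design(seed=5)
        assert n_tp == 80
        nominal = events["duration"].sum() + 2 * 12.0
        assert nominal == 216.0
        assert n_tp * 3.0 > nominal  # padded

    def test_event_design_respects_iti_bounds(self):
        events, n_tp = syn.event_design(["a", "b"], 5, seed=2)
        gaps = np.diff(events["onset"]) - events["duration"].to_numpy()[:-1]
        assert (gaps >= 3.0 - 1e-9).all() and (gaps <= 12.0 + 1e-9).all()
        assert (events["onset"] + events["duration"] <= n_tp * 3.0).all()

    def test_spike_is_flagged_by_dvars(self, small_labels):
        events, n_tp = syn.block_design(seed=0)
        run = syn.simulate_bold_run(
            small_labels, events, n_tp,
            {"approach": {"PA": 1.0}, "withdrawal": {"PW": 1.0}},
            noise_sd=0.3, spikes=[(40, 8.0)], seed=1)
        qc = glm.dvars_outliers(run.flat_series())
        assert qc.flags[40] and qc.flags[41]
        assert not qc.flags[0]


class TestSDPTrials:
    def test_zero_sd_gives_constant_trials(self):
        t = syn.simulate_sdp_trials(57.0, 0.0, 5, seed=0)
        assert np.all(t.trials == 57.0)
        assert len(t.usable()) == 5  # warm-up excluded from the 6 draws

    def test_seed_determinism(self):
        a = syn.simulate_sdp_trials(60.0, 10.0, 8, seed=9)
        b = syn.simulate_sdp_trials(60.0, 10.0, 8, seed=9)
        np.testing.assert_array_equal(a.trials, b.trials)

    def test_parameter_recovery_at_large_n(self):
        t = syn.simulate_sdp_trials(57.0, 11.3, 4000, seed=3)
        u = t.usable()
        assert u.mean() == pytest.approx(57.0, abs=3 * 11.3 / np.sqrt(4000))
        assert u.std(ddof=1) == pytest.approx(11.3, rel=0.05)
        assert (u > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.simulate_sdp_trials(-5.0, 1.0, 5)
        with pytest.raises(ValueError):
            syn.simulate_sdp_trials(57.0, 1.0, 1)
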