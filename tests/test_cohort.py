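"""Synthetic-cohort generator: stimuli, scanpaths, calibration helpers."""

import math

import numpy as np
import pandas as pd
import pytest

from gazesal.cohort import (
    CohortConfig,
    GroupParams,
    StimulusSpec,
    calibrate_duration_curve,
    count_pmf,
    duration_curve,
    expected_mean_duration,
    expected_sdd,
    generate_cohort,
    generate_scanpath,
    generate_stimulus_set,
    render_stimulus,
    sigma_for_target_sdd,
    simulate_duration_table,
    study_group_params,
)


def _params(**kw):
    base = dict(group_label="HC", n_fix_mean=9.0, n_fix_sd=1.0,
                dur_baseline_ms=240.0, dur_peak_ms=290.0, dur_peak_index=5,
                dur_converge_index=15, dur_converge_ms=290.0,
                dur_noise_sd_ms=0.0, dur_subject_sd_ms=0.0)
    base.update(kw)
    return GroupParams(**base)


# ---------------------------------------------------------------------------
# Stimulus sets
# ---------------------------------------------------------------------------


class TestStimulusSet:
    def test_default_set_is_balanced(self):
        specs = generate_stimulus_set(CohortConfig())
        assert len(specs) == 250
        per_cat = pd.Series([s.category for s in specs]).value_counts()
        assert (per_cat == 50).all() and len(per_cat) == 5

    def test_single_category(self):
        cfg = CohortConfig(n_stimuli=2, categories=("congruent",))
        specs = generate_stimulus_set(cfg)
        assert len(specs) == 2
        assert all(s.category == "congruent" for s in specs)

    def test_indivisible_count_errors_with_remainder(self):
        cfg = CohortConfig(n_stimuli=7, categories=("congruent", "incongruent"))
        with pytest.raises(ValueError, match="remainder 1"):
            generate_stimulus_set(cfg)

    def test_same_seed_identical(self):
        cfg = CohortConfig(n_stimuli=10)
        assert generate_stimulus_set(cfg, 5) == generate_stimulus_set(cfg, 5)

    def test_salient_region_required_for_salient_category(self):
        with pytest.raises(ValueError, match="salient_region"):
            StimulusSpec("x", "physically_salient", 100, 100, (), None, 0)


class TestRenderStimulus:
    SPEC = StimulusSpec("s", "physically_salient", 320, 180, (),
                        (240.0, 90.0, 30.0, 2.5), 7)

    def test_salient_region_has_elevated_rms_contrast(self):
        img = render_stimulus(self.SPEC)
        gray = img.mean(axis=2)
        yy, xx = np.mgrid[0:180, 0:320]
        inside = (xx - 240) ** 2 + (yy - 90) ** 2 <= 30**2
        rms_in = gray[inside].std()
        rms_out = gray[~inside].std()
        assert rms_in > 2 * rms_out

    def test_plain_texture_in_range(self):
        spec = StimulusSpec("p", "congruent", 64, 64, (), None, 3)
        img = render_stimulus(spec)
        assert img.shape == (64, 64, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_deterministic(self):
        np.testing.assert_array_equal(render_stimulus(self.SPEC),
                                      render_stimulus(self.SPEC))


# ---------------------------------------------------------------------------
# Scanpaths
# ---------------------------------------------------------------------------


class TestGenerateScanpath:
    def test_count_recovery_at_printed_hc_parameters(self, rng):
        # fixation counts should average to the configured mean (9.22)
        params = _params(n_fix_mean=9.22, n_fix_sd=0.75)
        uniform = np.full((8, 8), 1 / 64)
        counts = [len(generate_scanpath(None, uniform, uniform, params, 1e9, rng,
                                        center_bias_weight=0.0))
                  for _ in range(10_000)]
        mean, se = np.mean(counts), np.std(counts) / math.sqrt(len(counts))
        assert abs(mean - 9.22) < 3 * se + 0.01  # rounding bias is < 1%

    def test_degenerate_mixture_confines_fixations_to_disk(self, rng):
        h = w = 32
        yy, xx = np.mgrid[0:h, 0:w]
        disk = ((xx - 8) ** 2 + (yy - 8) ** 2 <= 36).astype(float)
        params = _params(w_bottomup_early=1.0, w_bottomup_late=1.0)
        path = generate_scanpath(None, disk, disk, params, 1e9, rng,
                                 screen_w=w, screen_h=h, center_bias_weight=0.0)
        cells_x = path["x_px"].to_numpy().astype(int)
        cells_y = path["y_px"].to_numpy().astype(int)
        assert disk[cells_y, cells_x].all()

    def test_truncation_floor_yields_one_fixation(self, rng):
        params = _params(n_fix_mean=0.1, n_fix_sd=0.1)
        uniform = np.full((8, 8), 1 / 64)
        for _ in range(50):
            path = generate_scanpath(None, uniform, uniform, params, 1e9, rng)
            assert len(path) == 1

    def test_all_zero_maps_error(self, rng):
        zero = np.zeros((8, 8))
        with pytest.raises(ValueError, match="zero"):
            generate_scanpath(None, zero, zero, _params(), 1e9, rng)

    def test_cumulative_duration_capped(self, rng):
        params = _params(n_fix_mean=30, n_fix_sd=0.1)
        uniform = np.full((8, 8), 1 / 64)
        path = generate_scanpath(None, uniform, uniform, params, 1000.0, rng)
        assert path["duration_ms"].sum() <= 1000.0 or len(path) == 1


class TestGenerateCohort:
    def test_trial_grid_and_labels(self):
        cfg = CohortConfig(n_schz=1, n_hc=0, n_stimuli=5,
                           categories=("congruent",), map_w=40, map_h=24)
        table, specs, maps = generate_cohort(cfg)
        assert table.groupby(["subject_id", "stimulus_id"]).ngroups == 5
        assert (table["group"] == "SCHZ").all()
        assert len(specs) == 5 and len(maps) == 5

    def test_same_seed_reproduces_table(self):
        cfg = CohortConfig(n_schz=2, n_hc=1, n_stimuli=4,
                           categories=("congruent", "incongruent"),
                           seed=9, map_w=40, map_h=24)
        t1, _, _ = generate_cohort(cfg)
        t2, _, _ = generate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_start_cross_prepended_each_trial(self, small_cohort):
        _, table, _, _ = small_cohort
        per_trial = table.groupby(["subject_id", "stimulus_id"])["is_start_cross"]
        assert (per_trial.sum() == 1).all()
        firsts = table[table["fix_index"] == 1]
        assert firsts["is_start_cross"].all()

    def test_default_config_dimensions(self):
        # full-size cohort: 53 subjects x 250 stimuli (coarse sampling lattice
        # to keep the check cheap; the trial grid is what is under test)
        cfg = CohortConfig(map_w=48, map_h=27)
        table, specs, _ = generate_cohort(cfg)
        assert len(specs) == 250
        assert table["subject_id"].nunique() == 53
        assert table.groupby(["subject_id", "stimulus_id"]).ngroups == 53 * 250


# ---------------------------------------------------------------------------
# Duration curve and calibration
# ---------------------------------------------------------------------------


class TestDurationModel:
    def test_curve_shape_piecewise_linear(self):
        p = _params(dur_baseline_ms=200, dur_peak_ms=400, dur_peak_index=5,
                    dur_converge_index=15, dur_converge_ms=300)
        k = np.arange(1, 21)
        c = duration_curve(p, k)
        assert c[0] == 200 and c[4] == 400 and c[14] == 300
        assert np.allclose(np.diff(c[:5]), 50)  # linear rise
        assert np.allclose(c[15:], 300)  # flat after convergence

    def test_expected_mean_duration_matches_brute_force(self, rng):
        p = _params()
        K = np.maximum(1, np.rint(rng.normal(p.n_fix_mean, p.n_fix_sd, 400_000))).astype(int)
        curve = duration_curve(p, np.arange(1, K.max() + 1))
        csum = np.concatenate([[0.0], np.cumsum(curve)])
        brute = csum[K].sum() / K.sum()
        assert abs(expected_mean_duration(p) - brute) < 0.2

    def test_calibration_hits_target(self):
        p = calibrate_duration_curve(_params(), 326.12)
        assert abs(expected_mean_duration(p) - 326.12) < 1e-9

    def test_count_pmf_sums_to_one(self):
        assert abs(count_pmf(8.92, 1.28).sum() - 1.0) < 1e-12

    def test_index_means_recover_curve_and_groups_converge(self, rng):
        # averaged durations per index reproduce the configured curves; the
        # SCHZ curve exceeds HC before the convergence index and matches after
        gp = {g: p.replace(dur_subject_sd_ms=0.0)
              for g, p in study_group_params().items()}
        tab = simulate_duration_table(gp, {"SCHZ": 40, "HC": 40}, 60, rng)
        mean_by = (tab.groupby(["group", "fix_index"])
                   .apply(lambda d: np.average(d["mean_duration_ms"],
                                               weights=d["n_trials"]),
                          include_groups=False).unstack(0))
        for g in ("SCHZ", "HC"):
            expect = duration_curve(gp[g], mean_by.index.to_numpy())
            got = mean_by[g].to_numpy()
            ok = ~np.isnan(got)
            assert np.allclose(got[ok][:10], expect[ok][:10], atol=6.0)
        both = mean_by.dropna()
        k = both.index.to_numpy()
        pre = (k >= 1) & (k < gp["SCHZ"].dur_converge_index - 1)
        assert (both["SCHZ"][pre] > both["HC"][pre]).all()


class TestSpatialCalibration:
    def test_expected_sdd_closed_form_without_bounds(self):
        assert expected_sdd(500.0) == pytest.approx(500.0 * math.sqrt(2))
        assert sigma_for_target_sdd(700.0) == pytest.approx(700.0 / math.sqrt(2))

    def test_truncation_aware_inverse_roundtrips(self):
        s = sigma_for_target_sdd(727.56, 3840, 2160)
        assert expected_sdd(s, 3840, 2160) == pytest.approx(727.56, abs=1e-6)
        # truncation requires a larger per-axis sigma than the naive inverse
        assert s > 727.56 / math.sqrt(2)

    def test_study_defaults_reproduce_printed_summaries(self):
        gp = study_group_params()
        assert gp["SCHZ"].n_fix_mean == 8.92
        assert expected_mean_duration(gp["SCHZ"]) == pytest.approx(326.12)
        assert expected_mean_duration(gp["HC"]) == pytest.approx(254.83)
        assert expected_sdd(gp["HC"].spread_sd_px, 3840, 2160) == pytest.approx(727.56)
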