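"""Synthetic cohort generator: geometry, signals, feature-level mode,
amplitude calibration unit behavior."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

from ccepflow.calibrate import (
    calibrate_amplitudes,
    collect_geometry_stats,
)
from ccepflow.cohort import generate_feature_cohort
from ccepflow.config import CohortConfig, EvokedModel, default_amp_by_class
from ccepflow.errors import CalibrationError, InvalidConfigError
from ccepflow.geometry import generate_geometry, sample_shaft_count
from ccepflow.pipeline import run_signal_patient
from ccepflow.schema import GROUPS, PREDICTOR_COLUMNS
from ccepflow.signal_sim import attach_acquisition_meta, simulate_ccep_session
from ccepflow.targets import ClinicalParams, FeatureTargets


class TestGeometry:
    def test_deterministic_given_seed(self, reduced_cfg):
        g1 = generate_geometry(reduced_cfg, 77, "SF")
        g2 = generate_geometry(reduced_cfg, 77, "SF")
        pd.testing.assert_frame_equal(g1.contact_table(), g2.contact_table())
        np.testing.assert_array_equal(g1.gm.values, g2.gm.values)
        np.testing.assert_array_equal(g1.resection.values, g2.resection.values)
        assert g1.soz_channel_ids == g2.soz_channel_ids

    def test_shaft_count_distribution_matches_cohort(self):
        """Mean electrode count 11.96 +/- 2.00, clipped to [4, 16]."""
        cfg = CohortConfig()
        rng = np.random.default_rng(0)
        draws = [sample_shaft_count(cfg, rng) for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(11.96, abs=0.2)
        assert min(draws) >= 4 and max(draws) <= 16

    def test_full_geometry_reports_sampled_shaft_count(self, reduced_cfg):
        counts = [
            generate_geometry(reduced_cfg, 900 + i, "SF").meta["n_shafts"]
            for i in range(12)
        ]
        assert all(reduced_cfg.shafts_range[0] <= c <= reduced_cfg.shafts_range[1]
                   for c in counts)

    def test_resection_voxel_count_tracks_target_volume(self):
        cfg = CohortConfig.reduced(resection_volume_sd_cm3=0.0)
        geom = generate_geometry(cfg, 5, "SF")
        assert geom.meta["resection_volume_cm3"] == pytest.approx(17.08)
        assert abs(geom.meta["resection_voxels"] - 17080) <= 0.2 * 17080

    def test_contact_pitch_respected(self, small_geometry):
        tab = small_geometry.contact_table()
        for _, shaft in tab.groupby("shaft"):
            xyz = shaft.sort_values("contact_index")[["x_mm", "y_mm", "z_mm"]].to_numpy()
            steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
            np.testing.assert_allclose(steps, 3.5, rtol=0.10)

    def test_too_few_contacts_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(contacts_range=(1, 1)).validate()

    def test_zone_guarantees(self, small_geometry):
        lab = small_geometry.labels
        assert lab["is_soz"].sum() == 1
        assert bool(lab.loc[lab["is_soz"], "in_resection"].all())
        for sel in (
            lab["is_soz"] & lab["is_gray"],
            lab["in_resection"] & ~lab["is_soz"] & lab["is_gray"],
            ~lab["in_resection"] & lab["is_gray"],
        ):
            assert sel.any()


class TestSignalSimulation:
    def test_default_protocol_gives_40_trials(self, small_geometry, stim_cfg, evoked_model):
        ep = simulate_ccep_session(
            small_geometry, stim_cfg, evoked_model, "SF", seed=1, stim_index=0
        )
        assert ep.n_trials == 40
        assert ep.data.shape[1] == len(small_geometry.contacts)
        assert ep.data.shape[2] == int(1.5 * small_geometry.meta["raw_fs_hz"])

    def test_deterministic_given_seed(self, small_geometry, stim_cfg, evoked_model):
        a = simulate_ccep_session(small_geometry, stim_cfg, evoked_model, "SF", 5, 2)
        b = simulate_ccep_session(small_geometry, stim_cfg, evoked_model, "SF", 5, 2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_null_signal_is_identically_zero(self, small_geometry, stim_cfg):
        silent = replace(
            EvokedModel(),
            noise_sd_uv=0.0,
            line_amp_uv=0.0,
            artifact_amp_uv=0.0,
            amp_by_class=default_amp_by_class(0.0, 0.0),
        )
        ep = simulate_ccep_session(small_geometry, stim_cfg, silent, "SF", 1, 0)
        assert np.abs(ep.data).max() == 0.0

    def test_pipeline_n1_rms_matches_template_oracle(self, small_geometry, stim_cfg):
        """Noise-free run: the measured N1 RMS equals the RMS of the
        amplitude-scaled template pushed through an independent filter path."""
        A = 37.0
        ev = replace(
            EvokedModel(),
            noise_sd_uv=0.0,
            line_amp_uv=0.0,
            artifact_amp_uv=0.0,
            amp_cv=0.0,
            patient_class_jitter=0.0,
            amp_by_class={g: {c: (A, 0.0) for c in default_amp_by_class()[g]}
                          for g in GROUPS},
        )
        from ccepflow.features import rms
        from ccepflow.preprocess import filter_cascade, preprocess_signals
        from ccepflow.schema import N1_WINDOW_MS
        from ccepflow.signal_sim import bipolar_contact_pairs, evoked_templates

        ep = simulate_ccep_session(small_geometry, stim_cfg, ev, "SF", seed=3,
                                   stim_index=0, collapse_trials=True)
        pairs = bipolar_contact_pairs(small_geometry)
        fs = small_geometry.meta["raw_fs_hz"]
        cleaned = preprocess_signals(ep.data, fs, 50.0, pairs)[0]
        t_out = -500.0 + np.arange(cleaned.shape[-1])
        base = (t_out >= -500) & (t_out < -10)
        cleaned = cleaned - cleaned[:, base].mean(axis=1, keepdims=True)
        measured = np.array([rms(cleaned[ch], N1_WINDOW_MS) for ch in range(5)
                             if ch != 0])
        _, t1, _, _ = evoked_templates(ev, fs, int(1.5 * fs), -500.0)
        sos = filter_cascade(fs, small_geometry.meta["line_freq_hz"])
        u = sp_signal.sosfiltfilt(sos, A * t1)[::2]
        t_ms = -500.0 + np.arange(u.size)
        u = u - u[(t_ms >= -500) & (t_ms < -10)].mean()
        expected = np.sqrt(np.mean(u[(t_ms >= 10) & (t_ms < 50)] ** 2))
        np.testing.assert_allclose(measured, expected, rtol=0.03)

    def test_incompatible_evoked_window_rejected(self, small_geometry, stim_cfg):
        bad = replace(EvokedModel(), n2_center_ms=240.0)  # template energy ok
        bad2 = replace(bad, n2_center_ms=990.0)  # beyond the 1000 ms epoch tail
        simulate_ccep_session(small_geometry, stim_cfg, bad, "SF", 1, 0,
                              collapse_trials=True)
        with pytest.raises(InvalidConfigError):
            EvokedModel(n2_center_ms=990.0).validate()
        with pytest.raises(InvalidConfigError):
            simulate_ccep_session(small_geometry, stim_cfg,
                                  replace(EvokedModel(), n2_width_ms=900.0),
                                  "SF", 1, 0)

    def test_collapsed_trials_match_full_simulation_statistically(self, stim_cfg):
        """The 1/sqrt(n_trials) collapsed mode reproduces the trial-averaged
        edge RMS distribution of the full 40-trial simulation."""
        cfg = CohortConfig.reduced(shafts_mean=4, shafts_sd=0.0, shafts_range=(4, 4))
        ev = EvokedModel()
        pooled = {}
        for mode in (True, False):
            vals = []
            for i in range(2):
                geom = generate_geometry(cfg, 3000 + i, "SF")
                attach_acquisition_meta(geom, cfg)
                _, edges = run_signal_patient(
                    geom, stim_cfg, ev, "SF", seed=4000 + i, collapse_trials=mode
                )
                vals.append(edges["rms_N1"].to_numpy())
            pooled[mode] = np.concatenate(vals)
        m_c, m_f = pooled[True].mean(), pooled[False].mean()
        se = np.sqrt(pooled[True].var() / pooled[True].size
                     + pooled[False].var() / pooled[False].size)
        assert abs(m_c - m_f) <= 4 * se


class TestFeatureLevelCohort:
    def test_degenerate_sd_zero_reproduces_means_exactly(self):
        targets = FeatureTargets.default().with_sd_zero_replaced(0.0)
        table = generate_feature_cohort(
            CohortConfig(), targets, ClinicalParams.default(), seed=1
        )
        sf = table[table.outcome == "SF"]
        assert (sf["OR_N1_out"] == targets.feature_mean("OR_N1_out", "SF")).all()
        assert (sf["IO_N2_out"] == targets.feature_mean("IO_N2_out", "SF")).all()

    def test_gtcs_prevalence_matches_cohort_rates(self):
        cfg = CohortConfig(n_sf=5000, n_nsf=5000)
        table = generate_feature_cohort(
            cfg, FeatureTargets.default(), ClinicalParams.default(), seed=2
        )
        nsf = table[table.outcome == "nSF"]
        sf = table[table.outcome == "SF"]
        assert nsf["gtcs"].mean() == pytest.approx(18 / 26, abs=0.02)
        assert sf["gtcs"].mean() == pytest.approx(11 / 30, abs=0.02)

    def test_row_count_and_schema(self):
        table = generate_feature_cohort(
            CohortConfig(), FeatureTargets.default(), ClinicalParams.default(), seed=3
        )
        assert len(table) == 56
        assert list(table.columns[:-1]) == list(PREDICTOR_COLUMNS)

    def test_negative_sd_rejected(self):
        bad = FeatureTargets.default()
        bad.table[("OR", "N1", "out")]["SF"] = (0.72, -0.1)
        with pytest.raises(InvalidConfigError):
            generate_feature_cohort(
                CohortConfig(), bad, ClinicalParams.default(), seed=0
            )

    def test_age_distributions_respect_ranges(self):
        table = generate_feature_cohort(
            CohortConfig(n_sf=400, n_nsf=400), FeatureTargets.default(),
            ClinicalParams.default(), seed=4
        )
        sf = table[table.outcome == "SF"]
        assert sf["age_onset"].between(0.5, 26.0).all()
        assert sf["age_onset"].median() == pytest.approx(11.8, abs=1.5)
        nsf = table[table.outcome == "nSF"]
        assert nsf["duration"].between(2.5, 32.0).all()

    def test_determinism(self):
        a = generate_feature_cohort(CohortConfig(), FeatureTargets.default(),
                                    ClinicalParams.default(), seed=5)
        b = generate_feature_cohort(CohortConfig(), FeatureTargets.default(),
                                    ClinicalParams.default(), seed=5)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def surrogate_stats(reduced_cfg, stim_cfg, evoked_model):
    return collect_geometry_stats(reduced_cfg, stim_cfg, evoked_model,
                                  seed=0, n_patients=12)


class TestCalibrationUnit:
    """Surrogate-only behavior (refine_rounds=0); the full-pipeline round trip
    is exercised by the acceptance suite."""

    def test_identical_targets_give_symmetric_amplitudes(self, surrogate_stats,
                                                         evoked_model):
        flat = FeatureTargets(
            table={k: {g: (1.2, 0.4) for g in GROUPS}
                   for k in FeatureTargets.default().table}
        )
        amps, _ = calibrate_amplitudes(flat, surrogate_stats, evoked=evoked_model,
                                       seed=0, refine_rounds=0)
        from ccepflow.calibrate import FEATURE_CLASSES

        for g in GROUPS:
            for comp_i in (0, 1):
                vals = [amps[g][c][comp_i] for c in FEATURE_CLASSES]
                assert max(vals) / min(vals) < 1.35

    def test_raising_one_target_raises_its_class_amplitude(self, surrogate_stats,
                                                           evoked_model):
        base = FeatureTargets.default()
        amps0, _ = calibrate_amplitudes(base, surrogate_stats, evoked=evoked_model,
                                        seed=0, refine_rounds=0)
        bumped = FeatureTargets.default()
        m, s = bumped.table[("IO", "N1", "out")]["nSF"]
        bumped.table[("IO", "N1", "out")]["nSF"] = (m + 0.15, s)
        amps1, _ = calibrate_amplitudes(bumped, surrogate_stats, evoked=evoked_model,
                                        seed=0, refine_rounds=0)
        # the ir->or N1 amplitude carries the IO-out target
        assert amps1["nSF"][("ir", "or")][0] > amps0["nSF"][("ir", "or")][0] * 1.03
        # untouched group barely moves
        assert amps1["SF"][("ir", "or")][0] == pytest.approx(
            amps0["SF"][("ir", "or")][0], rel=0.05
        )

    def test_unreachable_target_raises_with_residuals(self, surrogate_stats,
                                                      evoked_model):
        absurd = FeatureTargets.default()
        absurd.table[("IO", "N2", "out")]["nSF"] = (6.0, 1.0)
        with pytest.raises(CalibrationError) as err:
            calibrate_amplitudes(absurd, surrogate_stats, evoked=evoked_model,
                                 seed=0, refine_rounds=0, max_iter=40)
        assert err.value.residuals
        assert any(abs(v) > 0.1 for v in err.value.residuals.values())
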