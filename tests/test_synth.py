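"""Tests of the synthetic cohort generator: geometry, fields, rendering."""

import dataclasses

import numpy as np
import pytest

import preful3d as p
from preful3d import synth
from preful3d.config import CenterConfig


GRID64 = synth.Grid((64, 64, 64), (2.0, 2.0, 2.0))  # 8 mm^3 voxels


def _spec(**kw):
    base = dict(
        subject_id="S1", age=25.0, sex="F", center="C", breathing_frequency=15.0,
        tidal_volume_target=400.0, sv_mean=0.25, seed=3,
    )
    base.update(kw)
    return synth.SubjectSpec(**base)


class TestLungGeometry:
    def test_construction_masks_nested_and_vessels_inside(self):
        geo = synth.make_lung_geometry(_spec(lung_semiaxes=(30.0, 38.0, 55.0)), GRID64)
        assert geo.parenchyma_mask.any()
        assert geo.vessel_mask.any()
        assert np.all(~geo.vessel_mask | geo.parenchyma_mask)  # vessels in lungs
        assert np.all(~geo.exp_lung_mask | geo.insp_lung_mask)  # exp subset insp

    def test_tidal_volume_target_exact_voxel_count(self):
        # 400 mL at 8 mm^3 voxels = 50,000 voxels difference, within 1
        geo = synth.make_lung_geometry(_spec(lung_semiaxes=(30.0, 38.0, 55.0)), GRID64)
        diff = int(geo.insp_lung_mask.sum()) - int(geo.exp_lung_mask.sum())
        assert abs(diff - 50_000) <= 1

    def test_degenerate_semiaxes_raise(self):
        with pytest.raises(synth.GeometryError):
            synth.make_lung_geometry(_spec(lung_semiaxes=(0.0, 0.0, 0.0)), GRID64)

    def test_oversized_semiaxes_raise(self):
        with pytest.raises(synth.GeometryError):
            synth.make_lung_geometry(_spec(lung_semiaxes=(200.0, 50.0, 75.0)))


class TestVentilationField:
    def test_zero_heterogeneity_gives_constant_field(self):
        grid = synth.DEFAULT_GRID
        geo = synth.make_lung_geometry(_spec(), grid)
        prof = p.ScannerProfile("x", 1.5, snr=100.0, heterogeneity_scale=0.0)
        sv, defect = synth.sample_ventilation_field(
            _spec(), prof, geo.parenchyma_mask, grid, np.random.default_rng(0)
        )
        assert np.allclose(sv[geo.parenchyma_mask], 0.25)
        assert not defect.any()
        # rvent_true closed form: 0.25 / 1.25 = 0.2
        rvent = sv / (1.0 + sv)
        assert np.allclose(rvent[geo.parenchyma_mask], 0.2)

    def test_same_seed_identical_fields(self):
        grid = synth.DEFAULT_GRID
        geo = synth.make_lung_geometry(_spec(), grid)
        prof = p.ScannerProfile("x", 1.5, snr=100.0, heterogeneity_scale=1.0)
        sv1, _ = synth.sample_ventilation_field(
            _spec(), prof, geo.parenchyma_mask, grid, np.random.default_rng(7)
        )
        sv2, _ = synth.sample_ventilation_field(
            _spec(), prof, geo.parenchyma_mask, grid, np.random.default_rng(7)
        )
        np.testing.assert_array_equal(sv1, sv2)

    def test_negative_sv_mean_raises(self):
        grid = synth.DEFAULT_GRID
        geo = synth.make_lung_geometry(_spec(), grid)
        prof = p.ScannerProfile("x", 1.5, snr=100.0, heterogeneity_scale=1.0)
        with pytest.raises(synth.ParameterError):
            synth.sample_ventilation_field(
                _spec(sv_mean=-0.1), prof, geo.parenchyma_mask, grid,
                np.random.default_rng(0),
            )

    def test_defect_fraction_zeroes_requested_share(self):
        grid = synth.DEFAULT_GRID
        geo = synth.make_lung_geometry(_spec(), grid)
        prof = p.ScannerProfile("x", 1.5, snr=100.0, heterogeneity_scale=0.0)
        sv, defect = synth.sample_ventilation_field(
            _spec(defect_fraction=0.1), prof, geo.parenchyma_mask, grid,
            np.random.default_rng(0),
        )
        n_mask = int(geo.parenchyma_mask.sum())
        assert defect.sum() == round(0.1 * n_mask)
        assert np.all(sv[defect] == 0.0)

    def test_heterogeneity_monotonically_increases_field_cov(self):
        grid = synth.DEFAULT_GRID
        geo = synth.make_lung_geometry(_spec(), grid)
        covs = []
        for het in (0.5, 1.0, 1.5):
            prof = p.ScannerProfile("x", 1.5, snr=100.0, heterogeneity_scale=het)
            # same seed set: the underlying smooth field realization is shared
            sv, _ = synth.sample_ventilation_field(
                _spec(), prof, geo.parenchyma_mask, grid, np.random.default_rng(5)
            )
            rvent = sv / (1.0 + sv)
            vals = rvent[geo.parenchyma_mask]
            covs.append(vals.std() / vals.mean())
        assert covs[0] < covs[1] < covs[2]


class TestRendering:
    def test_signal_ratio_matches_dilution_model(self, noise_free_measurement):
        # S_exp / S_insp = 1 + sv = 1.25 for sv = 0.25
        m = noise_free_measurement
        img = m.images
        sig = img.data[m.analysis_mask]
        ratio = sig[:, img.exp_idx] / sig[:, img.insp_idx]
        assert np.allclose(ratio, 1.25)

    def test_zero_sv_gives_phase_constant_images(self):
        spec = _spec(sv_mean=0.0)
        prof = p.ScannerProfile("ideal", 1.5, snr=np.inf, heterogeneity_scale=0.0)
        m = p.simulate_measurement(spec, prof)
        first = m.images.data[..., 0]
        for ph in range(1, m.images.n_phases):
            np.testing.assert_array_equal(m.images.data[..., ph], first)

    def test_noise_free_render_bitwise_deterministic(self, noise_free_measurement):
        spec = _spec(subject_id="P1", age=25.0, breathing_frequency=15.0,
                     tidal_volume_target=400.0, seed=11)
        prof = p.ScannerProfile("ideal", 1.5, snr=np.inf, heterogeneity_scale=0.0)
        again = p.simulate_measurement(spec, prof)
        np.testing.assert_array_equal(
            again.images.data, noise_free_measurement.images.data
        )

    def test_too_few_phases_rejected(self):
        with pytest.raises(synth.ParameterError):
            synth.phase_inflation(2)

    def test_phase_inflation_hits_exact_extremes(self):
        for n in (3, 8, 12, 15):
            u = synth.phase_inflation(n)
            assert u[0] == 0.0
            assert u[n // 2] == 1.0
            assert np.all((u >= 0) & (u <= 1 + 1e-12))


class TestNavigator:
    def test_sample_count_matches_duration(self):
        nav = synth.make_navigator(12.0, duration_s=480.0, dt_s=0.1, noise_sd=0.0)
        assert nav.n == 4800
        assert np.all(np.diff(nav.timestamps) > 0)

    def test_noiseless_series_equals_waveform(self):
        nav = synth.make_navigator(15.0, duration_s=60.0, dt_s=0.1, noise_sd=0.0)
        expected = 0.5 * (1 - np.cos(2 * np.pi * 15.0 / 60.0 * nav.timestamps))
        np.testing.assert_allclose(nav.amplitude, expected)

    def test_full_cycles_present(self):
        nav = synth.make_navigator(15.0, duration_s=60.0, dt_s=0.1, noise_sd=0.0)
        # 15 breaths/min over 60 s: 15 maxima reaching 1
        n_peaks = np.sum(np.isclose(nav.amplitude, 1.0))
        assert n_peaks == 15

    def test_bad_dt_rejected(self):
        with pytest.raises(synth.ParameterError):
            synth.make_navigator(12.0, duration_s=10.0, dt_s=0.0, noise_sd=0.0)


class TestSimulateMeasurement:
    def test_habituation_scales_true_rvent_by_closed_form(self, ideal_profile):
        spec = _spec(seed=42)
        pert = synth.Perturbation(tidal_factor=0.85)
        m1 = p.simulate_measurement(spec, ideal_profile, 1, pert)
        m2 = p.simulate_measurement(spec, ideal_profile, 2, pert)
        sv = 0.25
        expected_m2 = (0.85 * sv) / (1 + 0.85 * sv)
        got1 = m1.ground_truth.rvent_true_field[m1.analysis_mask].mean()
        got2 = m2.ground_truth.rvent_true_field[m2.analysis_mask].mean()
        assert got1 == pytest.approx(sv / (1 + sv), abs=1e-12)
        assert got2 == pytest.approx(expected_m2, abs=1e-12)
        # ~12-13% relative decrease for sv = 0.25
        assert got2 / got1 == pytest.approx(expected_m2 / 0.2, abs=1e-12)

    def test_frequency_factor_scales_true_frequency(self, ideal_profile):
        pert = synth.Perturbation(frequency_factor=0.9)
        m2 = p.simulate_measurement(_spec(), ideal_profile, 2, pert)
        assert m2.ground_truth.true_breathing_frequency == pytest.approx(13.5)

    def test_unperturbed_noise_free_measurements_identical(self, ideal_profile):
        m1 = p.simulate_measurement(_spec(), ideal_profile, 1)
        m2 = p.simulate_measurement(_spec(), ideal_profile, 2)
        np.testing.assert_array_equal(m1.images.data, m2.images.data)

    def test_tidal_consistency_between_truth_and_masks(self, noisy_measurement):
        m = noisy_measurement
        voxvol = np.prod(m.images.voxel_size)
        mask_tv = (int(m.insp_lung_mask.sum()) - int(m.exp_lung_mask.sum())) * voxvol / 1000.0
        assert abs(m.ground_truth.true_tidal_volume - mask_tv) <= voxvol / 1000.0

    def test_noise_free_recovery_of_mean_rvent(self, noise_free_measurement):
        m = noise_free_measurement
        summary = p.summarize_measurement(m)
        truth = m.ground_truth.rvent_true_field[m.analysis_mask].mean()
        assert summary.mean_rvent == pytest.approx(truth, abs=1e-9)


class TestCohort:
    def test_cohort_size_mirrors_design(self):
        cfg = p.default_config(seed=1)
        # 24 subjects x 2 scanners x 2 measurements + 26 x 1 x 2 = 148
        n = sum(1 for _ in synth.iter_cohort_measurements(cfg))
        assert n == 148

    def test_empty_center_is_valid(self):
        cfg = p.fixture_config(seed=1)
        cfg = dataclasses.replace(
            cfg,
            centers=(
                CenterConfig("Center1", 0, ("C1-1.5T", "C1-3T")),
                CenterConfig("Center2", 2, ("C2-3T",)),
            ),
        )
        ms, table = synth.generate_cohort(cfg)
        assert len(ms) == 4
        assert set(table["center"]) == {"Center2"}

    def test_same_config_and_seed_identical_cohort_table(self):
        cfg = p.fixture_config(seed=9, n_per_center=2)
        _, t1 = synth.generate_cohort(cfg)
        _, t2 = synth.generate_cohort(cfg)
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        _, t1 = synth.generate_cohort(p.fixture_config(seed=1, n_per_center=2))
        _, t2 = synth.generate_cohort(p.fixture_config(seed=2, n_per_center=2))
        assert not t1["age"].equals(t2["age"])

    def test_demographics_within_ranges(self):
        cfg = p.fixture_config(seed=4, n_per_center=3)
        _, table = synth.generate_cohort(cfg)
        demo = cfg.demographics
        assert table["age"].between(*demo.age_range).all()
        assert set(table["sex"]) <= {"F", "M"}
        assert table["true_breathing_frequency"].between(
            demo.breathing_frequency_range[0] * 0.7,
            demo.breathing_frequency_range[1] * 1.4,
        ).all()
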