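"""Density conversion, ROI statistics, histograms, volumes, QC study."""

import numpy as np
import pandas as pd
import pytest

from gipct.densitometry import (DensityConversion, DensityVolume,
                                delta_to_density, density_histogram,
                                density_resolution, exposure_study, roi_stats,
                                threshold_segment, volume_mass)
from gipct.forward_model import project
from gipct.instrument import BeamSpec
from gipct.phantoms import (ScenarioParams, density_to_optical,
                            make_fetus_phantom)
from gipct.reconstruct import DeltaVolume

from conftest import G2_PITCH_UM, PIXEL_MM, TALBOT_MM, cylinder_phantom

LAM = 0.0496  # nm, 25 keV to 3 s.f.


def dvol(grid, vox=0.1):
    return DensityVolume(np.asarray(grid, dtype=float), vox)


class TestDeltaToDensity:
    def test_zero_contrast_gives_medium(self):
        conv = DensityConversion(LAM, medium_density=1.005, calibration=1.0)
        out = delta_to_density(DeltaVolume(np.zeros((2, 4, 4)), 0.1, LAM), conv)
        np.testing.assert_allclose(out.grid, 1.005)

    def test_inverse_of_optical_conversion(self):
        """Round trip ρ → δ → ρ at calibration 1.0 is exact."""
        params = ScenarioParams(shape=(32, 32, 32))
        ph = make_fetus_phantom(params)
        opt = density_to_optical(ph, BeamSpec(25.0))
        conv = DensityConversion(LAM, ph.z_over_m, 1.0, ph.medium_density)
        vol = DeltaVolume(opt.delta_contrast, ph.voxel_size_mm, LAM)
        out = delta_to_density(vol, conv)
        np.testing.assert_allclose(out.grid, ph.grid, rtol=1e-12)

    def test_unit_density_constant(self):
        conv = DensityConversion(LAM, 0.55, 1.0, 0.0)
        vol = DeltaVolume(np.full((1, 1, 1), 3.65e-7), 0.1, LAM)
        assert delta_to_density(vol, conv).grid[0, 0, 0] == pytest.approx(
            1.0, abs=5e-3)

    def test_calibration_scales_increment(self):
        vol = DeltaVolume(np.full((2, 2, 2), 1e-8), 0.1, LAM)
        base = delta_to_density(vol, DensityConversion(LAM, calibration=1.0))
        cal = delta_to_density(vol, DensityConversion(LAM, calibration=1.45))
        np.testing.assert_allclose(cal.grid - 1.0, 1.45 * (base.grid - 1.0),
                                   rtol=1e-12)

    def test_wavelength_mismatch_rejected(self):
        vol = DeltaVolume(np.zeros((1, 2, 2)), 0.1, 0.07)
        with pytest.raises(ValueError, match="wavelength"):
            delta_to_density(vol, DensityConversion(LAM))


class TestRoiStats:
    def test_constant_region(self):
        v = dvol(np.full((2, 3, 3), 1.23))
        mean, std, n = roi_stats(v, np.ones((2, 3, 3), bool))
        assert (mean, std, n) == (pytest.approx(1.23), 0.0, 18)

    def test_two_voxel_sample_std(self):
        grid = np.array([[[1.00, 1.02]]])
        mean, std, n = roi_stats(dvol(grid), np.ones((1, 1, 2), bool))
        assert mean == pytest.approx(1.01)
        assert std == pytest.approx(0.014142, abs=1e-5)  # n−1 convention
        assert n == 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_stats(dvol(np.ones((2, 2, 2))), np.zeros((2, 2, 2), bool))


class TestHistogram:
    def test_constant_roi_single_bin(self):
        v = dvol(np.full((1, 4, 4), 1.05))
        edges, counts, modes = density_histogram(v, np.ones((1, 4, 4), bool))
        assert (counts > 0).sum() == 1
        assert counts.sum() == 16

    def test_two_component_mixture_two_modes(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.01, 0.002, 4000)
        b = rng.normal(1.04, 0.002, 4000)
        grid = np.concatenate([a, b]).reshape(2, 40, 100)
        v = dvol(grid)
        edges, counts, modes = density_histogram(v, np.ones_like(grid, bool),
                                                 bin_width=0.002)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(1.01, abs=0.004)
        assert modes[1] == pytest.approx(1.04, abs=0.004)

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        grid = 1.0 + 0.05 * rng.random((3, 8, 8))
        mask = rng.random((3, 8, 8)) > 0.4
        _, counts, _ = density_histogram(dvol(grid), mask)
        assert counts.sum() == mask.sum()


class TestVolumeMass:
    def test_thousand_voxels(self):
        grid = np.ones((10, 10, 10))
        vol, mean, mass = volume_mass(dvol(grid, 0.1), np.ones_like(grid, bool))
        assert vol == pytest.approx(1.0)  # mm³
        assert mass == pytest.approx(1e-3)  # 1 mg in grams

    def test_additivity_over_split(self):
        rng = np.random.default_rng(3)
        grid = 1.0 + 0.1 * rng.random((4, 4, 4))
        half = np.zeros_like(grid, bool)
        half[:2] = True
        v1, _, m1 = volume_mass(dvol(grid), half)
        v2, _, m2 = volume_mass(dvol(grid), ~half)
        vt, _, mt = volume_mass(dvol(grid), np.ones_like(grid, bool))
        assert v1 + v2 == pytest.approx(vt)
        assert m1 + m2 == pytest.approx(mt)

    def test_mass_linear_in_density(self):
        grid = 1.0 + np.zeros((2, 2, 2))
        mask = np.ones_like(grid, bool)
        _, _, m1 = volume_mass(dvol(grid), mask)
        v2, _, m2 = volume_mass(dvol(2 * grid), mask)
        assert m2 == pytest.approx(2 * m1)
        assert v2 == pytest.approx(8 * 0.1**3)


class TestDensityResolution:
    def test_constant_background_zero(self):
        assert density_resolution(dvol(np.ones((2, 8, 8))),
                                  np.ones((2, 8, 8), bool)) == 0.0

    def test_injected_sigma_recovered(self):
        rng = np.random.default_rng(4)
        grid = 1.0 + rng.normal(0.0, 1.51e-3, (30, 30, 30))
        res = density_resolution(dvol(grid), np.ones_like(grid, bool))
        assert res == pytest.approx(1.51, rel=0.05)

    def test_offset_invariant(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0.0, 2e-3, (10, 10, 10))
        mask = np.ones((10, 10, 10), bool)
        r1 = density_resolution(dvol(1.0 + noise), mask)
        r2 = density_resolution(dvol(1.1 + noise), mask)
        assert r1 == pytest.approx(r2)


def test_threshold_segmentation():
    grid = np.array([[[1.0, 1.03, 1.06, 1.09]]])
    mask = threshold_segment(dvol(grid), 1.04, 1.08)
    np.testing.assert_array_equal(mask[0, 0], [False, False, True, False])


@pytest.fixture(scope="module")
def study():
    phantom, rr = cylinder_phantom(n=48, nz=2, radius=9.0, drho=0.02)
    opt = density_to_optical(phantom, BeamSpec(25.0))
    angles = np.arange(120) * 1.5
    ps = project(opt, angles, G2_PITCH_UM, TALBOT_MM)
    conv = DensityConversion(LAM, 0.55, 1.0, 1.0)
    bg = np.broadcast_to(((rr >= 13) & (rr <= 20))[None],
                         phantom.grid.shape).copy()
    return exposure_study(ps, [0.1, 0.5], 8600.0, 0.3, G2_PITCH_UM,
                          TALBOT_MM, conv, bg, (13, 20), seeds=(0, 1, 2))


class TestExposureStudy:
    def test_tidy_table(self, study):
        assert isinstance(study, pd.DataFrame)
        assert set(study.columns) >= {"exposure_s", "seed",
                                      "density_resolution_mg_cm3",
                                      "ring_metric_g_cm3"}
        assert len(study) == 6

    def test_longer_exposure_improves_resolution(self, study):
        g = study.groupby("exposure_s")["density_resolution_mg_cm3"].mean()
        assert g.loc[0.5] < g.loc[0.1]

    def test_single_exposure_rejected(self):
        with pytest.raises(ValueError):
            exposure_study(None, [0.1], 1.0, 0.3, G2_PITCH_UM, TALBOT_MM,
                           None, None, (1, 2))
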