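"""Projection and phase-stepping synthesis."""

import numpy as np
import pytest
from skimage.transform import radon

from gipct.forward_model import (flux_to_budget, project, simulate_stepping,
                                 stepping_curve)
from gipct.instrument import BeamSpec, DetectorSpec
from gipct.phantoms import DensityPhantom, OpticalVolume, density_to_optical
from gipct.retrieval import retrieve

from conftest import G2_PITCH_UM, PIXEL_MM, TALBOT_MM, cylinder_phantom


def small_projections(n=32, drho=0.05, angles=(0.0, 45.0, 90.0)):
    phantom, _ = cylinder_phantom(n=n, nz=3, radius=8.0, drho=drho)
    opt = density_to_optical(phantom, BeamSpec(25.0))
    return project(opt, np.asarray(angles), G2_PITCH_UM, TALBOT_MM), opt


class TestProject:
    def test_homogeneous_slab_zero_dphase(self):
        grid = np.full((3, 32, 32), 1.0)
        ph = DensityPhantom(grid, PIXEL_MM, 1.0)
        opt = density_to_optical(ph, BeamSpec(25.0))
        ps = project(opt, np.array([0.0, 90.0]), G2_PITCH_UM, TALBOT_MM)
        np.testing.assert_allclose(ps.dphase, 0.0, atol=1e-15)

    def test_cylinder_antisymmetric_and_zero_integral(self):
        ps, _ = small_projections()
        row = ps.dphase[0, 1, :]
        c = (len(row) - 1) / 2
        # ψ is odd about the cylinder axis; its integral over the full
        # profile vanishes (derivative of a compact bump)
        assert np.allclose(row + row[::-1], 0.0, atol=1e-6 * np.abs(row).max())
        assert abs(row.sum()) < 1e-3 * np.abs(row).sum()

    def test_psi_linear_in_delta(self):
        ps1, opt = small_projections(drho=0.02)
        opt2 = OpticalVolume(2 * opt.delta, opt.mu, opt.wavelength_nm,
                             opt.voxel_size_mm, 2 * opt.delta_medium)
        ps2 = project(opt2, ps1.angles_deg, G2_PITCH_UM, TALBOT_MM)
        np.testing.assert_allclose(ps2.dphase, 2 * ps1.dphase, rtol=1e-9,
                                   atol=1e-12)

    @pytest.mark.filterwarnings(
        "ignore:Radon transform.*zero outside:UserWarning")
    def test_line_integrals_match_skimage_radon(self):
        """The rotate-and-sum projector agrees with the classical Radon
        transform on an off-centre blob (independent oracle).  Odd grid
        size: both implementations then share the same rotation centre."""
        n = 49
        yy, xx = np.meshgrid(np.arange(n) - (n - 1) / 2,
                             np.arange(n) - (n - 1) / 2, indexing="ij")
        img = np.exp(-((yy - 6) ** 2 + (xx + 4) ** 2) / (2 * 4.0**2))
        grid = np.full((1, n, n), 1.0) + 0.02 * img[None]
        ph = DensityPhantom(grid, PIXEL_MM, 1.0)
        opt = density_to_optical(ph, BeamSpec(25.0))
        angles = np.array([0.0, 30.0, 77.0, 120.0])
        ps = project(opt, angles, G2_PITCH_UM, TALBOT_MM)
        # undo the derivative scaling to recover t_δ via cumulative sum
        scale = 2 * np.pi * TALBOT_MM / (G2_PITCH_UM * 1e-3)
        contrast = opt.delta_contrast[0]
        sino = radon(contrast, angles, circle=True).T * PIXEL_MM
        from scipy.integrate import cumulative_trapezoid

        for i in range(len(angles)):
            t = cumulative_trapezoid(ps.dphase[i, 0] / scale, dx=PIXEL_MM,
                                     initial=0.0)
            # compare the derivative-integrated profile with the oracle
            assert np.sqrt(np.mean((t - sino[i]) ** 2)) < 0.01 * sino.max()

    def test_edge_touching_object_warns(self):
        grid = np.full((2, 16, 16), 1.0)
        grid[:, :, 0] = 1.05
        ph = DensityPhantom(grid, PIXEL_MM, 1.0)
        opt = density_to_optical(ph, BeamSpec(25.0))
        with pytest.warns(UserWarning, match="edge"):
            project(opt, np.array([0.0]), G2_PITCH_UM, TALBOT_MM)


@pytest.fixture(scope="module")
def projections():
    return small_projections(drho=0.05)[0]


class TestSimulateStepping:
    @pytest.mark.parametrize("n_steps", [3, 5])
    def test_noiseless_round_trip(self, projections, n_steps):
        stack = simulate_stepping(projections, 0.0, 0.3, n_steps,
                                  noiseless=True)
        res = retrieve(stack.frames[1], axis=0)
        np.testing.assert_allclose(res.psi, projections.dphase[1], atol=1e-9)
        np.testing.assert_allclose(res.vis, 0.3, atol=1e-9)
        np.testing.assert_allclose(res.i0, projections.trans[1], rtol=1e-12)

    def test_frame_mean_equals_budget_times_trans(self, projections):
        stack = simulate_stepping(projections, 500.0, 0.3, 5, gain=2.0,
                                  noiseless=True)
        mean = stack.frames.mean(axis=1)
        np.testing.assert_allclose(mean, 2.0 * 500.0 * projections.trans,
                                   rtol=1e-12)

    def test_triangle_first_harmonic_is_8_over_pi_squared(self):
        """Fine stepping of a triangle curve retrieves (8/π²)·V_peak."""
        k = np.arange(64, dtype=float)
        frames = 100.0 * stepping_curve(k, 64, 0.4, 0.5, "triangle")
        res = retrieve(frames, axis=0)
        assert res.vis == pytest.approx(8 / np.pi**2 * 0.5, rel=5e-3)
        assert res.psi == pytest.approx(0.4, abs=2e-3)

    def test_triangle_alias_at_coarse_stepping(self):
        """At N=5 the triangle's odd harmonics n ≡ ±1 (mod 5) fold into the
        first harmonic; the retrieved visibility matches the exact Fourier
        alias sum, not 8/π²."""
        odd = range(1, 20001, 2)
        a1 = (8 / np.pi**2) * sum(1.0 / n**2 for n in odd if n % 5 in (1, 4))
        # the mean also picks up aliased harmonics n ≡ 0 (mod 5)
        i0 = 1.0 + 0.5 * (8 / np.pi**2) * sum(
            1.0 / n**2 for n in odd if n % 5 == 0)
        k = np.arange(5, dtype=float)
        frames = 100.0 * stepping_curve(k, 5, 0.0, 0.5, "triangle")
        res = retrieve(frames, axis=0)
        assert res.vis == pytest.approx(0.5 * a1 / i0, rel=1e-4)

    def test_poisson_variance_over_mean_equals_gain(self):
        from gipct.forward_model import ProjectionSet

        flat = ProjectionSet(np.array([0.0]), np.zeros((1, 64, 64)),
                             np.full((1, 64, 64), 0.9), PIXEL_MM)
        stack = simulate_stepping(flat, 200.0, 0.0, 5, gain=7.0, seed=11)
        counts = stack.frames.reshape(-1)
        # var/mean of Poisson photons scaled by gain g is g (≥10⁴ samples)
        assert counts.size >= 10**4
        ratio = counts.var() / counts.mean()
        assert ratio == pytest.approx(7.0, rel=0.05)

    def test_background_noise_decreases_with_budget(self, projections):
        sds = []
        for mult in (1, 2, 3, 4, 5):
            stack = simulate_stepping(projections, 860.0 * mult, 0.3, 5,
                                      seed=3)
            res = retrieve(stack.frames[0], axis=0)
            ref = retrieve(stack.reference, axis=0)
            sds.append(np.std(res.psi - ref.psi))
        assert np.all(np.diff(sds) < 0)

    def test_invalid_inputs_rejected(self, projections):
        with pytest.raises(ValueError):
            simulate_stepping(projections, -1.0, 0.3)
        with pytest.raises(ValueError):
            simulate_stepping(projections, 100.0, 1.5)
        with pytest.raises(ValueError):
            simulate_stepping(projections, 100.0, 0.3, n_steps=2)


class TestFluxToBudget:
    def test_bench_numbers(self):
        beam = BeamSpec(25.0, 1.2e8)
        det = DetectorSpec(effective_pixel_um=15.5)
        # 1.2e8 × (0.0155 mm)² × 0.1 s ≈ 2883 photons before system losses
        assert flux_to_budget(beam, det, 0.1, 1.0) == pytest.approx(2883, rel=1e-3)

    def test_zero_transmission(self):
        beam = BeamSpec(25.0, 1.2e8)
        det = DetectorSpec(effective_pixel_um=15.5)
        assert flux_to_budget(beam, det, 0.1, 0.0) == 0.0

    def test_linear_in_exposure(self):
        beam = BeamSpec(25.0, 1.2e8)
        det = DetectorSpec(effective_pixel_um=15.5)
        assert flux_to_budget(beam, det, 0.5) == pytest.approx(
            5 * flux_to_budget(beam, det, 0.1))
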