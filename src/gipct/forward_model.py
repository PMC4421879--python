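"""Acquisition simulation: projection and phase-stepping synthesis.

The beam is quasi-parallel (synchrotron bending-magnet station far from the
source), the rotation axis vertical (z) and the differential-phase
direction horizontal (detector x, perpendicular to the grating lines).
Per projection angle the object's δ and μ are line-integrated along the
beam; the stepping-curve phase measured behind the analyser grating is

    ψ = (2π z_T / d₂) · ∂t_δ/∂x,       t_δ(x, z) = ∫ δ ds,

with z_T the G1–G2 distance and d₂ the analyser pitch.  Phase stepping is
synthesized frame by frame: expected counts follow the stepping curve
(sinusoidal, or a unit-period triangle wave for fully coherent
illumination), photons are Poisson-sampled and the detector gain applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .instrument import BeamSpec, DetectorSpec
from .phantoms import OpticalVolume

__all__ = ["ProjectionSet", "SteppingStack", "project", "simulate_stepping",
           "flux_to_budget", "stepping_curve"]


@dataclass
class ProjectionSet:
    """Per-angle differential-phase and transmission maps.

    ``dphase``/``trans`` have shape (n_angles, nz, nx); angles are degrees
    in [0, 180), strictly increasing.
    """

    angles_deg: np.ndarray
    dphase: np.ndarray
    trans: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angle list must be strictly increasing")
        if not np.all(np.isfinite(self.dphase)):
            raise ValueError("differential phase must be finite")
        if np.any(self.trans <= 0) or np.any(self.trans > 1 + 1e-12):
            raise ValueError("transmission must lie in (0, 1]")


@dataclass
class SteppingStack:
    """Per-angle stacks of N_step count frames plus a no-sample reference."""

    frames: np.ndarray  # (n_angles, n_steps, nz, nx)
    reference: np.ndarray  # (n_steps, nz, nx)
    angles_deg: np.ndarray
    photon_budget: float
    visibility: float
    gain: float
    profile: Literal["sine", "triangle"]
    seed: Optional[int]

    @property
    def n_steps(self) -> int:
        return self.frames.shape[1]


def _central_diff(arr: np.ndarray, spacing: float) -> np.ndarray:
    """d/dx along the last axis: central interior, one-sided edges."""
    return np.gradient(arr, spacing, axis=-1)


def project(
    optical: OpticalVolume,
    angles_deg: np.ndarray,
    g2_pitch_um: float,
    talbot_distance_mm: float,
) -> ProjectionSet:
    """Parallel-beam projection of an optical volume.

    Per angle the volume is rotated about the vertical axis (linear
    interpolation, matching the classical rotate-and-sum Radon evaluation)
    and summed along the beam; δ is integrated relative to the surrounding
    medium so the background differential phase is zero, which mirrors a
    measurement flat-fielded against the saline-filled cell.  ψ uses
    central differences on the pixel grid; transmission is Beer–Lambert in
    the absolute μ.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    vol_d = np.ascontiguousarray(optical.delta_contrast)
    vol_mu = np.ascontiguousarray(optical.mu)
    nz, ny, nx = vol_d.shape
    px = optical.voxel_size_mm

    edge = max(np.abs(vol_d[:, [0, -1], :]).max(initial=0.0),
               np.abs(vol_d[:, :, [0, -1]]).max(initial=0.0))
    if edge > 1e-3 * max(np.abs(vol_d).max(initial=0.0), 1e-30):
        import warnings

        warnings.warn("object touches the grid edge; derivative artefacts likely")

    scale = 2.0 * np.pi * talbot_distance_mm / (g2_pitch_um * 1e-3)
    dphase = np.empty((len(angles_deg), nz, nx))
    trans = np.empty_like(dphase)
    mu_bg = float(np.median(vol_mu[:, 0, 0])) if vol_mu.size else 0.0
    for i, ang in enumerate(angles_deg):
        rot_d = ndimage.rotate(vol_d, -ang, axes=(1, 2), reshape=False,
                               order=1, mode="constant", cval=0.0)
        rot_m = ndimage.rotate(vol_mu, -ang, axes=(1, 2), reshape=False,
                               order=1, mode="constant", cval=mu_bg)
        t_delta = rot_d.sum(axis=1) * px  # mm · dimensionless
        t_mu = rot_m.sum(axis=1) * px
        dphase[i] = scale * _central_diff(t_delta, px)
        trans[i] = np.exp(-t_mu)
    return ProjectionSet(angles_deg, dphase, trans, px)


def stepping_curve(
    k: np.ndarray, n_steps: int, psi: np.ndarray, visibility: float,
    profile: Literal["sine", "triangle"] = "sine",
) -> np.ndarray:
    """Normalized stepping curve s_k = modulation at step k.

    Sine: 1 + V cos(2πk/N + ψ).  Triangle: 1 + V·tri(2πk/N + ψ) with tri
    the even, unit-amplitude, 2π-periodic triangle wave (tri(0)=1); its
    first Fourier harmonic is (8/π²)·V.
    """
    theta = 2.0 * np.pi * k / n_steps + psi
    if profile == "sine":
        return 1.0 + visibility * np.cos(theta)
    if profile == "triangle":
        u = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
        return 1.0 + visibility * (1.0 - 2.0 * np.abs(u) / np.pi)
    raise ValueError(f"unknown stepping profile {profile!r}")


def simulate_stepping(
    projections: ProjectionSet,
    photon_budget: float,
    visibility: float,
    n_steps: int = 5,
    profile: Literal["sine", "triangle"] = "sine",
    gain: float = 1.0,
    seed: Optional[int] = None,
    noiseless: bool = False,
    gain_error_rms: float = 0.0,
    flat_phase_error_rms: float = 0.0,
    flat_budget_factor: float = 1.0,
) -> SteppingStack:
    """Synthesize phase-stepping frame stacks from retrieved-quantity maps.

    Expected counts at step k are gain × budget × trans × s_k(ψ, V); in the
    default (Poisson) mode photons are sampled per pixel and the gain
    applied afterwards, so the count variance is gain × mean — the
    photon-limited regime of a lens-coupled detector with gain > 1.
    ``noiseless`` returns the expectations exactly.  The reference stack is
    the same curve with trans = 1 and ψ = 0.

    Two detector-correlated imperfections (fixed per pixel, constant over
    angles and steps, sample frames only) are available for ring-artefact
    studies: ``gain_error_rms``, a multiplicative intensity error — note a
    pure gain error cancels in the phase of the first harmonic — and
    ``flat_phase_error_rms``, a stepping-phase offset emulating analyser
    drift between the measurement and its flat reference, which survives
    retrieval and backprojects into rings.

    ``flat_budget_factor`` models the averaging of several flat-field
    blocks over a scan: the reference frames are sampled at factor × the
    per-frame budget and rescaled, reducing reference noise by √factor
    without biasing the flat correction.
    """
    if not 0 <= visibility <= 1:
        raise ValueError("visibility must lie in [0, 1]")
    if photon_budget < 0:
        raise ValueError("photon budget must be non-negative")
    if noiseless and photon_budget == 0:
        photon_budget = 1.0  # exact expectations: the overall scale cancels
    if n_steps < 3:
        raise ValueError("phase stepping needs at least 3 steps")
    rng = np.random.default_rng(seed)
    na, nz, nx = projections.dphase.shape
    k = np.arange(n_steps, dtype=float)[None, :, None, None]
    psi = projections.dphase[:, None, :, :]
    if flat_phase_error_rms > 0:
        psi = psi + flat_phase_error_rms * rng.standard_normal((nz, nx))[None, None]
    tr = projections.trans[:, None, :, :]
    expected = photon_budget * tr * stepping_curve(k, n_steps, psi, visibility, profile)
    ref_expected = photon_budget * stepping_curve(
        np.arange(n_steps, dtype=float)[:, None, None], n_steps, 0.0, visibility, profile
    ) * np.ones((n_steps, nz, nx))
    if gain_error_rms > 0:
        err = 1.0 + gain_error_rms * rng.standard_normal((nz, nx))
        expected = expected * np.clip(err, 0.1, None)[None, None, :, :]
    if noiseless:
        frames = gain * expected
        reference = gain * ref_expected
    else:
        frames = gain * rng.poisson(expected).astype(np.float64)
        reference = gain * rng.poisson(
            ref_expected * flat_budget_factor) / flat_budget_factor
    return SteppingStack(frames, reference, projections.angles_deg,
                         photon_budget, visibility, gain, profile, seed)


def flux_to_budget(
    beam: BeamSpec,
    detector: DetectorSpec,
    exposure_s: float,
    system_transmission: float = 1.0,
) -> float:
    """Expected detected photons per pixel per frame.

    flux density × (effective pixel)² × exposure × system transmission;
    the last factor lumps the water cell, gratings and scintillator.
    """
    if exposure_s < 0 or system_transmission < 0:
        raise ValueError("exposure and transmission must be non-negative")
    pix_mm = detector.pixel_um * 1e-3
    return beam.flux_density * pix_mm**2 * exposure_s * system_transmission
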