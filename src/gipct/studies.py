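"""End-to-end synthetic studies: specimen scenarios run through the whole
measurement chain and analysed the way the bench experiments are.

Each study generates a density phantom, converts it to optics, simulates
the scan (noiseless by default — these studies quantify the chain's
systematic fidelity, not photon statistics), retrieves, reconstructs and
converts back to mass density, then reports compartment statistics:

* ``fixation_comparison`` — a fresh/chemically-fixed pair of fetus-like
  phantoms; reports liver volume, density and mass in both states and the
  recovered shrinkage and density increment.
* ``stretch_series`` — the ring vessel under stepwise axial stretch;
  reports the wall-ROI mean density per step and the total increment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import densitometry, forward_model, phantoms, retrieval
from .instrument import BeamSpec
from .reconstruct import fbp_dpc

G2_PITCH_UM = 10.0
TALBOT_MM = 3024.0


def scan_to_density(
    phantom: phantoms.DensityPhantom,
    n_angles: int = 600,
    beam: Optional[BeamSpec] = None,
    photon_budget: float = 0.0,
    visibility: float = 0.3,
    n_steps: int = 5,
    seed: Optional[int] = None,
    calibration: float = 1.0,
    g2_pitch_um: float = G2_PITCH_UM,
    talbot_distance_mm: float = TALBOT_MM,
    flat_budget_factor: float = 8.0,
) -> densitometry.DensityVolume:
    """Run one phantom through simulate → retrieve → reconstruct → ρ.

    ``photon_budget`` 0 selects the noiseless (expectation) mode.
    """
    beam = beam or BeamSpec(25.0, 1.2e8)
    optical = phantoms.density_to_optical(phantom, beam)
    angles = np.arange(n_angles) * 180.0 / n_angles
    projs = forward_model.project(optical, angles, g2_pitch_um,
                                  talbot_distance_mm)
    stack = forward_model.simulate_stepping(
        projs, photon_budget, visibility, n_steps, seed=seed,
        noiseless=photon_budget <= 0, flat_budget_factor=flat_budget_factor)
    retrieved, _ = retrieval.retrieve_stack(stack)
    dph = np.stack([p.dphase for p in retrieved])
    vol = fbp_dpc(dph, angles, g2_pitch_um, talbot_distance_mm,
                  phantom.voxel_size_mm, wavelength_nm=optical.wavelength_nm)
    conv = densitometry.DensityConversion(
        optical.wavelength_nm, phantom.z_over_m, calibration,
        phantom.medium_density)
    return densitometry.delta_to_density(vol, conv)


@dataclass
class FixationResult:
    """Liver metrics of the fresh/fixed pair, measured on reconstructions."""

    fresh: Dict[str, float]
    fixed: Dict[str, float]

    @property
    def volume_ratio(self) -> float:
        return self.fixed["volume_mm3"] / self.fresh["volume_mm3"]

    @property
    def density_increment(self) -> float:
        return self.fixed["mean_density"] - self.fresh["mean_density"]

    @property
    def mass_change_g(self) -> float:
        return self.fixed["mass_g"] - self.fresh["mass_g"]


def _liver_metrics(
    dens: densitometry.DensityVolume,
    body_density: float,
    liver_density: float,
) -> Dict[str, float]:
    """Segment the liver by thresholding halfway between body and liver
    density (the liver is the densest compartment) and report its volume,
    interior mean density and mass."""
    from scipy import ndimage as ndi

    thr = 0.5 * (body_density + liver_density)
    mask = densitometry.threshold_segment(dens, thr)
    # keep the largest connected component: stray voxels are edge overshoot
    lab, n = ndi.label(mask)
    if n == 0:
        raise ValueError("liver segmentation found nothing above threshold")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    volume, _, mass = densitometry.volume_mass(dens, mask)
    core = ndi.binary_erosion(mask, iterations=2)
    mean = float(dens.grid[core].mean()) if core.any() \
        else float(dens.grid[mask].mean())
    return {"volume_mm3": volume, "mean_density": mean, "mass_g": mass}


def fixation_comparison(
    shape=(64, 64, 64),
    n_angles: int = 600,
    shrinkage: float = 0.35,
    density_increment: float = 0.015,
    seed: int = 0,
    **scan_kw,
) -> FixationResult:
    """Fresh-vs-fixed fetus pair through the full chain.

    The fixed phantom shrinks the liver by ``shrinkage`` (volume fraction)
    and raises tissue densities by ``density_increment``; the study then
    recovers both numbers from the reconstructed density maps alone.
    """
    out = {}
    dens_defaults = phantoms.FETUS_DEFAULTS
    for scenario in ("fetus_fresh", "fetus_fixed"):
        params = phantoms.ScenarioParams(
            scenario=scenario, shape=shape, shrinkage=shrinkage,
            density_increment=density_increment, seed=seed)
        ph = (phantoms.make_fetus_phantom(params))
        dens = scan_to_density(ph, n_angles=n_angles, seed=seed, **scan_kw)
        inc = density_increment if scenario == "fetus_fixed" else 0.0
        out[scenario] = _liver_metrics(
            dens, dens_defaults["body"] + inc, dens_defaults["liver"] + inc)
    return FixationResult(out["fetus_fresh"], out["fetus_fixed"])


def stretch_series(
    n_steps_stretch: int = 5,
    shape=(96, 96, 96),
    n_angles: int = 300,
    density_increment: float = 0.005,
    seed: int = 0,
    roi_half_height: int = 4,
    **scan_kw,
) -> pd.DataFrame:
    """Ring-vessel stretch series through the full chain.

    The wall ROI is a fixed annular band that stays inside the inner wall
    layer at every step (the same position on the specimen as it thins),
    mirroring a fixed 20 × 20-pixel box on a wall that is thick compared
    with the ROI.  Returns one row per stretch step with the ROI mean/std
    and the wall histogram mode count at step 0.
    """
    all_params = [
        phantoms.ScenarioParams(
            scenario="aorta_stretch", shape=shape, stretch_step=k,
            n_stretch_steps=n_steps_stretch,
            density_increment=density_increment, seed=seed)
        for k in range(n_steps_stretch + 1)
    ]
    all_ph = [phantoms.make_aorta_phantom(p) for p in all_params]
    # fixed ROI: inside the intima at its thinnest (final step) geometry
    lumen_r, r1_final, _ = all_ph[-1].meta["wall_radii_vox"]
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    rr = np.hypot(yy, xx)
    band = (rr >= lumen_r + 1.5) & (rr <= r1_final - 1.5)
    zc = (nz - 1) // 2
    roi = np.zeros(shape, dtype=bool)
    roi[zc - roi_half_height: zc + roi_half_height + 1] = band

    rows = []
    for k, ph in enumerate(all_ph):
        dens = scan_to_density(ph, n_angles=n_angles, seed=seed, **scan_kw)
        mean, std, n = densitometry.roi_stats(dens, roi)
        row = dict(step=k, roi_mean=mean, roi_std=std, roi_n=n)
        if k == 0:
            wall = np.broadcast_to(
                (rr >= lumen_r + 1) & (rr <= ph.meta["wall_radii_vox"][2] - 1),
                shape) & (ph.labels > 0)
            _, _, modes = densitometry.density_histogram(
                dens, wall, bin_width=0.002)
            row["n_modes_step0"] = len(modes)
        rows.append(row)
    return pd.DataFrame(rows)
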