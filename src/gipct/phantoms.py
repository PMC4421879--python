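"""Voxelized mass-density phantoms and their optical conversion.

Two scenario families are provided, mirroring the specimens a quantitative
phase-contrast densitometry study works with:

* a fetus-like body in saline with labelled organ compartments, whose
  chemically-fixed variant shrinks the liver compartment and raises all
  tissue densities by a small increment (formalin fixation emulation);
* a ring-shaped vessel (aorta segment) with two concentric wall layers of
  distinct density, stretched axially step by step so that the wall thins
  while each layer conserves its mass — which raises the layer densities.

Densities are in g cm⁻³ on a cubic voxel grid; the surrounding medium is
normal saline at ``medium_density``.  Compartment edges are anti-aliased
over one voxel in the density grid (so integral quantities like compartment
mass converge to their continuous values), while the integer label map uses
the half-coverage surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple

import numpy as np

from .constants import delta_per_unit_density
from .instrument import BeamSpec

__all__ = [
    "ScenarioParams",
    "DensityPhantom",
    "OpticalVolume",
    "make_fetus_phantom",
    "make_aorta_phantom",
    "density_to_optical",
]

#: Labels used by the fetus scenario.
LABEL_MEDIUM, LABEL_BODY, LABEL_LIVER, LABEL_BRAIN = 0, 1, 2, 3
#: Labels used by the aorta scenario.
LABEL_INTIMA, LABEL_EXTERNA = 1, 2


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of a synthetic specimen scenario.

    ``densities`` holds the baseline (fresh / unstretched) compartment
    densities in g cm⁻³.  ``shrinkage`` is the fixation-induced fractional
    volume loss of the liver; ``density_increment`` the fixation density
    rise applied to every tissue compartment.  For the aorta,
    ``density_increment`` is the total wall-density rise from step 0 to
    ``n_stretch_steps`` and ``stretch_per_step`` the fractional axial
    elongation per step.
    """

    scenario: Literal["fetus_fresh", "fetus_fixed", "aorta_stretch"] = "fetus_fresh"
    shape: Tuple[int, int, int] = (128, 128, 128)
    voxel_size_mm: float = 0.1
    medium_density: float = 1.0
    z_over_m: float = 0.55
    densities: Dict[str, float] = field(default_factory=dict)
    shrinkage: float = 0.35
    density_increment: float = 0.015
    stretch_step: int = 0
    n_stretch_steps: int = 5
    stretch_per_step: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.shrinkage < 1:
            raise ValueError("shrinkage must lie in [0, 1)")
        if self.density_increment < 0:
            raise ValueError("density increment must be non-negative")
        if self.stretch_step < 0:
            raise ValueError("stretch step must be >= 0")
        if self.medium_density <= 0:
            raise ValueError("medium density must be positive")


FETUS_DEFAULTS = {"body": 1.030, "liver": 1.055, "brain": 1.040}
AORTA_DEFAULTS = {"intima": 1.060, "externa": 1.045}


@dataclass
class DensityPhantom:
    """A voxel grid of mass density with an optional compartment label map."""

    grid: np.ndarray  # (nz, ny, nx), g cm⁻³
    voxel_size_mm: float
    medium_density: float
    z_over_m: float = 0.55
    labels: Optional[np.ndarray] = None
    params: Optional[ScenarioParams] = None
    meta: Dict[str, object] = field(default_factory=dict)  # analytic geometry

    def __post_init__(self) -> None:
        if np.any(self.grid <= 0):
            raise ValueError("mass densities must be positive")
        if self.labels is not None and self.labels.shape != self.grid.shape:
            raise ValueError("labels must share the grid shape")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    def compartment_volume_mm3(self, label: int) -> float:
        if self.labels is None:
            raise ValueError("phantom has no label map")
        return int((self.labels == label).sum()) * self.voxel_volume_mm3

    def compartment_mass_g(self, label: int) -> float:
        """Mass in grams: Σ ρ·dV over the labelled voxels (mm³·g cm⁻³ → mg)."""
        if self.labels is None:
            raise ValueError("phantom has no label map")
        mask = self.labels == label
        return float(self.grid[mask].sum()) * self.voxel_volume_mm3 * 1e-3

    def write(self, path: str | Path) -> None:
        from . import io

        io.write_phantom(self, path)


@dataclass
class OpticalVolume:
    """Refractive-index decrement δ and linear attenuation μ per voxel."""

    delta: np.ndarray  # dimensionless
    mu: np.ndarray  # mm⁻¹
    wavelength_nm: float
    voxel_size_mm: float
    delta_medium: float  # δ of the surrounding saline

    @property
    def delta_contrast(self) -> np.ndarray:
        """Δδ relative to the medium (what the tomogram reconstructs)."""
        return self.delta - self.delta_medium


def _ellipsoid_coverage(
    shape: Tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    """Fractional voxel coverage of an ellipsoid, anti-aliased over ~1 voxel.

    The signed radial coordinate r(x) = |(x−c)/a| is mapped through a linear
    edge ramp of width one voxel (in the local normal direction), which makes
    volume integrals second-order accurate without supersampling.
    """
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    u = np.stack([(zz - center[0]) / semi_axes[0],
                  (yy - center[1]) / semi_axes[1],
                  (xx - center[2]) / semi_axes[2]])
    r = np.sqrt((u**2).sum(axis=0))
    # approximate distance to the surface in voxels
    a_eff = 3.0 / (1.0 / semi_axes).sum()  # harmonic-mean semi-axis
    dist = (1.0 - r) * a_eff
    return np.clip(dist + 0.5, 0.0, 1.0)


def make_fetus_phantom(params: ScenarioParams) -> DensityPhantom:
    """Nested-ellipsoid fetus-like phantom in saline.

    Compartments: body (large ellipsoid), liver and brain-like organ
    (smaller ellipsoids inside the body).  The ``fetus_fixed`` scenario
    shrinks the liver isotropically about its centroid by the configured
    fractional volume loss and raises every tissue compartment's density by
    ``density_increment``.  Deterministic given the parameters and seed.
    """
    if params.scenario not in ("fetus_fresh", "fetus_fixed"):
        raise ValueError(f"not a fetus scenario: {params.scenario}")
    shape = params.shape
    dens = {**FETUS_DEFAULTS, **params.densities}
    fixed = params.scenario == "fetus_fixed"
    inc = params.density_increment if fixed else 0.0

    n = np.asarray(shape, dtype=float)
    center = (n - 1) / 2.0
    body_ax = n * np.array([0.40, 0.30, 0.30])
    liver_ax = n * np.array([0.13, 0.12, 0.12])
    liver_c = center + n * np.array([0.10, 0.0, 0.05])
    brain_ax = n * np.array([0.10, 0.10, 0.10])
    brain_c = center - n * np.array([0.22, 0.0, 0.02])
    if fixed:
        liver_ax = liver_ax * (1.0 - params.shrinkage) ** (1.0 / 3.0)

    for c, a in ((center, body_ax), (liver_c, liver_ax), (brain_c, brain_ax)):
        if np.any(c - a < -0.5) or np.any(c + a > n - 0.5) or a.min() < 1.5:
            raise ValueError("compartment exceeds the phantom grid "
                             "or falls below the voxel resolution")

    body = _ellipsoid_coverage(shape, center, body_ax)
    liver = _ellipsoid_coverage(shape, liver_c, liver_ax)
    brain = _ellipsoid_coverage(shape, brain_c, brain_ax)

    grid = np.full(shape, params.medium_density, dtype=np.float64)
    grid += body * (dens["body"] + inc - params.medium_density)
    grid += liver * (dens["liver"] + inc - (dens["body"] + inc))
    grid += brain * (dens["brain"] + inc - (dens["body"] + inc))

    labels = np.zeros(shape, dtype=np.uint8)
    labels[body >= 0.5] = LABEL_BODY
    labels[liver >= 0.5] = LABEL_LIVER
    labels[brain >= 0.5] = LABEL_BRAIN

    return DensityPhantom(grid, params.voxel_size_mm, params.medium_density,
                          params.z_over_m, labels, params)


def _annulus_coverage(rr: np.ndarray, r_in: float, r_out: float) -> np.ndarray:
    inner = np.clip(rr - r_in + 0.5, 0.0, 1.0)
    outer = np.clip(r_out - rr + 0.5, 0.0, 1.0)
    return inner * outer


def make_aorta_phantom(params: ScenarioParams) -> DensityPhantom:
    """Ring-shaped vessel phantom with a two-layer wall under axial stretch.

    The wall is an annular cylinder along the z axis with an inner layer
    (tunica intima) and outer layer (tunica externa) at distinct baseline
    densities, producing a bimodal wall-density histogram.  Stretch step k
    elongates the cylinder by ``1 + k·stretch_per_step``; each layer's mass
    ρ·V is held at its step-0 value while its density is raised linearly so
    that the total rise at ``n_stretch_steps`` equals ``density_increment``
    — so the wall necessarily thins as the ring stretches.
    """
    if params.scenario != "aorta_stretch":
        raise ValueError(f"not an aorta scenario: {params.scenario}")
    nz, ny, nx = params.shape
    dens = {**AORTA_DEFAULTS, **params.densities}
    k = params.stretch_step
    K = max(params.n_stretch_steps, 1)

    # baseline geometry in voxels
    lumen_r = 0.22 * nx
    t_int0 = 0.085 * nx
    t_ext0 = 0.085 * nx
    length0 = 0.55 * nz

    rho = {name: dens[name] + params.density_increment * k / K
           for name in ("intima", "externa")}
    stretch = 1.0 + params.stretch_per_step * k
    length = length0 * stretch

    # per-layer volume from mass conservation: V_k = V_0 ρ_0 / ρ_k
    r1_0 = lumen_r + t_int0
    r2_0 = r1_0 + t_ext0
    area_int = math.pi * (r1_0**2 - lumen_r**2) * (length0 / length) \
        * dens["intima"] / rho["intima"]
    area_ext = math.pi * (r2_0**2 - r1_0**2) * (length0 / length) \
        * dens["externa"] / rho["externa"]
    r1 = math.sqrt(lumen_r**2 + area_int / math.pi)
    r2 = math.sqrt(r1**2 + area_ext / math.pi)
    if min(r1 - lumen_r, r2 - r1) < 1.0:
        raise ValueError("stretched wall layer thinner than one voxel")
    if r2 > 0.48 * min(nx, ny) or length > nz - 2:
        raise ValueError("vessel exceeds the phantom grid")

    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    rr = np.hypot(yy - (ny - 1) / 2.0, xx - (nx - 1) / 2.0)
    cov_int = _annulus_coverage(rr, lumen_r, r1)
    cov_ext = _annulus_coverage(rr, r1, r2)

    z = np.arange(nz, dtype=float)
    zc = (nz - 1) / 2.0
    axial = np.clip(length / 2.0 - np.abs(z - zc) + 0.5, 0.0, 1.0)

    grid = np.full(params.shape, params.medium_density, dtype=np.float64)
    grid += axial[:, None, None] * (
        cov_int * (rho["intima"] - params.medium_density)
        + cov_ext * (rho["externa"] - params.medium_density)
    )
    labels = np.zeros(params.shape, dtype=np.uint8)
    in_z = axial >= 0.5
    lab2d = np.zeros((ny, nx), dtype=np.uint8)
    lab2d[cov_int >= 0.5] = LABEL_INTIMA
    lab2d[cov_ext >= 0.5] = LABEL_EXTERNA
    labels[in_z] = lab2d

    vox3 = params.voxel_size_mm**3
    meta = {
        "layer_densities": rho,
        "layer_volumes_mm3": {
            "intima": area_int * length * vox3,
            "externa": area_ext * length * vox3,
        },
        "length_mm": length * params.voxel_size_mm,
        "wall_radii_vox": (lumen_r, r1, r2),
    }
    return DensityPhantom(grid, params.voxel_size_mm, params.medium_density,
                          params.z_over_m, labels, params, meta)


def density_to_optical(
    phantom: DensityPhantom,
    beam: BeamSpec,
    mu_per_density: float = 0.0507,
    wavelength_rounding: Literal["full", "3sf"] = "3sf",
) -> OpticalVolume:
    """Convert mass density to optical properties at the beam energy.

    δ(ρ) = r_e λ² N_A (Z/M) ρ / (2π) per voxel; attenuation uses a single
    proportionality constant μ = ``mu_per_density`` × ρ (tissue ≈ water;
    the default 0.0507 mm⁻¹ per g cm⁻³ is water at 25 keV).  Absorption is
    not the contrast mechanism here — it only sets photon statistics.
    """
    if phantom.z_over_m is None or phantom.z_over_m <= 0:
        raise ValueError("phantom must carry a positive Z/M")
    lam = beam.wavelength(wavelength_rounding)
    factor = delta_per_unit_density(lam, phantom.z_over_m)
    delta = factor * phantom.grid
    mu = mu_per_density * phantom.grid
    return OpticalVolume(delta, mu, lam, phantom.voxel_size_mm,
                         factor * phantom.medium_density)
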