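"""Closed-form design calculations for a two-grating Talbot interferometer.

A phase grating G1 imprints a periodic phase modulation on a quasi-parallel
monochromatic beam; its intensity self-image forms at fractional Talbot
distances downstream, where an absorbing analyser grating G2 converts
sub-pixel fringe shifts into intensity modulation.  The routines here cover
the instrument-level arithmetic: wavelength conversion, Talbot distances,
the geometry of a G2 tilted toward the optical axis (and the virtual
wavelength spread it induces), the energy scaling of the G1 phase shift,
detector geometry, and Beer–Lambert transmission budgets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .constants import HC_KEV_NM

__all__ = [
    "BeamSpec",
    "GratingSpec",
    "GeometrySpec",
    "DetectorSpec",
    "AttenuationEntry",
    "energy_to_wavelength",
    "talbot_distance",
    "tilt_span",
    "achromatic_shift",
    "grating_phase_shift",
    "effective_geometry",
    "transmission",
    "round_sig",
]


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def energy_to_wavelength(
    energy_kev: float,
    rounding: Literal["full", "3sf"] = "full",
) -> float:
    """Convert photon energy (keV) to wavelength (nm) via λ = hc/E.

    ``rounding='3sf'`` truncates the result to three significant figures;
    this is the mode that reproduces the bench numbers quoted at
    λ(25 keV) = 0.0496 nm.
    """
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    lam = HC_KEV_NM / energy_kev
    if rounding == "3sf":
        return round_sig(lam, 3)
    if rounding != "full":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return lam


def talbot_distance(pitch_um: float, wavelength_nm: float, order: int) -> float:
    """Fractional Talbot distance of a π/2 phase grating, in mm.

    z_T = p d² / (2 λ) with odd Talbot order p.
    """
    if order < 1 or order % 2 == 0:
        raise ValueError(f"Talbot order must be an odd positive integer, got {order}")
    if pitch_um <= 0 or wavelength_nm <= 0:
        raise ValueError("pitch and wavelength must be positive")
    d_m = pitch_um * 1e-6
    lam_m = wavelength_nm * 1e-9
    return order * d_m**2 / (2.0 * lam_m) * 1e3


def tilt_span(extent_mm: float, tilt_deg: float) -> float:
    """Half-span Δz of the G1–G2 distance across a tilted G2, in mm.

    With G2's centre at the Talbot distance and the grating inclined by
    ``tilt_deg`` toward the optical axis, the G1–G2 distance varies by
    ±(extent/2)·sin(tilt) between the edges of the grating.
    """
    if extent_mm < 0:
        raise ValueError("grating extent must be non-negative")
    if not 0 <= tilt_deg <= 90:
        raise ValueError(f"tilt angle must lie in [0, 90] degrees, got {tilt_deg}")
    return 0.5 * extent_mm * math.sin(math.radians(tilt_deg))


def achromatic_shift(
    delta_z_mm: float, talbot_distance_mm: float, wavelength_nm: Optional[float] = None
) -> tuple[float, float]:
    """Virtual wavelength shift induced by a G1–G2 distance span ±Δz.

    Since z_T ∝ 1/λ, operating G2 between z_T − Δz and z_T + Δz is
    equivalent to a wavelength spread of relative full span
    Δλ/λ = 2Δz/z_T.  Returns ``(delta_lambda_nm, relative_shift)``;
    ``delta_lambda_nm`` is 0 when no wavelength is supplied.
    """
    if talbot_distance_mm <= 0:
        raise ValueError("Talbot distance must be positive")
    rel = 2.0 * delta_z_mm / talbot_distance_mm
    dlam = rel * wavelength_nm if wavelength_nm is not None else 0.0
    return dlam, rel


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic beam at the sample: energy (keV) and photon flux
    density (photons s⁻¹ mm⁻²)."""

    energy_kev: float
    flux_density: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError("beam energy must be positive")
        if self.flux_density < 0:
            raise ValueError("flux density must be non-negative")

    @property
    def wavelength_nm(self) -> float:
        return energy_to_wavelength(self.energy_kev)

    def wavelength(self, rounding: Literal["full", "3sf"] = "full") -> float:
        return energy_to_wavelength(self.energy_kev, rounding)


@dataclass(frozen=True)
class GratingSpec:
    """One grating: pitch d (µm), kind, design energy/phase for a phase
    grating, physical extent (mm) and inclination toward the optical axis
    (deg, 0 = perpendicular)."""

    pitch_um: float
    kind: Literal["phase", "absorption"] = "phase"
    design_energy_kev: float = 0.0
    design_phase_shift: float = 0.0
    extent_mm: float = 0.0
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("grating pitch must be positive")
        if not 0 <= self.tilt_deg <= 90:
            raise ValueError("tilt must lie in [0, 90] degrees")
        if self.kind == "phase" and not 0 < self.design_phase_shift <= math.pi:
            raise ValueError("design phase shift must lie in (0, π]")


def grating_phase_shift(grating: GratingSpec, energy_kev: float) -> float:
    """Phase shift of a phase grating at ``energy_kev``, in radians.

    Uses the φ ∝ 1/E scaling (δ ∝ λ², thickness fixed), valid away from
    absorption edges of the grating material; this is a model assumption,
    not a tabulated-δ lookup.
    """
    if energy_kev <= 0:
        raise ValueError("query energy must be positive")
    if grating.kind != "phase":
        raise ValueError("phase shift is defined for phase gratings only")
    return grating.design_phase_shift * grating.design_energy_kev / energy_kev


@dataclass(frozen=True)
class DetectorSpec:
    """Lens-coupled scintillator camera: native pixel (µm), lens
    demagnification, pixel count per side, readout time (s), A/D counts per
    detected photon, and an optional effective-pixel override (µm) for the
    case where the calibrated object-plane pixel differs from
    native/magnification."""

    native_pixel_um: float = 6.5
    magnification: float = 0.425
    n_pixels: int = 2048
    readout_s: float = 0.05
    gain: float = 1.0
    effective_pixel_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.native_pixel_um <= 0 or self.n_pixels <= 0 or self.gain <= 0:
            raise ValueError("detector fields must be positive")
        if self.magnification == 0:
            raise ValueError("magnification must be non-zero")

    @property
    def pixel_um(self) -> float:
        if self.effective_pixel_um is not None:
            return self.effective_pixel_um
        return self.native_pixel_um / self.magnification


def effective_geometry(detector: DetectorSpec) -> tuple[float, float]:
    """Object-plane pixel (µm) and field of view (mm, to 0.1 mm)."""
    pix = detector.pixel_um
    fov = round(detector.n_pixels * pix * 1e-3, 1)
    return pix, fov


@dataclass(frozen=True)
class GeometrySpec:
    """Derived interferometer geometry: Talbot order, distance, tilted-G2
    half-span Δz and the virtual wavelength shift it induces."""

    talbot_order: int
    talbot_distance_mm: float
    delta_z_mm: float = 0.0
    delta_lambda_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.talbot_order < 1 or self.talbot_order % 2 == 0:
            raise ValueError("Talbot order must be odd and >= 1")
        if self.talbot_distance_mm <= 0:
            raise ValueError("Talbot distance must be positive")
        if self.delta_z_mm < 0:
            raise ValueError("delta_z must be non-negative")

    @classmethod
    def from_specs(
        cls, beam: BeamSpec, g1: GratingSpec, g2: GratingSpec, order: int = 3,
        wavelength_rounding: Literal["full", "3sf"] = "3sf",
    ) -> "GeometrySpec":
        lam = beam.wavelength(wavelength_rounding)
        z = talbot_distance(g1.pitch_um, lam, order)
        dz = tilt_span(g2.extent_mm, g2.tilt_deg)
        dlam, _ = achromatic_shift(dz, z, lam)
        return cls(order, z, dz, dlam)


@dataclass(frozen=True)
class AttenuationEntry:
    """One absorber in the beam path: mass attenuation coefficient
    (cm² g⁻¹) at the working energy, density (g cm⁻³), path length (mm)."""

    material: str
    mu_over_rho_cm2_g: float
    density_g_cm3: float
    path_mm: float

    def __post_init__(self) -> None:
        if self.mu_over_rho_cm2_g < 0 or self.density_g_cm3 < 0:
            raise ValueError("attenuation coefficients must be non-negative")
        if self.path_mm < 0:
            raise ValueError("path length must be non-negative")

    @property
    def optical_depth(self) -> float:
        return self.mu_over_rho_cm2_g * self.density_g_cm3 * self.path_mm * 0.1


def transmission(entries: Iterable[AttenuationEntry]) -> float:
    """Beer–Lambert transmission exp(−Σ (μ/ρ)·ρ·t) over the entries.

    Coefficients are caller-supplied (no embedded attenuation database);
    an empty list is a clear beam with transmission 1.
    """
    total = sum(e.optical_depth for e in entries)
    return math.exp(-total)
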