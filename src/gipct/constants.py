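"""Physical constants used throughout the package, fixed in one place.

Unit conventions: photon energies in keV, wavelengths in nm, lengths on the
bench in mm, grating pitches in µm, mass densities in g cm⁻³.
"""

#: hc in keV·nm, so that wavelength_nm = HC_KEV_NM / energy_keV.
HC_KEV_NM = 1.23984

#: Classical electron radius in metres.
R_E_M = 2.8179e-15

#: Avogadro's constant in mol⁻¹.
N_AVOGADRO = 6.022e23


def delta_per_unit_density(wavelength_nm: float, z_over_m: float) -> float:
    """Refractive-index decrement per unit mass density, dδ/dρ.

    For soft matter far from absorption edges the decrement is proportional
    to electron density,

        δ = r_e λ² N_A (Z/M) ρ / (2π),

    with Z/M the electrons-per-molecular-weight ratio (dimensionless
    convention, mol g⁻¹ scale; 0.55 is the soft-tissue average).

    Parameters
    ----------
    wavelength_nm : X-ray wavelength in nm.
    z_over_m : Z/M ratio of the material.

    Returns
    -------
    float
        δ per (g cm⁻³), dimensionless per unit density.
    """
    import math

    lam_m = wavelength_nm * 1e-9
    # ρ in g cm⁻³ → g m⁻³ carries a factor 1e6
    return R_E_M * lam_m**2 * N_AVOGADRO * z_over_m * 1e6 / (2.0 * math.pi)
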