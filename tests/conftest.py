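"""Shared fixtures: small synthetic volumes and an independent ramp-FBP
oracle used for two-route reconstruction checks."""

from __future__ import annotations

import numpy as np
import pytest

from gipct.instrument import BeamSpec
from gipct.phantoms import DensityPhantom, density_to_optical

G2_PITCH_UM = 10.0
TALBOT_MM = 3024.0
PIXEL_MM = 0.1


def cylinder_phantom(n=64, nz=3, radius=12.0, drho=0.02, medium=1.0):
    """Antialiased homogeneous cylinder (axis vertical) in saline."""
    yy, xx = np.meshgrid(np.arange(n) - (n - 1) / 2,
                         np.arange(n) - (n - 1) / 2, indexing="ij")
    rr = np.hypot(yy, xx)
    cov = np.clip(radius - rr + 0.5, 0.0, 1.0)
    grid = np.full((nz, n, n), medium) + drho * cov[None]
    return DensityPhantom(grid, PIXEL_MM, medium), rr


@pytest.fixture(scope="session")
def cylinder_optical():
    phantom, rr = cylinder_phantom()
    return density_to_optical(phantom, BeamSpec(25.0)), rr


def ramp_fbp_oracle(p_px: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Independent route: ramp-filter integrated projections, backproject.

    ``p_px`` are line integrals in pixel units, shape (n_angles, nx).
    Written from the textbook FBP formula, not shared with the package's
    Hilbert filtering code.
    """
    na, nx = p_px.shape
    npad = 4 * nx
    f = np.fft.fftfreq(npad)
    filt = np.fft.fft(p_px, n=npad, axis=-1) * np.abs(f)
    g = np.fft.ifft(filt, axis=-1).real[:, :nx]
    c = (nx - 1) / 2.0
    xs = np.arange(nx) - c
    xg, yg = np.meshgrid(xs, xs, indexing="xy")
    rec = np.zeros((nx, nx))
    for i, ang in enumerate(angles_deg):
        th = np.deg2rad(ang)
        s = xg * np.cos(th) - yg * np.sin(th) + c
        s0 = np.floor(s).astype(int)
        w = s - s0
        val = (1 - w) * g[i][np.clip(s0, 0, nx - 1)] \
            + w * g[i][np.clip(s0 + 1, 0, nx - 1)]
        rec += np.where((s >= 0) & (s <= nx - 1), val, 0.0)
    return rec * np.pi / na
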