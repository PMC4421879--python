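"""N-step phase-stepping retrieval and flat-field correction.

Per pixel the stepping curve I_k = I₀[1 + V cos(2πk/N + ψ)] is sampled at N
equally spaced analyser positions over one grating period.  The standard
first-harmonic estimator recovers the triplet exactly for a noiseless
sinusoid at any N ≥ 3:

    I₀ = mean_k I_k,   a₁ = (2/N) Σ_k I_k e^{−2πik/N},
    ψ = arg a₁,        V = |a₁| / I₀.

Flat-field correction divides/subtracts a no-sample retrieval (nearest in
rotation angle) to remove instrument-induced transmission, phase and
visibility structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = ["RetrievalResult", "RetrievedProjection", "retrieve",
           "flat_correct", "unwrap_rows", "wrap_phase", "nearest_flat_index"]


class RetrievalResult(NamedTuple):
    """Per-pixel (mean intensity, stepping phase, visibility) maps plus a
    validity mask (False where the mean intensity vanished)."""

    i0: np.ndarray
    psi: np.ndarray
    vis: np.ndarray
    valid: np.ndarray


@dataclass
class RetrievedProjection:
    """Flat-corrected projection: transmission, differential phase wrapped
    to (−π, π], and the sample/reference visibility ratio (dark field)."""

    trans: np.ndarray
    dphase: np.ndarray
    vis_ratio: np.ndarray
    angle_deg: float = 0.0
    valid: Optional[np.ndarray] = None


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


def retrieve(frames: np.ndarray, axis: int = 0) -> RetrievalResult:
    """First-harmonic retrieval over the stepping axis.

    ``frames`` holds the N_step count images along ``axis``; any other
    shape (single pixel, row, stack of angles) is accepted.
    """
    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[axis]
    if n < 3:
        raise ValueError(f"phase stepping retrieval needs >= 3 frames, got {n}")
    frames = np.moveaxis(frames, axis, 0)
    k = np.arange(n).reshape((n,) + (1,) * (frames.ndim - 1))
    phases = np.exp(-2j * np.pi * k / n)
    i0 = frames.mean(axis=0)
    a1 = (2.0 / n) * (frames * phases).sum(axis=0)
    valid = i0 > 0
    safe = np.where(valid, i0, 1.0)
    psi = np.angle(a1)
    vis = np.abs(a1) / safe
    psi = np.where(valid, psi, 0.0)
    vis = np.where(valid, vis, 0.0)
    return RetrievalResult(i0, psi, vis, valid)


def flat_correct(
    sample: RetrievalResult, reference: RetrievalResult, angle_deg: float = 0.0
) -> RetrievedProjection:
    """Reference the sample retrieval against a no-sample (flat) retrieval."""
    if sample.i0.shape != reference.i0.shape:
        raise ValueError("sample and reference shapes differ")
    valid = sample.valid & reference.valid
    ref_i0 = np.where(valid, reference.i0, 1.0)
    ref_v = np.where(reference.vis > 0, reference.vis, 1.0)
    trans = np.where(valid, sample.i0 / ref_i0, 0.0)
    dphase = np.where(valid, wrap_phase(sample.psi - reference.psi), 0.0)
    vis_ratio = np.where(valid, sample.vis / ref_v, 0.0)
    return RetrievedProjection(trans, dphase, vis_ratio, angle_deg, valid)


def unwrap_rows(dphase: np.ndarray) -> np.ndarray:
    """1-D phase unwrapping along the differential (last) axis, per row.

    Successive differences exceeding π are shifted by multiples of 2π;
    a map without jumps is returned unchanged.
    """
    return np.unwrap(np.asarray(dphase, dtype=np.float64), axis=-1)


def nearest_flat_index(angle_deg: float, flat_angles_deg: Sequence[float]) -> int:
    """Index of the flat block nearest in rotation angle."""
    flats = np.asarray(flat_angles_deg, dtype=float)
    if flats.size == 0:
        raise ValueError("no flat blocks available")
    return int(np.argmin(np.abs(flats - angle_deg)))


def retrieve_stack(stack) -> tuple[list[RetrievedProjection], RetrievalResult]:
    """Retrieve and flat-correct every angle of a SteppingStack.

    Returns the per-angle flat-corrected projections and the reference
    retrieval used for all of them (a single simulated flat block).
    """
    ref = retrieve(stack.reference, axis=0)
    out = []
    for i, ang in enumerate(np.atleast_1d(stack.angles_deg)):
        s = retrieve(stack.frames[i], axis=0)
        out.append(flat_correct(s, ref, float(ang)))
    return out, ref
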