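"""Run configuration: defaults, loading, validation."""

from __future__ import annotations

import copy
import math
from pathlib import Path
from typing import Any, Dict, List, Tuple

import yaml

Finding = Tuple[str, str]  # (level: "error"|"warning", message)

DEFAULT_CONFIG: Dict[str, Any] = {
    "instrument": {
        "energy_kev": 25.0,
        "flux_density": 1.2e8,  # photons s^-1 mm^-2 at the sample
        "g1": {"pitch_um": 10.0, "design_energy_kev": 18.8,
               "design_phase": math.pi / 2, "extent_mm": 25.0},
        "g2": {"pitch_um": 10.0, "extent_mm": 25.0, "tilt_deg": 45.0},
        "talbot_order": 3,
        "detector": {"native_pixel_um": 6.5, "magnification": 0.425,
                     "n_pixels": 2048, "readout_s": 0.05,
                     "effective_pixel_um": 15.5},
    },
    "scan": {
        "n_projections": 600, "n_steps": 5, "exposure_s": 0.5,
        "readout_s": 0.05, "settle_s": 0.03, "pulses_per_180": 90000,
        "pulse_resolution_deg": 0.002, "flat_interval_deg": 36.0,
        "flat_frames": None,
    },
    "phantom": {
        "scenario": "fetus_fresh", "shape": [48, 48, 48],
        "voxel_size_mm": 0.1, "medium_density": 1.0, "z_over_m": 0.55,
        "shrinkage": 0.35, "density_increment": 0.015, "stretch_step": 0,
    },
    "simulation": {
        "n_angles": 60, "photon_budget": 0.0, "visibility": 0.3,
        "profile": "sine", "gain": 7.0, "noiseless": True, "seed": 0,
    },
    "reconstruction": {"apodize": True},
    "densitometry": {"calibration": 1.0, "bin_width_g_cm3": 0.002},
    "output_dir": "runs/demo",
}

_KNOWN_SCENARIOS = ("fetus_fresh", "fetus_fixed", "aorta_stretch")


def default_config() -> Dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> Dict[str, Any]:
    """Load a YAML config merged over the package defaults."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    return cfg


def validate_config(cfg: Dict[str, Any] | str | Path) -> List[Finding]:
    """Sanity-check a configuration; returns (level, message) findings."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    findings: List[Finding] = []

    inst, scan, ph, sim = (cfg["instrument"], cfg["scan"], cfg["phantom"],
                           cfg["simulation"])
    if inst["energy_kev"] <= 0:
        findings.append(("error", "instrument.energy_kev must be positive"))
    order = inst["talbot_order"]
    if order < 1 or order % 2 == 0:
        findings.append(("error", f"talbot_order must be odd, got {order}"))
    if not 0 <= inst["g2"].get("tilt_deg", 0.0) <= 90:
        findings.append(("error", "g2.tilt_deg must lie in [0, 90]"))

    if scan["n_steps"] < 3:
        findings.append(("error", "scan.n_steps must be >= 3"))
    for key in ("exposure_s", "readout_s", "settle_s"):
        if scan[key] < 0:
            findings.append(("error", f"scan.{key} must be non-negative"))
    if not math.isclose(scan["pulses_per_180"] * scan["pulse_resolution_deg"],
                        180.0, rel_tol=1e-9):
        findings.append(("error",
                         "pulses_per_180 × pulse_resolution_deg must equal 180°"))
    fi = scan["flat_interval_deg"]
    if fi > 0:
        ratio = 180.0 / fi
        if not math.isclose(ratio, round(ratio), rel_tol=1e-9):
            findings.append(("warning",
                             f"flat interval {fi}° does not divide 180°; the last "
                             "partial interval gets no flat block"))

    if ph["scenario"] not in _KNOWN_SCENARIOS:
        findings.append(("error", f"unknown phantom scenario {ph['scenario']!r}"))
    if not 0 <= ph["shrinkage"] < 1:
        findings.append(("error", "phantom.shrinkage must lie in [0, 1)"))
    if ph["density_increment"] < 0:
        findings.append(("error", "phantom.density_increment must be >= 0"))

    if not 0 <= sim["visibility"] <= 1:
        findings.append(("error", "simulation.visibility must lie in [0, 1]"))
    if sim["profile"] not in ("sine", "triangle"):
        findings.append(("error", f"unknown stepping profile {sim['profile']!r}"))
    if sim["n_angles"] < 3:
        findings.append(("error", "simulation.n_angles must be >= 3"))
    return findings
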