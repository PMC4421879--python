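"""Pipeline driver: phantom → simulate → retrieve → reconstruct → report.

Every stage is re-entrant from its on-disk artifacts, deterministic for a
fixed seed, and records its outputs in a manifest JSON with checksums.
One seed governs all stochastic stages; per-stage streams are split
deterministically from it by stable stage labels.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import zlib
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np

from . import densitometry, forward_model, io, phantoms, retrieval, scheduler
from .config import validate_config
from .instrument import (BeamSpec, DetectorSpec, GeometrySpec, GratingSpec,
                         effective_geometry)
from .reconstruct import fbp_dpc

STAGES = ("phantom", "simulate", "retrieve", "reconstruct", "report")


def stage_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(label.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def design_summary(cfg: Dict[str, Any]) -> Dict[str, float]:
    """Closed-form instrument and scan numbers (calculator mode)."""
    inst, scan = cfg["instrument"], cfg["scan"]
    beam = BeamSpec(inst["energy_kev"], inst.get("flux_density", 0.0))
    g1 = GratingSpec(inst["g1"]["pitch_um"], "phase",
                     inst["g1"]["design_energy_kev"], inst["g1"]["design_phase"],
                     inst["g1"].get("extent_mm", 0.0))
    g2 = GratingSpec(inst["g2"]["pitch_um"], "absorption",
                     extent_mm=inst["g2"].get("extent_mm", 0.0),
                     tilt_deg=inst["g2"].get("tilt_deg", 0.0))
    geom = GeometrySpec.from_specs(beam, g1, g2, inst["talbot_order"])
    det = DetectorSpec(**inst["detector"])
    pix, fov = effective_geometry(det)
    protocol = scheduler.ScanProtocol(
        n_projections=scan["n_projections"], n_steps=scan["n_steps"],
        exposure_s=scan["exposure_s"], readout_s=scan["readout_s"],
        settle_s=scan["settle_s"], pulses_per_180=scan["pulses_per_180"],
        pulse_resolution_deg=scan["pulse_resolution_deg"],
        flat_interval_deg=scan["flat_interval_deg"],
        flat_frames=scan.get("flat_frames"),
    )
    return {
        "wavelength_nm": beam.wavelength("3sf"),
        "talbot_distance_mm": geom.talbot_distance_mm,
        "delta_z_mm": geom.delta_z_mm,
        "relative_wavelength_shift": 2 * geom.delta_z_mm / geom.talbot_distance_mm,
        "delta_lambda_nm": geom.delta_lambda_nm,
        "effective_pixel_um": pix,
        "field_of_view_mm": fov,
        "stepping_period_s": scheduler.step_period(protocol),
        "rotation_speed_pps": scheduler.rotation_speed(protocol),
        "total_time_s": scheduler.total_time(protocol),
    }


def _geometry(cfg: Dict[str, Any]) -> tuple[BeamSpec, float, float]:
    inst = cfg["instrument"]
    beam = BeamSpec(inst["energy_kev"], inst.get("flux_density", 0.0))
    lam = beam.wavelength("3sf")
    from .instrument import talbot_distance

    z = talbot_distance(inst["g1"]["pitch_um"], lam, inst["talbot_order"])
    return beam, inst["g2"]["pitch_um"], z


def run_pipeline(
    cfg: Dict[str, Any],
    stages: Optional[Sequence[str]] = None,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
    log=lambda msg: None,
) -> Dict[str, Any]:
    """Execute the pipeline (or a contiguous subset of stages) and return
    the manifest.  Earlier stages are consumed from disk when skipped."""
    problems = [f for f in validate_config(cfg) if f[0] == "error"]
    if problems:
        raise ValueError("invalid config: " + "; ".join(m for _, m in problems))
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg["simulation"]["seed"] if seed is None else seed)

    manifest_path = out / "manifest.json"
    manifest: Dict[str, Any] = (
        json.loads(manifest_path.read_text()) if manifest_path.exists()
        else {"artifacts": {}}
    )
    manifest["seed"] = master_seed
    arts: Dict[str, str] = manifest["artifacts"]

    def record(name: str, path: Path) -> None:
        arts[name] = _sha256(path)

    def require(name: str, stage: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs artifact '{name}'; run its upstream "
                "stage first")
        return p

    beam, g2_pitch, z_t = _geometry(cfg)
    sim = cfg["simulation"]
    t_start = time.time()

    if "phantom" in stages:
        t0 = time.time()
        ph_cfg = cfg["phantom"]
        params = phantoms.ScenarioParams(
            scenario=ph_cfg["scenario"], shape=tuple(ph_cfg["shape"]),
            voxel_size_mm=ph_cfg["voxel_size_mm"],
            medium_density=ph_cfg["medium_density"],
            z_over_m=ph_cfg["z_over_m"], shrinkage=ph_cfg["shrinkage"],
            density_increment=ph_cfg["density_increment"],
            stretch_step=ph_cfg["stretch_step"],
            seed=stage_seed(master_seed, "phantom"),
        )
        maker = (phantoms.make_aorta_phantom if params.scenario == "aorta_stretch"
                 else phantoms.make_fetus_phantom)
        phantom = maker(params)
        io.write_phantom(phantom, out / "phantom.tif")
        record("phantom.tif", out / "phantom.tif")
        if phantom.labels is not None:
            record("phantom_labels.tif", out / "phantom_labels.tif")
        log(f"phantom: {params.scenario} {params.shape} "
            f"[{time.time() - t0:.2f} s]")

    if "simulate" in stages:
        t0 = time.time()
        phantom = io.read_phantom(require("phantom.tif", "simulate"))
        optical = phantoms.density_to_optical(phantom, beam)
        n_ang = sim["n_angles"]
        angles = np.arange(n_ang) * 180.0 / n_ang
        projs = forward_model.project(optical, angles, g2_pitch, z_t)
        stack = forward_model.simulate_stepping(
            projs, photon_budget=sim["photon_budget"],
            visibility=sim["visibility"], n_steps=cfg["scan"]["n_steps"],
            profile=sim["profile"], gain=sim["gain"],
            seed=stage_seed(master_seed, "simulate"),
            noiseless=bool(sim.get("noiseless", False)) or sim["photon_budget"] <= 0,
        )
        steps_dir = out / "stepping"
        steps_dir.mkdir(exist_ok=True)
        dtype = "float32" if stack.frames.dtype.kind == "f" else "uint16"
        for i, ang in enumerate(angles):
            p = steps_dir / f"angle_{i:04d}.tif"
            io.write_stack(p, stack.frames[i], {"angle_deg": float(ang)}, "float32")
            record(f"stepping/{p.name}", p)
        io.write_stack(steps_dir / "reference.tif", stack.reference, {}, "float32")
        record("stepping/reference.tif", steps_dir / "reference.tif")
        (steps_dir / "manifest.json").write_text(json.dumps({
            "angles_deg": angles.tolist(), "seed": stack.seed,
            "photon_budget": stack.photon_budget, "visibility": stack.visibility,
            "gain": stack.gain, "profile": stack.profile,
            "pixel_size_mm": projs.pixel_size_mm,
        }, indent=2))
        record("stepping/manifest.json", steps_dir / "manifest.json")
        log(f"simulate: {n_ang} angles [{time.time() - t0:.2f} s]")

    if "retrieve" in stages:
        t0 = time.time()
        steps_dir = out / "stepping"
        meta = json.loads(require("stepping/manifest.json", "retrieve").read_text())
        angles = np.asarray(meta["angles_deg"])
        ref_frames, _ = io.read_stack(steps_dir / "reference.tif")
        ref = retrieval.retrieve(ref_frames, axis=0)
        trans, dph, visr = [], [], []
        for i, ang in enumerate(angles):
            frames, _ = io.read_stack(steps_dir / f"angle_{i:04d}.tif")
            rp = retrieval.flat_correct(retrieval.retrieve(frames, axis=0), ref,
                                        float(ang))
            trans.append(rp.trans)
            dph.append(rp.dphase)
            visr.append(rp.vis_ratio)
        for name, data in (("trans", trans), ("dphase", dph), ("vis_ratio", visr)):
            p = out / f"retrieved_{name}.tif"
            io.write_stack(p, np.stack(data), {
                "angles_deg": angles.tolist(),
                "pixel_size_mm": meta["pixel_size_mm"]})
            record(p.name, p)
        log(f"retrieve: {len(angles)} angles [{time.time() - t0:.2f} s]")

    if "reconstruct" in stages:
        t0 = time.time()
        dph, meta = io.read_stack(require("retrieved_dphase.tif", "reconstruct"))
        angles = np.asarray(meta["angles_deg"])
        vol = fbp_dpc(dph.astype(np.float64), angles, g2_pitch, z_t,
                      meta["pixel_size_mm"],
                      apodize=cfg["reconstruction"]["apodize"],
                      wavelength_nm=beam.wavelength("3sf"))
        io.write_delta_volume(vol, out / "delta_volume.tif")
        record("delta_volume.tif", out / "delta_volume.tif")
        log(f"reconstruct: {vol.grid.shape} [{time.time() - t0:.2f} s]")

    if "report" in stages:
        t0 = time.time()
        vol = io.read_delta_volume(require("delta_volume.tif", "report"))
        phantom = io.read_phantom(require("phantom.tif", "report"))
        dens_cfg = cfg["densitometry"]
        conv = densitometry.DensityConversion(
            beam.wavelength("3sf"), phantom.z_over_m,
            dens_cfg["calibration"], phantom.medium_density)
        dv = densitometry.delta_to_density(vol, conv)
        masks: Dict[str, np.ndarray] = {}
        if phantom.labels is not None:
            for lab in np.unique(phantom.labels):
                if lab == 0:
                    continue
                masks[f"label_{int(lab)}"] = phantom.labels == lab
        bg = _background_mask(phantom)
        report = densitometry.build_report(dv, masks, bg,
                                           dens_cfg["bin_width_g_cm3"])
        report.to_csv(out / "density_report.csv")
        record("density_report.csv", out / "density_report.csv")
        for name, (edges, counts) in report.histograms.items():
            hist_path = out / f"histogram_{name}.csv"
            centers = 0.5 * (edges[:-1] + edges[1:])
            with open(hist_path, "w") as fh:
                fh.write("bin_center,count\n")
                for c, cnt in zip(centers, counts):
                    fh.write(f"{c:.6f},{int(cnt)}\n")
            record(hist_path.name, hist_path)
        summary = {
            "background_resolution_mg_cm3": report.background_resolution_mg_cm3,
            "rois": report.rois.to_dict(orient="records"),
        }
        (out / "density_report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        record("density_report.json", out / "density_report.json")
        log(f"report: {len(masks)} compartments [{time.time() - t0:.2f} s]")

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _background_mask(phantom: phantoms.DensityPhantom) -> np.ndarray:
    """Medium voxels inside the reconstructed cylinder, away from the sample."""
    nz, ny, nx = phantom.grid.shape
    yy, xx = np.meshgrid(np.arange(ny) - (ny - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    rr = np.hypot(yy, xx)
    inside = rr <= min(ny, nx) / 2.0 - 3
    medium = phantom.grid <= phantom.medium_density + 1e-9
    if phantom.labels is not None:
        medium &= phantom.labels == 0
    from scipy import ndimage as ndi

    medium = ndi.binary_erosion(medium, iterations=2)
    return medium & inside[None, :, :]
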