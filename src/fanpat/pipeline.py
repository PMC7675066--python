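"""Stage runner and bundled phantom fixtures.

``run_pipeline`` executes simulate -> preprocess -> reconstruct -> evaluate
for any contiguous subset of stages, passing artifacts through well-known
file names in the output directory.  Every artifact embeds the config hash,
so identical config + seed reproduce identical outputs and a stale input is
detectable.  ``make_fixture`` writes ready-to-run configs for canonical
phantoms, including a calibration phantom that emulates the threaded-wire
scaffold topology (0.25 mm diameter line -> 0.0125 cm radius, stored as a
radius explicitly) and a 0.5 mm rod embedded 2 cm deep.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import RunConfig, config_hash
from .evaluate import depth_error, image_error, line_profile, rmse, snr_fwhm, ssim
from .io import load_scan, save_json, save_scan, save_volume
from .preprocess import preprocess_planes
from .reconstruct import reconstruct_scan
from .simulate import simulate_scan, voxelize_phantom

log = logging.getLogger("fanpat")

STAGES = ("simulate", "preprocess", "reconstruct", "evaluate")

__all__ = ["run_pipeline", "make_fixture", "fixture_config", "FIXTURES"]


def run_pipeline(config: RunConfig, stages=STAGES, outdir=".") -> dict:
    """Run the requested stages; returns a dict of artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ValueError(f"no valid stages among {STAGES}")
    chash = config_hash(config)
    meta = {"config_hash": chash, "version": __version__, "config": config.to_dict()}
    artifacts: dict = {}

    geom = config.build_geometry()
    plan = config.build_plan()
    illum = config.build_illuminator(geom)
    optics = config.build_optics()
    grid = config.build_grid()

    scan_path = outdir / "scan.h5"
    clean_path = outdir / "clean.h5"
    recon_path = outdir / "recon.nii.gz"

    if "simulate" in stages:
        log.info("simulate: %d poses", plan.n_angles)
        planes = simulate_scan(
            config.build_phantom(), geom, illum, plan, optics,
            directivity=config.build_directivity(), noise=config.build_noise(),
            n_patches=config.reconstruction.n_patches, grid_spacing=grid.spacing,
        )
        save_scan(scan_path, planes, meta)
        artifacts["scan"] = scan_path

    if "preprocess" in stages:
        if not scan_path.exists():
            raise FileNotFoundError(
                f"{scan_path} is missing; run the 'simulate' stage (or supply a scan) first"
            )
        planes, _ = load_scan(scan_path)
        pp = config.preprocess
        clean, report = preprocess_planes(
            planes, order=pp.order, cutoff=pp.cutoff, k=pp.k, zero_phase=pp.zero_phase
        )
        save_scan(clean_path, clean, meta)
        save_json(
            outdir / "denoise_report.json",
            {
                "config_hash": chash,
                "discarded_rank": report.discarded_rank,
                "noise_fraction": report.noise_fraction,
                "per_plane_noise_fraction": report.flags,
            },
        )
        artifacts["clean"] = clean_path

    if "reconstruct" in stages:
        src = clean_path if clean_path.exists() else scan_path
        if not src.exists():
            raise FileNotFoundError(
                f"neither {clean_path} nor {scan_path} exists; run 'preprocess' or 'simulate' first"
            )
        planes, _ = load_scan(src)
        rc = config.reconstruction
        vol = reconstruct_scan(
            planes, geom, illum, plan, optics, grid,
            directivity=config.build_directivity(), compensate=rc.compensation,
            n_patches=rc.n_patches, epsilon=rc.epsilon,
        )
        save_volume(
            recon_path,
            vol,
            sidecar={
                "config_hash": chash,
                "kind": vol.kind,
                "compensation": vol.compensation,
                "directivity_used": vol.directivity_used,
                "grid": {"origin": grid.origin, "spacing": grid.spacing, "shape": grid.shape},
                "extras": vol.extras,
            },
        )
        artifacts["recon"] = recon_path

    if "evaluate" in stages:
        if not recon_path.exists():
            raise FileNotFoundError(f"{recon_path} is missing; run 'reconstruct' first")
        from .io import load_volume

        values, _ = load_volume(recon_path)
        model = voxelize_phantom(config.build_phantom(), grid)
        ev = config.evaluation
        report = {
            "config_hash": chash,
            "rmse": rmse(values / max(np.abs(values).max(), 1e-300), model / max(model.max(), 1e-300)),
            "ssim": ssim(values / max(np.abs(values).max(), 1e-300), model / max(model.max(), 1e-300)),
        }
        if np.any(model):
            report["image_error"] = image_error(values, model, normalize=ev.normalize)
            curve = depth_error(values, model, grid, n_shells=ev.n_shells)
            report["depth_shell_edges_cm"] = curve.shell_edges
            report["depth_shell_errors"] = curve.errors
        if ev.profile_p0 is not None and ev.profile_p1 is not None:
            prof, step_mm = line_profile(values, grid, ev.profile_p0, ev.profile_p1)
            pm = snr_fwhm(prof, values, step_mm)
            report["snr_db"] = pm.snr_db
            report["fwhm_mm"] = pm.fwhm
        save_json(outdir / "report.json", report)
        artifacts["report"] = outdir / "report.json"

    return artifacts


# ---------------------------------------------------------------------------
# fixtures

_APEX = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])  # arc-apex direction


def _desk_plan(n_angles: int = 16) -> dict:
    # record long enough to reach the whole grid from every pose
    return {
        "n_angles": n_angles,
        "angular_step": 360.0 / n_angles,
        "sampling_rate": 40e6,
        "n_samples": 4800,
        "sound_speed": 1500.0,
    }


def _grid_around(center: np.ndarray, shape=(64, 64, 64), spacing: float = 0.05) -> dict:
    origin = center - spacing * (np.asarray(shape) - 1) / 2
    return {"origin": [round(float(v), 6) for v in origin], "spacing": spacing,
            "shape": list(shape)}


def _wire(start, end, radius, absorption=1.0):
    return [[round(float(v), 6) for v in start], [round(float(v), 6) for v in end],
            radius, absorption]


def _cal_phantom_wires(
    center: np.ndarray, n_columns: int = 5, column_radius: float = 1.2,
    heights=(-0.8, 0.0, 0.8), wire_radius: float = 0.0125,
):
    """Thread one line through holes on a ring of columns at varying heights."""
    attach = []
    for i, h in enumerate(heights):
        for j in range(n_columns):
            ang = 2 * np.pi * ((j * 2) % n_columns) / n_columns  # skip pattern
            attach.append(center + np.array(
                [column_radius * np.cos(ang), column_radius * np.sin(ang), h]
            ))
    return [
        _wire(attach[k], attach[k + 1], wire_radius) for k in range(len(attach) - 1)
    ]


def fixture_config(name: str) -> dict:
    """Ready-to-run config dict for a named fixture phantom."""
    c0 = 9.0 * _APEX  # 3 cm deep in front of the arc apex
    if name == "point_source":
        # single absorber on the rotation axis at 3 cm depth
        p = np.array([0.0, 0.0, 9.0])
        return {
            "plan": _desk_plan(16),
            "grid": _grid_around(p, shape=(48, 48, 48)),
            "phantom": {"wires": [_wire(p - [0, 0, 0.012], p + [0, 0, 0.012], 0.0125)]},
            "noise": {"enabled": False},
        }
    if name == "three_wire":
        w = []
        for depth, tilt in ((1.0, -0.3), (2.0, 0.0), (3.0, 0.3)):
            c = (12.0 - depth) * _APEX
            w.append(_wire(c + np.array([tilt, -1.2, 0]), c + np.array([-tilt, 1.2, 0]), 0.0125))
        return {
            "plan": _desk_plan(16),
            "grid": _grid_around(10.0 * _APEX, shape=(64, 64, 64)),
            "phantom": {"wires": w},
            "optics": {"mu_a0": 0.0075, "mu_s": 15.0},
        }
    if name == "cal_phantom":
        return {
            "plan": _desk_plan(16),
            "grid": _grid_around(c0, shape=(64, 64, 64)),
            "phantom": {"wires": _cal_phantom_wires(c0)},
            "optics": {"mu_a0": 0.0075, "mu_s": 15.0},
        }
    if name == "deep_rod":
        c = 10.0 * _APEX  # 2 cm deep
        return {
            "plan": _desk_plan(16),
            "grid": _grid_around(c, shape=(48, 48, 48)),
            "phantom": {"wires": [_wire(c - [0, 0.5, 0], c + [0, 0.5, 0], 0.025)]},
        }
    raise ValueError(f"unknown fixture {name!r}; valid: {sorted(FIXTURES)}")


FIXTURES = ("point_source", "three_wire", "cal_phantom", "deep_rod")


def make_fixture(name: str, out_dir=".") -> Path:
    """Write <name>.yaml into out_dir; regeneration is byte-identical."""
    cfg = fixture_config(name)
    RunConfig.from_dict(cfg)  # validate
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
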