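"""Canned desk-scale simulation studies.

These reproduce, at workstation scale, the system-level checks used to
characterize the scanner: forward-then-invert point-source localization, the
four-variant (directivity x illumination-compensation) depth-error
comparison, and SNR/FWHM of a deep rod.  Problem sizes are chosen so each
study runs in minutes on one CPU; the methods note discusses what the
reductions preserve.

Two design constraints recur.  First, the temporal pulse is set to 1 MHz so
the reconstructed point response (a few tenths of a millimeter at full DAQ
bandwidth) is resolvable on the 1 mm study grids; a sharper pulse would
alias between voxel centers.  Second, phantoms are placed where the reduced
pose count still covers them: localization targets sit near the rotation
axis, where pose planes bunch together, and depth-error wires lie in the
pose-0 imaging plane, which the arc views head-on exactly as the real
scanner images its in-plane slice.
"""

from __future__ import annotations

import numpy as np

from .evaluate import compare_variants, line_profile, snr_fwhm
from .geometry import AcquisitionPlan, VoxelGrid, build_array, default_illuminator, rotate_pose
from .optics import MILK_MIX_OPTICS
from .reconstruct import DirectivityModel, backproject_plane
from .simulate import NoiseModel, PhantomModel, default_pulse, simulate_scan, voxelize_phantom

__all__ = ["localization_study", "depth_error_study", "deep_rod_study"]

_APEX = np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)])
_TANG = np.array([np.cos(np.pi / 4), 0.0, -np.sin(np.pi / 4)])


def localization_study(
    seed: int,
    n_sources: int = 10,
    n_angles: int = 32,
    grid_shape: int = 64,
    spacing: float = 0.1,
    min_separation: float = 1.2,
) -> dict:
    """Noise-free forward-then-invert localization of random point sources.

    Point absorbers are scattered near the rotation axis, a full scan is
    simulated without noise or directivity (the check isolates the delay
    geometry), and each source is located by the argmax of |reconstruction|
    in a 9-voxel window centered on its true position.  Returns per-source
    localization errors in voxel units.
    """
    rng = np.random.default_rng(seed)
    geom = build_array()
    plan = AcquisitionPlan(
        n_angles=n_angles, angular_step=360.0 / n_angles, n_samples=4800
    )
    illum = default_illuminator(geom)
    center = np.array([0.0, 0.0, 3.0])
    half = spacing * (grid_shape - 1) / 2
    grid = VoxelGrid(origin=tuple(center - half), spacing=spacing, shape=(grid_shape,) * 3)

    sources: list[np.ndarray] = []
    while len(sources) < n_sources:
        p = center + rng.uniform(-2.6, 2.6, 3)
        if all(np.linalg.norm(p - q) > min_separation for q in sources):
            sources.append(p)
    pts = np.asarray(sources)

    from .reconstruct import reconstruct_scan
    from .simulate import _forward_points

    planes = []
    for a in plan.pose_angles:
        g, _ = rotate_pose(geom, illum, float(a))
        planes.append(
            _forward_points(
                pts, np.ones(n_sources), np.ones(n_sources), g, plan, float(a),
                pulse=default_pulse(plan.sampling_rate, center_frequency=1e6),
            )
        )
    acc = reconstruct_scan(
        planes, geom, illum, plan, MILK_MIX_OPTICS, grid,
        compensate=False, accumulation="sum",
    ).values

    errors = []
    for p in pts:
        true_idx = grid.world_to_index(p)
        idx = np.round(true_idx).astype(int)
        lo = np.maximum(idx - 4, 0)
        hi = np.minimum(idx + 5, grid_shape)
        sub = np.abs(acc[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
        am = np.unravel_index(np.argmax(sub), sub.shape)
        # offset, in voxels per axis, between the peak voxel and the voxel
        # containing the true source: 0 = same voxel, 1 = immediate neighbor
        errors.append(float(np.abs(lo + np.array(am) - idx).max()))
    return {
        "errors_voxels": errors,
        "max_error_voxels": max(errors),
        "n_sources": n_sources,
        "n_angles": n_angles,
        "grid_shape": grid_shape,
        "spacing_cm": spacing,
    }


def in_plane_wire_phantom(radius: float = 0.0125) -> PhantomModel:
    """Three 0.25 mm wires at 0.8 / 1.8 / 2.8 cm depth, tangential in-plane.

    Built in the equator-apex frame (arc centered at polar angle 90°, so the
    imaging plane's depth axis is +x and the wires run along z, aligned with
    the evaluation grid).
    """
    return PhantomModel(
        wires=tuple(
            ((x, 0.0, -1.55), (x, 0.0, 1.55), radius, 1.0) for x in (11.2, 10.2, 9.2)
        )
    )


def _simulate_and_preprocess(
    phantom, geom, plan, illum, optics, directivity, seed, with_noise, grid_spacing
):
    """Stream simulate (+noise, +preprocess) pose by pose, storing float32.

    A full 200-pose scan in double precision would hold several GB; cleaned
    planes are stored at single precision, which is far below the noise floor.
    Band/white noise is referenced to the scan's strongest plane, like the
    DAQ's absolute noise floor.
    """
    from .optics import fluence_at_points
    from .preprocess import energy_normalize, lowpass, svd_denoise
    from .simulate import _forward_points, add_noise, phantom_point_sources

    pulse = default_pulse(plan.sampling_rate)
    pts, strength = phantom_point_sources(phantom, grid_spacing / 4)
    planes = []
    for angle in plan.pose_angles:
        g, il = rotate_pose(geom, illum, float(angle))
        psi = fluence_at_points(pts, il, optics)
        p = _forward_points(
            pts, strength, psi, g, plan, float(angle),
            directivity=directivity, pulse=pulse,
        )
        p.samples = p.samples.astype(np.float32)
        planes.append(p)
    if not with_noise:
        return planes
    scan_scale = max(
        float(np.sqrt(np.mean(p.samples.astype(float) ** 2))) for p in planes
    )
    seeds = np.random.SeedSequence(seed).spawn(plan.n_angles)
    noise = NoiseModel(seed=seed)
    cleaned = []
    for p, s in zip(planes, seeds):
        q = add_noise(
            p.copy_with(samples=p.samples.astype(float)), noise,
            rng=np.random.default_rng(s), scale=scan_scale,
        )
        q = lowpass(q)
        q, _ = svd_denoise(q, k=10)
        q.samples = q.samples.astype(np.float32)
        cleaned.append(q)
    ref = float(np.mean([q.pulse_energy for q in cleaned]))
    out = []
    for q in cleaned:
        q = energy_normalize(q, ref)
        q.samples = q.samples.astype(np.float32)
        out.append(q)
    return out


def depth_error_study(
    seed: int,
    n_angles: int = 200,
    n_shells: int = 50,
    with_noise: bool = True,
) -> dict:
    """Four-variant reconstruction of the in-plane wire phantom, depth-resolved.

    Simulates the full acquisition at the scanner's native 200 x 1.8° pose
    sampling (directivity and fan fluence in the forward model, structured
    noise if requested), runs the preprocessing chain per pose, reconstructs
    with and without directivity weighting and fluence compensation, and
    scores each variant against the voxelized phantom with the depth-shell
    relative error.  The evaluation grid is a one-voxel-thick slab through
    the imaging plane: the elevational (cross-plane) point response of the
    lensed elements is several millimetres wide, and a thin binary wire model
    cannot meaningfully score that direction.  Planes are simulated and
    preprocessed one at a time and stored as float32 to bound memory.
    """
    geom = build_array(arc_center_polar_deg=90.0)  # depth axis along +x
    plan = AcquisitionPlan(
        n_angles=n_angles, angular_step=360.0 / n_angles, n_samples=3600
    )
    illum = default_illuminator(geom)
    optics = MILK_MIX_OPTICS
    phantom = in_plane_wire_phantom()
    grid = VoxelGrid(origin=(7.2, 0.0, -2.35), spacing=0.1, shape=(48, 1, 48))
    model = voxelize_phantom(phantom, grid)
    directivity = DirectivityModel()
    planes = _simulate_and_preprocess(
        phantom, geom, plan, illum, optics, directivity, seed, with_noise, grid.spacing
    )
    report = compare_variants(
        planes, geom, illum, plan, optics, grid, model,
        directivity=directivity, n_shells=n_shells,
    )
    edges = np.asarray(report["both"]["depth_shell_edges_cm"])
    mid = (edges[:-1] + edges[1:]) / 2
    model_vox = np.asarray(report["both"]["depth_shell_model_voxels"])
    out = {
        "shell_mid_depth_cm": mid.tolist(),
        "populated": (model_vox > 0).tolist(),
        "image_error": {k: report[k]["image_error"] for k in ("neither", "directivity", "illumination", "both")},
        "depth_errors": {k: report[k]["depth_shell_errors"] for k in ("neither", "directivity", "illumination", "both")},
    }
    deep = (model_vox > 0) & (mid > 1.5)
    nb = np.asarray(report["neither"]["depth_shell_errors"])[deep]
    bo = np.asarray(report["both"]["depth_shell_errors"])[deep]
    out["deep_shells"] = int(deep.sum())
    out["both_below_neither_deep"] = bool(np.all(bo < nb))
    out["mean_improvement_deep_pct"] = float(100 * (1 - np.mean(bo / nb)))
    return out


def deep_rod_study(seed: int, n_angles: int = 200) -> dict:
    """SNR and FWHM of a 0.5 mm rod at 2 cm depth, full pipeline with noise.

    Same acquisition and slab-evaluation design as :func:`depth_error_study`,
    with a single 1 cm rod running tangentially in the imaging plane; the
    profile crosses the rod perpendicular to its axis along the depth
    direction.
    """
    geom = build_array(arc_center_polar_deg=90.0)
    plan = AcquisitionPlan(n_angles=n_angles, angular_step=360.0 / n_angles, n_samples=3600)
    illum = default_illuminator(geom)
    optics = MILK_MIX_OPTICS
    rod = ((10.0, 0.0, -0.5), (10.0, 0.0, 0.5), 0.025, 1.0)  # 2 cm deep
    phantom = PhantomModel(wires=(rod,))
    grid = VoxelGrid(origin=(7.2, 0.0, -2.35), spacing=0.1, shape=(48, 1, 48))
    dm = DirectivityModel()
    planes = _simulate_and_preprocess(
        phantom, geom, plan, illum, optics, dm, seed, True, grid.spacing
    )
    from .reconstruct import reconstruct_scan

    vol = reconstruct_scan(
        planes, geom, illum, plan, optics, grid, directivity=dm, compensate=True
    )
    prof, step_mm = line_profile(
        vol.values, grid, (7.3, 0.0, 0.0), (11.8, 0.0, 0.0), n=180
    )
    m = snr_fwhm(prof, vol.values, step_mm)
    return {"snr_db": m.snr_db, "fwhm_mm": m.fwhm, "n_angles": n_angles}
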