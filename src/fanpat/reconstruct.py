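"""Filtered back-projection with directivity weighting and fluence compensation.

The inversion follows the universal back-projection form for a spherical
detection geometry: each voxel is a weighted average, over detector elements,
of the ramp-filtered record b(t) = p(t) - t dp/dt evaluated at the acoustic
time of flight.  The weight is the solid angle the element subtends from the
voxel, optionally multiplied by the separable Gaussian angular sensitivity of
the lensed elements.  Normalizing by the per-voxel weight sum realizes the
2/Omega_0 prefactor as a weighted mean, which mitigates the partial-view bias
of an arc aperture; the absolute pressure scale is arbitrary throughout.

Because the illuminator is fixed to the rotating transducer, the fluence map
differs per pose; dividing each pose's pressure by its own fluence before
accumulating yields an absorption estimate that cannot be factored into a
single fluence correction applied at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AcquisitionPlan,
    ArrayGeometry,
    IlluminatorGeometry,
    VoxelGrid,
    element_angles,
    rotate_pose,
    solid_angle_weight,
)
from .optics import FluenceVolume, OpticalProperties, fluence_map
from .simulate import RFPlane

__all__ = [
    "DirectivityModel",
    "ReconVolume",
    "directivity_weight",
    "ramp_term",
    "backproject_plane",
    "backproject_plane_reference",
    "compensate_and_accumulate",
    "reconstruct_scan",
]


@dataclass(frozen=True)
class DirectivityModel:
    """Separable Gaussian angular sensitivity S0(theta_L, theta_E), unit on-axis."""

    sigma_L: float = 18.5  # degrees, lateral
    sigma_E: float = 6.2   # degrees, elevational
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma_L <= 0 or self.sigma_E <= 0:
            raise ValueError("directivity sigmas must be positive")


@dataclass
class ReconVolume:
    """Reconstructed voxel volume: initial pressure or absorption estimate."""

    grid: VoxelGrid
    values: np.ndarray
    kind: str = "pressure"          # pressure | absorption
    compensation: str = "none"      # none | fluence
    directivity_used: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values do not match the grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed values must be finite")


def directivity_weight(theta_l, theta_e, model: DirectivityModel):
    """exp(-theta_L^2/(2 sigma_L^2)) * exp(-theta_E^2/(2 sigma_E^2)), degrees in."""
    tl = np.asarray(theta_l, float)
    te = np.asarray(theta_e, float)
    return np.exp(-(tl**2) / (2 * model.sigma_L**2) - (te**2) / (2 * model.sigma_E**2))


def ramp_term(channel_samples: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Ramp-filtered record b(t) = p(t) - t dp/dt along the last axis.

    t is measured from the laser firing instant (sample 0); the derivative is
    by central differences with one-sided stencils at the ends.
    """
    x = np.asarray(channel_samples, float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 time samples")
    dt = 1.0 / sampling_rate
    t = np.arange(x.shape[-1]) * dt
    dp = np.gradient(x, dt, axis=-1)
    return x - t * dp


def backproject_plane(
    plane: RFPlane,
    geom: ArrayGeometry,
    plan: AcquisitionPlan,
    grid: VoxelGrid,
    directivity: DirectivityModel | None = None,
) -> ReconVolume:
    """Back-project one preprocessed RF plane onto the grid (numba-accelerated).

    Voxels beyond the record's reach for a given element receive no
    contribution from it; the per-voxel fraction of skipped elements is
    summarized in ``extras['out_of_window_fraction']``.
    """
    from ._kernels import backproject_kernel

    use_dir = directivity is not None and directivity.enabled
    sig_l = directivity.sigma_L if use_dir else 1.0
    sig_e = directivity.sigma_E if use_dir else 1.0
    b = ramp_term(plane.samples, plane.sampling_rate)
    vox = grid.voxel_centers()
    samples_per_cm = plane.sampling_rate / plan.sound_speed_cm
    vals, wsum, missed = backproject_kernel(
        np.ascontiguousarray(b),
        np.ascontiguousarray(geom.element_positions),
        np.ascontiguousarray(geom.element_normals),
        np.ascontiguousarray(geom.element_lateral),
        np.ascontiguousarray(geom.element_elevational),
        float(geom.element_area),
        np.ascontiguousarray(vox),
        float(samples_per_cm),
        float(sig_l),
        float(sig_e),
        use_dir,
    )
    return ReconVolume(
        grid=grid,
        values=vals.reshape(grid.shape),
        kind="pressure",
        directivity_used=use_dir,
        extras={
            "out_of_window_fraction": float(missed.sum() / (len(vox) * geom.n_elements)),
            "uncovered_voxels": int(np.sum(wsum == 0)),
            "weight_sum": wsum.reshape(grid.shape),
        },
    )


def backproject_plane_reference(
    plane: RFPlane,
    geom: ArrayGeometry,
    plan: AcquisitionPlan,
    grid: VoxelGrid,
    directivity: DirectivityModel | None = None,
) -> ReconVolume:
    """Literal per-voxel / per-element transcription of the back-projection sum.

    Slow, loop-based reference used to validate the optimized kernel on tiny
    instances; kept in the package so external data can be spot-checked too.
    """
    use_dir = directivity is not None and directivity.enabled
    b = ramp_term(plane.samples, plane.sampling_rate)
    n_t = b.shape[1]
    vox = grid.voxel_centers()
    out = np.zeros(len(vox))
    for i, r in enumerate(vox):
        acc = 0.0
        wacc = 0.0
        for e in range(geom.n_elements):
            th_l, th_e, dist = element_angles(
                geom.element_positions[e],
                geom.element_normals[e],
                geom.element_lateral[e],
                r,
            )
            tau = dist / plan.sound_speed_cm * plane.sampling_rate
            if tau > n_t - 1:
                continue
            w = solid_angle_weight(
                geom.element_positions[e], geom.element_normals[e], geom.element_area, r
            )
            if use_dir:
                w *= float(directivity_weight(th_l, th_e, directivity))
            val = float(np.interp(tau, np.arange(n_t), b[e]))
            acc += w * val
            wacc += w
        out[i] = acc / wacc if wacc > 0 else 0.0
    return ReconVolume(grid=grid, values=out.reshape(grid.shape), directivity_used=use_dir)


def compensate_and_accumulate(
    pressure: ReconVolume,
    fluence: FluenceVolume,
    accumulator: ReconVolume | None = None,
    epsilon: float = 0.01,
) -> ReconVolume:
    """Divide a pose's pressure by its fluence and add into the running estimate.

    Voxels whose fluence is below ``epsilon`` times the pose's maximum are
    masked (no contribution) rather than divided by a near-zero; the masked
    count is tallied in ``extras['masked_voxels']``.
    """
    if tuple(pressure.grid.shape) != tuple(fluence.grid.shape):
        raise ValueError("pressure and fluence grids differ")
    if accumulator is None:
        accumulator = ReconVolume(
            grid=pressure.grid,
            values=np.zeros(pressure.grid.shape),
            kind="absorption",
            compensation="fluence",
            directivity_used=pressure.directivity_used,
            extras={"masked_voxels": 0, "n_poses": 0},
        )
    psi = fluence.values
    psi_max = float(psi.max())
    if psi_max == 0.0:
        mask = np.zeros(psi.shape, bool)
    else:
        mask = psi >= epsilon * psi_max
    contrib = np.zeros_like(psi)
    contrib[mask] = pressure.values[mask] / psi[mask]
    accumulator.values += contrib
    accumulator.extras["masked_voxels"] = accumulator.extras.get("masked_voxels", 0) + int(
        (~mask).sum()
    )
    accumulator.extras["n_poses"] = accumulator.extras.get("n_poses", 0) + 1
    return accumulator


def reconstruct_scan(
    planes: list[RFPlane],
    geom: ArrayGeometry,
    illum: IlluminatorGeometry,
    plan: AcquisitionPlan,
    optics: OpticalProperties,
    grid: VoxelGrid,
    directivity: DirectivityModel | None = None,
    compensate: bool = True,
    n_patches: int = 200,
    epsilon: float = 0.01,
    accumulation: str = "weighted",
) -> ReconVolume:
    """Accumulate a full tomographic reconstruction over all poses.

    For each plane: rotate the geometry to its pose, back-project, and (if
    compensating) divide by that pose's fluence map before accumulating.

    The default ``weighted`` accumulation combines poses as a per-voxel
    weighted mean using each pose's summed back-projection weights.  This
    extends the solid-angle normalization over the whole detection surface
    swept out by the rotation: a pose that views a voxel at grazing angles,
    from far away, or outside its directivity cone contributes in proportion
    to its actual sensitivity.  Without this, every pose enters at equal
    strength, and dividing a distant pose's noise-level estimate by its tiny
    fluence floods deep voxels with amplified artifacts.  ``accumulation=
    "sum"`` restores the plain per-pose sum.  Either way accumulation
    commutes, so pose order cannot change the result.  Covers the four
    comparison variants via ``directivity`` and ``compensate``.
    """
    if accumulation not in ("weighted", "sum"):
        raise ValueError("accumulation must be 'weighted' or 'sum'")
    expected = set(np.round(plan.pose_angles, 9))
    got = set(np.round([p.pose_angle for p in planes], 9))
    partial = not expected <= got
    if partial:
        import warnings

        warnings.warn("scan is missing poses; reconstruction is partial", stacklevel=2)
    if not planes:
        raise ValueError("no planes to reconstruct")
    use_dir = directivity is not None and directivity.enabled
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    masked_total = 0
    for plane in planes:
        g, il = rotate_pose(geom, illum, plane.pose_angle)
        bp = backproject_plane(plane, g, plan, grid, directivity)
        w = bp.extras["weight_sum"] if accumulation == "weighted" else np.ones(grid.shape)
        if compensate:
            fl = fluence_map(
                grid, il, optics, n_patches=n_patches, pose_angle=plane.pose_angle
            )
            psi = fl.values
            psi_max = float(psi.max())
            mask = psi >= epsilon * psi_max if psi_max > 0 else np.zeros(psi.shape, bool)
            masked_total += int((~mask).sum())
            num[mask] += (w * bp.values)[mask] / psi[mask]
            den[mask] += w[mask]
        else:
            num += w * bp.values
            den += w
    if accumulation == "weighted":
        values = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    else:
        values = num
    return ReconVolume(
        grid=grid,
        values=values,
        kind="absorption" if compensate else "pressure",
        compensation="fluence" if compensate else "none",
        directivity_used=use_dir,
        extras={
            "n_poses": len(planes),
            "partial": partial,
            "masked_voxels": masked_total,
            "accumulation": accumulation,
        },
    )
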