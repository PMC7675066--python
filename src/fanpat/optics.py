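"""Diffusion-approximation fluence model for the fan illuminator.

The fluence at a point r inside a homogeneous scattering medium, a distance
``r`` from a point source on the illuminated dome band B, is the diffuse
Green's function

    Psi(r) = exp(-mu_eff r) / (4 pi D r),

with diffusion coefficient D = 1/(3 (mu_a0 + mu_s')) and effective attenuation
mu_eff = sqrt(mu_a0 / D).  The fan's total fluence is the integral of this
kernel over B, parameterized by the two divergence angles and evaluated by a
midpoint quadrature over surface patches.  Because the illuminator rotates
rigidly with the transducer, the map must be recomputed for every tomographic
pose.  Only relative fluence matters downstream; an optional global scale is
exposed but defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import IlluminatorGeometry, VoxelGrid

__all__ = [
    "OpticalProperties",
    "FluenceVolume",
    "derive_optics",
    "point_fluence",
    "fluence_at_points",
    "fluence_map",
    "window_profile",
    "collimated_equivalent_fluence",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical coefficients and the derived diffusion quantities (cm units)."""

    mu_a0: float          # absorption, 1/cm
    mu_s: float           # scattering, 1/cm
    g: float = 0.0        # anisotropy
    mu_s_prime: float = 0.0   # reduced scattering, 1/cm (derived)
    D: float = 0.0            # diffusion coefficient, cm (derived)
    mu_eff: float = 0.0       # effective attenuation, 1/cm (derived)
    diffusion_limit_ok: bool = True

    def __post_init__(self) -> None:
        if self.mu_a0 < 0 or self.mu_s < 0:
            raise ValueError("optical coefficients must be non-negative")
        if not (0.0 <= self.g < 1.0):
            raise ValueError("anisotropy g must be in [0, 1)")
        msp = self.mu_s * (1.0 - self.g)
        D = 1.0 / (3.0 * (self.mu_a0 + msp))
        mu_eff = np.sqrt(self.mu_a0 / D)
        object.__setattr__(self, "mu_s_prime", msp)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "mu_eff", mu_eff)
        # advisory: Eq. holds in the diffusion limit mu_a0 << mu_s'
        ok = msp > 0 and self.mu_a0 / msp <= 0.1 or self.mu_a0 == 0
        object.__setattr__(self, "diffusion_limit_ok", bool(ok))


def derive_optics(mu_a0: float, mu_s: float, g: float = 0.0) -> OpticalProperties:
    """Build :class:`OpticalProperties` with D, mu_s', mu_eff derived."""
    return OpticalProperties(mu_a0=mu_a0, mu_s=mu_s, g=g)


# Paper-reported bulk coefficients at 700 nm (cm^-1).
BREAST_OPTICS = derive_optics(mu_a0=0.2, mu_s=10.0)
MILK_MIX_OPTICS = derive_optics(mu_a0=0.0075, mu_s=15.0)  # 50/50 milk/water


@dataclass(frozen=True)
class FluenceVolume:
    """Relative fluence sampled on a voxel grid for one acquisition pose."""

    grid: VoxelGrid
    pose_angle: float
    values: np.ndarray  # grid.shape, >= 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != tuple(self.grid.shape):
            raise ValueError("fluence values do not match the grid shape")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("fluence must be finite and non-negative")
        object.__setattr__(self, "values", v)


def point_fluence(distance, optics: OpticalProperties):
    """Diffuse point-source fluence exp(-mu_eff r)/(4 pi D r), distance in cm."""
    r = np.asarray(distance, float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    return np.exp(-optics.mu_eff * r) / (4.0 * np.pi * optics.D * r)


def patch_layout(illum: IlluminatorGeometry, n_patches: int):
    """Midpoint patch centers on the band B and their quadrature weights.

    The fan integral is over the two divergence angles, so each patch carries
    the angular measure dtheta x dphi it covers (the diffuser spreads energy
    uniformly per angle, not per unit dome area).  The (n_theta, n_phi)
    factorization of ``n_patches`` is chosen among exact divisors to best
    match the fan's divergence aspect ratio, so a thin fan gets a single row
    of patches along the window.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    wide = np.deg2rad(illum.wide_divergence)
    narrow = np.deg2rad(illum.narrow_divergence)
    target = np.sqrt(n_patches * narrow / wide)
    divisors = [d for d in range(1, n_patches + 1) if n_patches % d == 0]
    n_phi = min(divisors, key=lambda d: abs(d - target))
    n_theta = n_patches // n_phi

    th = -wide / 2 + (np.arange(n_theta) + 0.5) * wide / n_theta
    ph = -narrow / 2 + (np.arange(n_phi) + 0.5) * narrow / n_phi
    T, P = np.meshgrid(th, ph, indexing="ij")
    centers = illum.surface_points(T, P).reshape(-1, 3)
    weights = np.full(len(centers), (wide / n_theta) * (narrow / n_phi))
    return centers, weights


def fluence_at_points(
    points: np.ndarray,
    illum: IlluminatorGeometry,
    optics: OpticalProperties,
    n_patches: int = 200,
    dist_floor: float = 0.025,
    scale: float = 1.0,
    chunk: int = 65536,
) -> np.ndarray:
    """Fan-surface fluence integral evaluated at arbitrary points (cm).

    Distances below ``dist_floor`` (default half of the 0.5 mm voxel pitch)
    are clamped to avoid the 1/r singularity at the surface.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    centers, weights = patch_layout(illum, n_patches)
    out = np.empty(len(pts))
    for lo in range(0, len(pts), chunk):
        block = pts[lo : lo + chunk]
        d = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=-1)
        np.maximum(d, dist_floor, out=d)
        out[lo : lo + chunk] = (
            np.exp(-optics.mu_eff * d) / (4.0 * np.pi * optics.D * d)
        ) @ weights
    return scale * out


def fluence_map(
    grid: VoxelGrid,
    illum: IlluminatorGeometry,
    optics: OpticalProperties,
    n_patches: int = 200,
    pose_angle: float = 0.0,
    scale: float = 1.0,
) -> FluenceVolume:
    """Per-voxel fluence for one pose (illuminator already rotated to the pose)."""
    vals = fluence_at_points(
        grid.voxel_centers(),
        illum,
        optics,
        n_patches=n_patches,
        dist_floor=grid.spacing / 2,
        scale=scale,
    )
    return FluenceVolume(grid=grid, pose_angle=pose_angle, values=vals.reshape(grid.shape))


def window_profile(
    illum: IlluminatorGeometry,
    optics: OpticalProperties,
    arc_positions: np.ndarray,
    standoff: float = 0.1,
    n_patches: int = 200,
) -> np.ndarray:
    """Modeled fluence just inside the sample along the optical window arc.

    ``arc_positions`` are arc-length coordinates (cm) along the window,
    measured from the window center; ``standoff`` is the depth below the dome
    surface at which the profile is evaluated.
    """
    s = np.asarray(arc_positions, float)
    half = illum.window_arc_length / 2
    if np.any(np.abs(s) > half + 1e-9):
        raise ValueError("arc positions fall outside the window span")
    R = illum.dome_radius
    center = illum.surface_points(np.array(0.0), np.array(0.0))
    center_hat = center / np.linalg.norm(center)
    # rotate the window-center direction within the fan plane (axis = narrow_axis)
    k = illum.narrow_axis
    ang = s / R
    pts = []
    for a in ang:
        c, sn = np.cos(a), np.sin(a)
        v = c * center_hat + sn * np.cross(k, center_hat) + (1 - c) * (k @ center_hat) * k
        pts.append((R - standoff) * v)
    return fluence_at_points(np.array(pts), illum, optics, n_patches=n_patches)


def collimated_equivalent_fluence(
    pulse_energy_mj: float = 35.0, surface_area_cm2: float = 250.0
) -> float:
    """Average surface fluence (mJ/cm^2) if the pulse were collimated over the dome.

    Spreading the per-pulse energy measured at the optical window uniformly
    over the dome surface gives the collimated-equivalent average fluence used
    to compare the fan geometry against full-surface illumination.
    """
    if pulse_energy_mj < 0 or surface_area_cm2 <= 0:
        raise ValueError("energy must be >= 0 and area > 0")
    return pulse_energy_mj / surface_area_cm2
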