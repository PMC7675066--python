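"""Image-quality metrics: SNR/FWHM from profiles, RMSE, SSIM, relative image
error, and depth-resolved error shells.

SNR follows the amplitude convention: the mean amplitude over the peak region
(the contiguous run above half the profile maximum containing the argmax)
divided by the standard deviation of the amplitude over the whole evaluated
image, reported as 20 log10 of the ratio.  The peak region's width is the
FWHM.  The relative image error is ||A - M||_2 / ||M||_2 against the known
phantom model; resolving it in equal-width spherical shells of distance from
the transducer surface exposes how reconstruction variants degrade with
imaging depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.metrics import structural_similarity

from .geometry import VoxelGrid
from .reconstruct import DirectivityModel, ReconVolume, reconstruct_scan

__all__ = [
    "ProfileMetrics",
    "DepthErrorCurve",
    "line_profile",
    "snr_fwhm",
    "rmse",
    "ssim",
    "normalize_volume",
    "image_error",
    "depth_error",
    "compare_variants",
]


@dataclass(frozen=True)
class ProfileMetrics:
    snr_db: float
    fwhm: float              # same length unit as the supplied spacing
    peak_region: tuple[int, int]  # [start, stop) indices

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("SNR must be finite")
        if self.fwhm <= 0:
            raise ValueError("FWHM must be positive")


@dataclass(frozen=True)
class DepthErrorCurve:
    """Per-shell relative errors plus the raw norm pieces they recombine from."""

    shell_edges: np.ndarray     # (n_shells + 1,) cm, depth from detector surface
    errors: np.ndarray          # (n_shells,), NaN where a shell is empty
    sq_num: np.ndarray          # per-shell sum of (A-M)^2
    sq_den: np.ndarray          # per-shell sum of M^2
    model_voxels: np.ndarray    # per-shell count of non-zero model voxels

    def global_error(self) -> float:
        return float(np.sqrt(self.sq_num.sum() / self.sq_den.sum()))


def line_profile(
    volume: np.ndarray, grid: VoxelGrid, p0, p1, n: int = 200
) -> tuple[np.ndarray, float]:
    """Sample |volume| along the segment p0->p1 (world cm); returns (profile, step).

    The step is returned in mm so FWHMs read off the profile are in mm.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    t = np.linspace(0.0, 1.0, n)
    pts = p0 + t[:, None] * (p1 - p0)
    idx = grid.world_to_index(pts).T
    prof = map_coordinates(np.abs(volume), idx, order=1, mode="constant", cval=0.0)
    step_mm = np.linalg.norm(p1 - p0) / (n - 1) * 10.0
    return prof, step_mm


def snr_fwhm(profile: np.ndarray, image_values: np.ndarray, spacing: float) -> ProfileMetrics:
    """Peak-region SNR (dB) and FWHM from an amplitude profile.

    ``spacing`` is the sample spacing of the profile; FWHM is the peak-region
    sample count times spacing.  Raises on flat or all-zero profiles.
    """
    prof = np.abs(np.asarray(profile, float))
    if prof.size < 1 or prof.max() <= 0 or np.allclose(prof, prof[0]):
        raise ValueError("profile has no peak")
    imax = int(np.argmax(prof))
    half = 0.5 * prof[imax]
    lo = imax
    while lo > 0 and prof[lo - 1] > half:
        lo -= 1
    hi = imax + 1
    while hi < prof.size and prof[hi] > half:
        hi += 1
    sigma = float(np.std(np.abs(np.asarray(image_values, float))))
    if sigma == 0.0:
        raise ValueError("image amplitude has zero spread; SNR undefined")
    snr = float(np.mean(prof[lo:hi]) / sigma)
    return ProfileMetrics(
        snr_db=20.0 * np.log10(snr), fwhm=(hi - lo) * spacing, peak_region=(lo, hi)
    )


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-squared voxelwise difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Mean windowed structural similarity (standard constants)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = float(hi - lo) or 1.0
    return float(structural_similarity(a, b, data_range=data_range))


def normalize_volume(v: np.ndarray, policy: str = "unit-max") -> np.ndarray:
    """Scale-normalize an arbitrary-unit volume before error metrics.

    unit-max divides by max |v| (the default: reconstructions are compared to
    a binary model); unit-norm divides by the two-norm; none leaves v as is.
    """
    v = np.asarray(v, float)
    if policy == "none":
        return v
    if policy == "unit-max":
        m = np.abs(v).max()
    elif policy == "unit-norm":
        m = np.linalg.norm(v.ravel())
    else:
        raise ValueError(f"unknown normalization policy: {policy}")
    return v / m if m > 0 else v


def image_error(a: np.ndarray, m: np.ndarray, normalize: str = "none") -> float:
    """Relative image error ||A - M||_2 / ||M||_2 (optionally pre-normalized)."""
    a = np.asarray(a, float)
    m = np.asarray(m, float)
    if a.shape != m.shape:
        raise ValueError("shape mismatch")
    if not np.any(m):
        raise ValueError("model volume is all zero")
    a = normalize_volume(a, normalize)
    m = normalize_volume(m, normalize)
    return float(np.linalg.norm((a - m).ravel()) / np.linalg.norm(m.ravel()))


def depth_error(
    a: np.ndarray,
    m: np.ndarray,
    grid: VoxelGrid,
    center=(0.0, 0.0, 0.0),
    n_shells: int = 50,
    detector_radius: float = 12.0,
    normalize: str = "unit-max",
) -> DepthErrorCurve:
    """Relative error resolved in equal-width spherical depth shells.

    Depth is distance inward from the spherical detector surface:
    depth = detector_radius - |r - center|.  Shells partition the grid's
    depth range into ``n_shells`` equal-width bins; empty shells are NaN.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    a = normalize_volume(np.asarray(a, float), normalize).ravel()
    m = normalize_volume(np.asarray(m, float), normalize).ravel()
    depth = detector_radius - np.linalg.norm(
        grid.voxel_centers() - np.asarray(center, float), axis=1
    )
    edges = np.linspace(depth.min(), depth.max(), n_shells + 1)
    which = np.clip(np.searchsorted(edges, depth, side="right") - 1, 0, n_shells - 1)
    sq_num = np.zeros(n_shells)
    sq_den = np.zeros(n_shells)
    counts = np.zeros(n_shells, int)
    model_vox = np.zeros(n_shells, int)
    np.add.at(sq_num, which, (a - m) ** 2)
    np.add.at(sq_den, which, m**2)
    np.add.at(counts, which, 1)
    np.add.at(model_vox, which, (m != 0).astype(int))
    errors = np.full(n_shells, np.nan)
    ok = (counts > 0) & (sq_den > 0)
    errors[ok] = np.sqrt(sq_num[ok] / sq_den[ok])
    return DepthErrorCurve(
        shell_edges=edges, errors=errors, sq_num=sq_num, sq_den=sq_den, model_voxels=model_vox
    )


VARIANTS = {
    "neither": (False, False),
    "directivity": (True, False),
    "illumination": (False, True),
    "both": (True, True),
}


def compare_variants(
    planes,
    geom,
    illum,
    plan,
    optics,
    grid: VoxelGrid,
    model_volume: np.ndarray,
    directivity: DirectivityModel | None = None,
    profile_endpoints=None,
    n_patches: int = 200,
    epsilon: float = 0.01,
    n_shells: int = 50,
    detector_radius: float = 12.0,
) -> dict:
    """Reconstruct the four (+/- directivity, +/- compensation) variants and score them.

    Returns a dict keyed by variant name with image error, depth-shell curve,
    and (when profile endpoints are given) SNR and FWHM along the profile.
    """
    if directivity is None:
        directivity = DirectivityModel()
    report = {}
    for name, (use_dir, use_comp) in VARIANTS.items():
        vol = reconstruct_scan(
            planes,
            geom,
            illum,
            plan,
            optics,
            grid,
            directivity=directivity if use_dir else None,
            compensate=use_comp,
            n_patches=n_patches,
            epsilon=epsilon,
        )
        entry: dict = {
            "directivity": use_dir,
            "illumination_compensation": use_comp,
            "image_error": image_error(vol.values, model_volume, normalize="unit-max"),
        }
        curve = depth_error(
            vol.values, model_volume, grid, n_shells=n_shells,
            detector_radius=detector_radius,
        )
        entry["depth_shell_edges_cm"] = curve.shell_edges.tolist()
        entry["depth_shell_errors"] = curve.errors.tolist()
        entry["depth_shell_model_voxels"] = curve.model_voxels.tolist()
        if profile_endpoints is not None:
            prof, step_mm = line_profile(vol.values, grid, *profile_endpoints)
            pm = snr_fwhm(prof, vol.values, step_mm)
            entry["snr_db"] = pm.snr_db
            entry["fwhm_mm"] = pm.fwhm
        report[name] = entry
        report.setdefault("_volumes", {})[name] = vol
    return report
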