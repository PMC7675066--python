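"""Synthetic phantoms and forward RF modeling.

The forward model implements the photoacoustic proportionality: each absorbing
point emits a pressure transient whose amplitude is proportional to local
fluence x absorption, scaled by the element's angular sensitivity and 1/r
spherical spreading, and arriving after the acoustic time of flight.  The
temporal pulse defaults to a band-limited bipolar wavelet (derivative of a
Gaussian) because a true delta pulse aliases at 40 MHz sampling.  Structured
noise mimics the cross-channel bands seen on the DAQ: low-rank outer products
of a channel profile and a temporal burst, plus white noise and per-pulse
energy jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.signal import fftconvolve

from .geometry import (
    AcquisitionPlan,
    ArrayGeometry,
    IlluminatorGeometry,
    VoxelGrid,
    rotate_pose,
)
from .optics import FluenceVolume, OpticalProperties, fluence_at_points

__all__ = [
    "PhantomModel",
    "RFPlane",
    "NoiseModel",
    "gaussian_pulse",
    "default_pulse",
    "voxelize_phantom",
    "phantom_point_sources",
    "forward_rf",
    "add_noise",
    "simulate_scan",
]


@dataclass(frozen=True)
class PhantomModel:
    """Wire-segment phantom: list of (start, end, radius, absorption), cm units."""

    wires: tuple = ()
    background_absorption: float = 0.0

    def __post_init__(self) -> None:
        wires = []
        for w in self.wires:
            start, end, radius, mu_a = w
            if radius <= 0:
                raise ValueError("wire radius must be positive")
            wires.append(
                (np.asarray(start, float), np.asarray(end, float), float(radius), float(mu_a))
            )
        object.__setattr__(self, "wires", tuple(wires))


@dataclass
class RFPlane:
    """One tomographic pose's channels x time pressure record."""

    pose_angle: float
    samples: np.ndarray       # (n_channels, n_samples)
    pulse_energy: float = 1.0  # mJ
    sampling_rate: float = 40e6

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    def copy_with(self, samples=None, pulse_energy=None) -> "RFPlane":
        return RFPlane(
            pose_angle=self.pose_angle,
            samples=self.samples if samples is None else samples,
            pulse_energy=self.pulse_energy if pulse_energy is None else pulse_energy,
            sampling_rate=self.sampling_rate,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Structured RF noise: low-rank cross-channel bands + white noise + jitter.

    Amplitudes are relative to the RMS of the clean plane (or 1 for an all-zero
    plane).  ``energy_jitter`` is the fractional half-width of the per-pulse
    energy variation; the recorded signal scales with the drawn energy, the
    metadata records it, so downstream energy normalization can undo it.
    The parameters are calibration knobs — the hardware's noise spectrum is
    not quantified — but their defaults make the bands dominate the leading
    singular values, as observed on the real DAQ.
    """

    band_count: int = 8
    band_rank: int = 1
    band_amplitude: float = 3.0
    white_sigma: float = 0.05
    energy_jitter: float = 0.125
    seed: int = 0


def gaussian_pulse(sampling_rate: float, sigma_s: float = 5e-8) -> tuple[np.ndarray, int]:
    """Unipolar Gaussian kernel (unit peak) and the index of its peak."""
    n = max(1, int(round(4 * sigma_s * sampling_rate)))
    t = np.arange(-n, n + 1) / sampling_rate
    k = np.exp(-0.5 * (t / sigma_s) ** 2)
    return k, n


def default_pulse(sampling_rate: float, center_frequency: float = 5e6) -> tuple[np.ndarray, int]:
    """Bipolar derivative-of-Gaussian wavelet with unit peak.

    The spectrum peaks at ``center_frequency`` (sigma = 1/(2 pi f0)), placing
    the pulse inside the DAQ's 2-20 MHz band at 40 MHz sampling.  Returns the
    kernel and the index of its center (the zero crossing at the arrival time).
    """
    sigma = 1.0 / (2 * np.pi * center_frequency)
    n = max(2, int(round(4 * sigma * sampling_rate)))
    t = np.arange(-n, n + 1) / sampling_rate
    k = -t * np.exp(-0.5 * (t / sigma) ** 2)
    k /= np.abs(k).max()
    return k, n


def voxelize_phantom(phantom: PhantomModel, grid: VoxelGrid) -> np.ndarray:
    """Rasterize wires onto the grid: absorption inside a wire radius, else background.

    The result doubles as the model volume M for image-error evaluation.
    """
    vol = np.full(grid.shape, phantom.background_absorption, float)
    pts = grid.voxel_centers()
    lo = np.asarray(grid.origin) - grid.spacing
    hi = np.asarray(grid.origin) + grid.spacing * np.asarray(grid.shape)
    for start, end, radius, mu_a in phantom.wires:
        if np.any(np.minimum(start, end) > hi) or np.any(np.maximum(start, end) < lo):
            warnings.warn("wire lies outside the grid; clipped", stacklevel=2)
        seg = end - start
        L2 = float(seg @ seg)
        if L2 == 0.0:
            d = np.linalg.norm(pts - start, axis=1)
        else:
            t = np.clip((pts - start) @ seg / L2, 0.0, 1.0)
            d = np.linalg.norm(pts - (start + t[:, None] * seg), axis=1)
        inside = (d <= radius).reshape(grid.shape)
        vol[inside] = mu_a
    return vol


def phantom_point_sources(
    phantom: PhantomModel, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize wires into point-source chains (positions, strengths).

    Points are spaced ``spacing`` cm apart along each wire axis (quarter-voxel
    spacing by convention); each carries absorption x cross-section x spacing
    so that total source strength matches the wire volume integral.
    """
    points, strengths = [], []
    for start, end, radius, mu_a in phantom.wires:
        length = float(np.linalg.norm(end - start))
        n = max(2, int(np.ceil(length / spacing)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = start + t[:, None] * (end - start)
        w = mu_a * np.pi * radius**2 * (length / (n - 1))
        points.append(pts)
        strengths.append(np.full(n, w))
    if not points:
        return np.zeros((0, 3)), np.zeros(0)
    return np.concatenate(points), np.concatenate(strengths)


def _forward_points(
    points: np.ndarray,
    source_strength: np.ndarray,
    fluence_at_sources: np.ndarray,
    geom: ArrayGeometry,
    plan: AcquisitionPlan,
    pose_angle: float,
    directivity=None,
    pulse: tuple[np.ndarray, int] | None = None,
    require_coverage: bool = False,
) -> RFPlane:
    """Superpose point-source transients onto a channels x time record."""
    if pulse is None:
        pulse = default_pulse(plan.sampling_rate)
    kernel, k_center = pulse
    n_el, n_t = geom.n_elements, plan.n_samples
    rec = np.zeros((n_el, n_t))
    amp0 = source_strength * fluence_at_sources
    live = amp0 != 0.0
    if np.any(live):
        pts = points[live]
        amp0 = amp0[live]
        d = np.linalg.norm(
            pts[None, :, :] - geom.element_positions[:, None, :], axis=-1
        )  # (E, S)
        tau = d / plan.sound_speed_cm * plan.sampling_rate
        if require_coverage and tau.max() > n_t - 1:
            raise ValueError("time window too short for the farthest source point")
        amp = amp0[None, :] / d
        if directivity is not None and getattr(directivity, "enabled", True):
            v = pts[None, :, :] - geom.element_positions[:, None, :]
            a = np.einsum("esk,ek->es", v, geom.element_normals)
            b = np.einsum("esk,ek->es", v, geom.element_lateral)
            c = np.einsum("esk,ek->es", v, geom.element_elevational)
            th_l = np.degrees(np.arctan2(b, a))
            th_e = np.degrees(np.arctan2(c, a))
            amp = amp * np.exp(
                -(th_l**2) / (2 * directivity.sigma_L**2)
                - (th_e**2) / (2 * directivity.sigma_E**2)
            )
        i0 = np.floor(tau).astype(np.int64)
        frac = tau - i0
        ok0 = (i0 >= 0) & (i0 <= n_t - 1)
        ok1 = (i0 + 1 >= 0) & (i0 + 1 <= n_t - 1)
        eidx = np.broadcast_to(np.arange(n_el)[:, None], tau.shape)
        np.add.at(rec, (eidx[ok0], i0[ok0]), (amp * (1 - frac))[ok0])
        np.add.at(rec, (eidx[ok1], (i0 + 1)[ok1]), (amp * frac)[ok1])
        full = fftconvolve(rec, kernel[None, :], mode="full", axes=1)
        rec = full[:, k_center : k_center + n_t]
    return RFPlane(
        pose_angle=pose_angle,
        samples=rec,
        pulse_energy=1.0,
        sampling_rate=plan.sampling_rate,
    )


def forward_rf(
    phantom_volume: np.ndarray,
    geom: ArrayGeometry,
    plan: AcquisitionPlan,
    fluence: FluenceVolume,
    directivity=None,
    pulse: tuple[np.ndarray, int] | None = None,
    require_coverage: bool = False,
) -> RFPlane:
    """Forward-model one pose's RF record from a voxelized absorption volume.

    Every non-zero voxel acts as a point source with amplitude proportional to
    fluence x absorption x directivity / distance, delayed by the time of
    flight (sub-sample delays linearly interpolated).  Arrivals beyond the
    record are dropped unless ``require_coverage`` requests a hard error.
    """
    grid = fluence.grid
    vol = np.asarray(phantom_volume, float)
    if vol.shape != tuple(grid.shape):
        raise ValueError("phantom volume and fluence grid shapes differ")
    mask = vol.ravel() != 0.0
    pts = grid.voxel_centers()[mask]
    strength = vol.ravel()[mask] * grid.spacing**3
    psi = fluence.values.ravel()[mask]
    return _forward_points(
        pts,
        strength,
        psi,
        geom,
        plan,
        pose_angle=fluence.pose_angle,
        directivity=directivity,
        pulse=pulse,
        require_coverage=require_coverage,
    )


def _band(rng: np.random.Generator, n_el: int, n_t: int, rank: int) -> np.ndarray:
    """One low-rank cross-channel band (channel profile x temporal burst)."""
    out = np.zeros((n_el, n_t))
    for _ in range(rank):
        c0 = rng.uniform(0, n_el)
        width = rng.uniform(n_el / 16, n_el / 4)
        profile = np.exp(-0.5 * ((np.arange(n_el) - c0) / width) ** 2)
        t0 = rng.uniform(0, n_t)
        tw = rng.uniform(n_t / 40, n_t / 10)
        f = rng.uniform(0.02, 0.12)  # cycles/sample, low-frequency burst
        t = np.arange(n_t)
        burst = np.exp(-0.5 * ((t - t0) / tw) ** 2) * np.cos(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
        out += np.outer(profile, burst)
    return out


def add_noise(
    plane: RFPlane,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
    scale: float | None = None,
) -> RFPlane:
    """Add band + white noise and apply per-pulse energy jitter (seeded).

    ``scale`` is the amplitude reference the relative noise levels multiply.
    It defaults to this plane's RMS, but a whole scan should pass one shared
    scale (see :func:`simulate_scan`): the DAQ's noise floor is a property of
    the electronics, not of how much light a given pose happens to collect.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    x = plane.samples
    if scale is None:
        scale = float(np.sqrt(np.mean(x**2)))
    if scale == 0.0:
        scale = 1.0
    energy_factor = 1.0
    if noise.energy_jitter > 0:
        energy_factor = 1.0 + rng.uniform(-noise.energy_jitter, noise.energy_jitter)
    out = x * energy_factor
    if noise.band_amplitude > 0:
        for _ in range(noise.band_count):
            b = _band(rng, x.shape[0], x.shape[1], noise.band_rank)
            b *= noise.band_amplitude * scale / max(np.abs(b).max(), 1e-300)
            out = out + b
    if noise.white_sigma > 0:
        out = out + rng.normal(0.0, noise.white_sigma * scale, size=x.shape)
    return plane.copy_with(samples=out, pulse_energy=plane.pulse_energy * energy_factor)


def simulate_scan(
    phantom: PhantomModel,
    geom: ArrayGeometry,
    illum: IlluminatorGeometry,
    plan: AcquisitionPlan,
    optics: OpticalProperties,
    directivity=None,
    noise: NoiseModel | None = None,
    n_patches: int = 200,
    pulse: tuple[np.ndarray, int] | None = None,
    source_spacing: float | None = None,
    grid_spacing: float = 0.05,
) -> list[RFPlane]:
    """Simulate the full rotating-dome acquisition: one RF plane per pose.

    Wires are discretized as point-source chains at quarter-voxel spacing and
    the fluence is re-evaluated at the source points for every pose with the
    rigidly rotated illuminator.  Noise amplitudes are referenced to the
    strongest plane's RMS, so poses the fan misses still carry the same
    absolute noise floor.  All randomness derives from ``noise.seed``.
    """
    if source_spacing is None:
        source_spacing = grid_spacing / 4
    pts, strength = phantom_point_sources(phantom, source_spacing)
    planes: list[RFPlane] = []
    for angle in plan.pose_angles:
        g, il = rotate_pose(geom, illum, float(angle))
        if len(pts):
            psi = fluence_at_points(pts, il, optics, n_patches=n_patches)
        else:
            psi = np.zeros(0)
        planes.append(
            _forward_points(
                pts, strength, psi, g, plan, pose_angle=float(angle),
                directivity=directivity, pulse=pulse,
            )
        )
    if noise is not None:
        seeds = np.random.SeedSequence(noise.seed).spawn(plan.n_angles)
        scan_scale = max(float(np.sqrt(np.mean(p.samples**2))) for p in planes)
        planes = [
            add_noise(p, noise, rng=np.random.default_rng(s), scale=scan_scale or None)
            for p, s in zip(planes, seeds)
        ]
    return planes
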