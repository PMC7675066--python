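"""RF conditioning before reconstruction.

The pipeline order is fixed: Butterworth low-pass (the low-frequency content
must survive for the SVD step), then truncated-SVD band-noise subtraction,
then per-pulse energy normalization.  The cross-channel noise bands are
low-rank in the channels x time matrix and dominate the leading singular
values, so subtracting the rank-k reconstruction removes them; k defaults to
10, the value found to balance noise removal against signal loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .simulate import RFPlane

__all__ = ["DenoiseReport", "lowpass", "svd_denoise", "energy_normalize", "preprocess_planes"]


@dataclass
class DenoiseReport:
    """Bookkeeping for SVD denoising: rank removed and energy fraction taken out."""

    discarded_rank: int
    noise_fraction: float
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_fraction <= 1.0 + 1e-12):
            raise ValueError("noise_fraction must lie in [0, 1]")


def lowpass(
    plane: RFPlane, order: int = 5, cutoff: float = 14.5e6, zero_phase: bool = True
) -> RFPlane:
    """Butterworth low-pass along time, per channel.

    Zero-phase (forward-backward) application by default so that arrival
    times, which back-projection depends on, are not shifted; a single-pass
    causal mode is available.
    """
    fs = plane.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff <= 0 or order < 1:
        raise ValueError("cutoff and order must be positive")
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        y = sosfiltfilt(sos, plane.samples, axis=1)
    else:
        y = sosfilt(sos, plane.samples, axis=1)
    return plane.copy_with(samples=y)


def svd_denoise(plane: RFPlane, k: int = 10) -> tuple[RFPlane, DenoiseReport]:
    """Subtract the rank-k truncated SVD reconstruction (the band noise)."""
    m = plane.samples
    max_k = min(m.shape)
    if not (0 <= k <= max_k):
        raise ValueError(f"k must be in [0, {max_k}]")
    if k == 0:
        return plane.copy_with(samples=m.copy()), DenoiseReport(0, 0.0)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    noise = (u[:, :k] * s[:k]) @ vt[:k]
    total = float(np.sum(s**2))
    frac = float(np.sum(s[:k] ** 2) / total) if total > 0 else 0.0
    return plane.copy_with(samples=m - noise), DenoiseReport(k, min(frac, 1.0))


def energy_normalize(plane: RFPlane, reference_energy: float) -> RFPlane:
    """Scale samples by reference_energy / pulse_energy (relative-energy removal)."""
    if plane.pulse_energy <= 0 or reference_energy <= 0:
        raise ValueError("pulse energies must be positive")
    f = reference_energy / plane.pulse_energy
    return plane.copy_with(samples=plane.samples * f, pulse_energy=reference_energy)


def preprocess_planes(
    planes: list[RFPlane],
    order: int = 5,
    cutoff: float = 14.5e6,
    k: int = 10,
    reference_energy: float | None = None,
    zero_phase: bool = True,
) -> tuple[list[RFPlane], DenoiseReport]:
    """Run lowpass -> svd_denoise -> energy_normalize over a whole scan.

    The reference energy defaults to the scan-mean pulse energy.  Each plane
    is processed independently (statelessly), so plane order cannot affect
    results.  Returns the cleaned planes and an aggregate report whose flags
    list holds each plane's removed-energy fraction.
    """
    if reference_energy is None:
        reference_energy = float(np.mean([p.pulse_energy for p in planes]))
    out, fracs = [], []
    for p in planes:
        q = lowpass(p, order=order, cutoff=cutoff, zero_phase=zero_phase)
        q, rep = svd_denoise(q, k=k)
        q = energy_normalize(q, reference_energy)
        out.append(q)
        fracs.append(rep.noise_fraction)
    mean_frac = float(np.mean(fracs)) if fracs else 0.0
    return out, DenoiseReport(k, mean_frac, flags=fracs)
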