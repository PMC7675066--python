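"""Numba-compiled hot loop for weighted back-projection.

One thread block per voxel: loop over elements, evaluate the ramp-filtered
record at the time of flight (linear interpolation), weight by solid angle
and optionally by the separable Gaussian directivity, and normalize by the
per-voxel weight sum.  Each voxel is written exactly once, so the result is
independent of the parallel schedule.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, prange


@njit(parallel=True, cache=True)
def backproject_kernel(
    b,            # (n_el, n_t) ramp-filtered records
    pos,          # (n_el, 3) element positions, cm
    nrm,          # (n_el, 3) element normals
    lat,          # (n_el, 3) element lateral axes
    elev,         # (n_el, 3) element elevational axes
    area,         # element area, cm^2
    vox,          # (M, 3) voxel centers, cm
    samples_per_cm,  # sampling_rate / sound_speed_cm
    sigma_l,      # degrees
    sigma_e,      # degrees
    use_directivity,  # bool
):
    n_el = pos.shape[0]
    n_t = b.shape[1]
    m = vox.shape[0]
    vals = np.zeros(m)
    wsum = np.zeros(m)
    missed = np.zeros(m)
    rad2deg = 180.0 / math.pi
    inv2sl = 1.0 / (2.0 * sigma_l * sigma_l)
    inv2se = 1.0 / (2.0 * sigma_e * sigma_e)
    for i in prange(m):
        vx = vox[i, 0]
        vy = vox[i, 1]
        vz = vox[i, 2]
        acc = 0.0
        wacc = 0.0
        miss = 0.0
        for e in range(n_el):
            dx = vx - pos[e, 0]
            dy = vy - pos[e, 1]
            dz = vz - pos[e, 2]
            dist = math.sqrt(dx * dx + dy * dy + dz * dz)
            if dist == 0.0:
                continue
            tau = dist * samples_per_cm
            if tau > n_t - 1:
                miss += 1.0
                continue
            a = dx * nrm[e, 0] + dy * nrm[e, 1] + dz * nrm[e, 2]
            cos_t = a / dist
            if cos_t <= 0.0:
                continue
            w = area * cos_t / (dist * dist)
            if use_directivity:
                bb = dx * lat[e, 0] + dy * lat[e, 1] + dz * lat[e, 2]
                cc = dx * elev[e, 0] + dy * elev[e, 1] + dz * elev[e, 2]
                th_l = math.atan2(bb, a) * rad2deg
                th_e = math.atan2(cc, a) * rad2deg
                w *= math.exp(-th_l * th_l * inv2sl - th_e * th_e * inv2se)
            i0 = int(math.floor(tau))
            frac = tau - i0
            if i0 >= n_t - 1:
                val = b[e, n_t - 1]
            else:
                val = b[e, i0] * (1.0 - frac) + b[e, i0 + 1] * frac
            acc += w * val
            wacc += w
        if wacc > 0.0:
            vals[i] = acc / wacc
        wsum[i] = wacc
        missed[i] = miss
    return vals, wsum, missed
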