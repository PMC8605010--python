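"""Numba production kernel for the transport loop.

Same physics and the same random-draw order as
:mod:`nervelight.transport` (standard scattering convention), compiled
for production ray budgets.  Seeding ``np.random.seed`` inside the
jitted function reproduces numpy's legacy MT19937 stream, so a run with
a given seed is bit-for-bit reproducible and agrees with the pure-Python
engine driven by ``np.random.RandomState`` with the same seed (voxel
values match to float round-off; the kernel attenuates samples by a
multiplicative per-step decay instead of one exp per sample).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["propagate_rays"]


@njit(cache=True)
def propagate_rays(
    starts,          # (m, 3) float64 launch points
    dirs,            # (m, 3) float64 unit launch directions
    rays_per_entry,  # int
    radius,          # cylinder radius, mm
    length,          # cylinder length, mm
    path_rate,       # free-path rate, mm^-1 (mean free path = 1/path_rate)
    g,               # anisotropy
    mu_eff,          # effective attenuation, mm^-1
    cos_crit,        # cos(critical angle); < -1 disables reflection
    step,            # deposition step, mm
    origin,          # (3,) grid origin
    vox,             # voxel size, mm
    grid,            # (nx, ny, nz) float64, modified in place
    seed,            # RNG seed
    max_events,      # per-packet event cap
    use_table,       # 0: inverse-cdf HG sampling, 1: weighted list
    table_cos,       # (res,) cos(theta) values of the weighted list
    table_cdf,       # (res,) cumulative weights of the weighted list
):
    """Propagate every ray of every mesh entry into ``grid``.

    Returns (launched, transmitted, cap_exits, capped, reflections,
    scatters, skipped_samples).
    """
    np.random.seed(seed)
    nx, ny, nz = grid.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    inv_vox = 1.0 / vox
    decay = math.exp(-mu_eff * step)
    pullback = 1.0 - 1e-12

    launched = 0
    transmitted = 0
    cap_exits = 0
    capped = 0
    reflections = 0
    scatters = 0
    skipped = 0

    for e in range(starts.shape[0]):
        for _ray in range(rays_per_entry):
            launched += 1
            px, py, pz = starts[e, 0], starts[e, 1], starts[e, 2]
            dx, dy, dz = dirs[e, 0], dirs[e, 1], dirs[e, 2]
            t = 0.0
            events = 0
            u = np.random.random()
            path = -math.log(1.0 - u) / path_rate
            while True:
                events += 1
                if events > max_events:
                    capped += 1
                    break
                # first boundary crossing along the current direction
                s_side = 1e300
                a = dx * dx + dy * dy
                if a > 1e-30:
                    b = px * dx + py * dy
                    c = px * px + py * py - radius * radius
                    disc = b * b - a * c
                    if disc > 0.0:
                        s = (-b + math.sqrt(disc)) / a
                        if s > 1e-12:
                            s_side = s
                s_cap = 1e300
                if dz > 1e-30:
                    s_cap = (length - pz) / dz
                elif dz < -1e-30:
                    s_cap = -pz / dz

                s_exit = s_side if s_side < s_cap else s_cap
                seg = path if path < s_exit else s_exit

                # deposit remaining intensity every `step` along [p, p+seg)
                n = int(math.ceil(seg / step - 1e-9))
                if n > 0:
                    intensity = math.exp(-mu_eff * t)
                    for k in range(n):
                        s = k * step
                        x = px + s * dx
                        y = py + s * dy
                        z = pz + s * dz
                        ix = int(math.floor((x - ox) * inv_vox))
                        iy = int(math.floor((y - oy) * inv_vox))
                        iz = int(math.floor((z - oz) * inv_vox))
                        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                            grid[ix, iy, iz] += intensity
                        else:
                            skipped += 1
                        intensity *= decay
                t += seg
                px += seg * dx
                py += seg * dy
                pz += seg * dz

                if path < s_exit:
                    # full free path: HG scatter with uniform azimuth
                    u1 = np.random.random()
                    if use_table == 1:
                        j = np.searchsorted(table_cdf, u1, side="right")
                        if j >= table_cos.shape[0]:
                            j = table_cos.shape[0] - 1
                        cos_t = table_cos[j]
                    elif g == 0.0:
                        cos_t = 2.0 * u1 - 1.0
                    else:
                        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
                        cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    u2 = np.random.random()
                    phi = 2.0 * math.pi * u2
                    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                    if abs(dz) > 0.999999:
                        sign = 1.0 if dz >= 0 else -1.0
                        ndx = sin_t * math.cos(phi)
                        ndy = sign * sin_t * math.sin(phi)
                        ndz = sign * cos_t
                    else:
                        den = math.sqrt(1.0 - dz * dz)
                        ndx = sin_t * (dx * dz * math.cos(phi) - dy * math.sin(phi)) / den + dx * cos_t
                        ndy = sin_t * (dy * dz * math.cos(phi) + dx * math.sin(phi)) / den + dy * cos_t
                        ndz = -sin_t * math.cos(phi) * den + dz * cos_t
                    norm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
                    dx, dy, dz = ndx / norm, ndy / norm, ndz / norm
                    scatters += 1
                    u3 = np.random.random()
                    path = -math.log(1.0 - u3) / path_rate
                    continue

                if s_cap < s_side:
                    cap_exits += 1
                    break

                # side wall: reflect above the critical angle, else transmit
                nxn = px / radius
                nyn = py / radius
                cos_i = dx * nxn + dy * nyn
                if cos_i > 1.0:
                    cos_i = 1.0
                if cos_i <= cos_crit:
                    dx -= 2.0 * cos_i * nxn
                    dy -= 2.0 * cos_i * nyn
                    px *= pullback
                    py *= pullback
                    reflections += 1
                    u = np.random.random()
                    path = -math.log(1.0 - u) / path_rate
                    continue
                transmitted += 1
                break

    return launched, transmitted, cap_exits, capped, reflections, scatters, skipped
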