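"""Scripted micro-fixtures and brute-force oracles.

These utilities make the transport loop testable event by event without
any full-scale run: :class:`ScriptedRng` replays a queued sequence of
physical draws (path lengths, deflection angles, azimuth uniforms)
through the reference engine, and :func:`brute_force_grid` re-deposits a
recorded trace with an independent, deliberately naive code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .media import NerveModel
from .transport import PhotonPacket, RunConfig, VoxelGrid, propagate_packet

__all__ = ["ScriptedRng", "ScriptExhausted", "scripted_trajectory",
           "brute_force_grid"]


class ScriptExhausted(RuntimeError):
    """The scripted trajectory ran past the end of its queued draws."""


@dataclass
class ScriptedRng:
    """Replays queued physical draws instead of random ones.

    ``path_lengths`` feed the exponential free-path draws directly (mm);
    ``thetas`` feed the HG deflection angles (radians); ``uniforms`` feed
    whatever raw uniform draws the direction update consumes (the azimuth
    in the standard convention; pivot and orthogonal components in the
    paper-literal one).  Raises :class:`ScriptExhausted` when a queue
    runs dry, and replays identically from a fresh copy.
    """

    path_lengths: list = field(default_factory=list)
    thetas: list = field(default_factory=list)
    uniforms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._paths = list(self.path_lengths)
        self._thetas = list(self.thetas)
        self._uniforms = list(self.uniforms)

    def copy(self) -> "ScriptedRng":
        return ScriptedRng(list(self.path_lengths), list(self.thetas),
                           list(self.uniforms))

    def next_path_length(self) -> float:
        if not self._paths:
            raise ScriptExhausted("path-length script exhausted")
        return self._paths.pop(0)

    def next_theta(self) -> float:
        if not self._thetas:
            raise ScriptExhausted("theta script exhausted")
        return self._thetas.pop(0)

    def random_sample(self) -> float:
        if not self._uniforms:
            raise ScriptExhausted("uniform script exhausted")
        return self._uniforms.pop(0)


def scripted_trajectory(
    script: ScriptedRng,
    nerve: NerveModel,
    config: RunConfig,
    start,
    direction,
    grid: VoxelGrid | None = None,
):
    """Run one packet through the reference engine on scripted draws.

    Returns ``(trace, exit_record, grid)`` where ``trace`` is the list of
    per-segment events ``(kind, start, end, t_end, intensity_end,
    theta_or_angle)`` — every quantity computable by hand from the script.
    """
    if grid is None:
        grid = VoxelGrid.for_nerve(nerve, config.voxel_size)
    packet = PhotonPacket(np.asarray(start, dtype=float),
                          np.asarray(direction, dtype=float))
    trace: list = []
    record = propagate_packet(packet, nerve, grid, script.copy(), config,
                              trace=trace)
    return trace, record, grid


def brute_force_grid(trace, nerve: NerveModel, voxel_size: float,
                     step: float) -> VoxelGrid:
    """Naive re-deposition of a recorded trace into a fresh grid.

    Independent of the engine's deposition code on purpose: it walks each
    traced segment sample by sample with its own loop and evaluates the
    decay law directly.  Voxel binning uses the shared half-open
    convention ``floor((x - origin) / voxel)`` — the binning expression is
    part of the deposition contract, not of the logic under test.  Must
    agree with the engine voxel for voxel.
    """
    grid = VoxelGrid.for_nerve(nerve, voxel_size)
    mu = nerve.medium.mu_eff

    t_start = 0.0
    for _kind, p0, p1, t_end, _intensity, _theta in trace:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        length = float(np.linalg.norm(p1 - p0))
        if length > 0.0:
            d = (p1 - p0) / length
            k = 0
            while k * step < length - 1e-9 * step:
                p = p0 + (k * step) * d
                ix = int(math.floor((p[0] - grid.origin[0]) / voxel_size))
                iy = int(math.floor((p[1] - grid.origin[1]) / voxel_size))
                iz = int(math.floor((p[2] - grid.origin[2]) / voxel_size))
                inside = (
                    0 <= ix < grid.dims[0]
                    and 0 <= iy < grid.dims[1]
                    and 0 <= iz < grid.dims[2]
                )
                if inside:
                    grid.values[ix, iy, iz] += math.exp(-mu * (t_start + k * step))
                else:
                    grid.skipped_samples += 1
                k += 1
        t_start = t_end
    return grid
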