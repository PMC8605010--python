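"""Plot helpers for profiles, sweeps and grid slices."""

from __future__ import annotations

import numpy as np


def plot_radial_profiles(profiles: dict, ax=None, normalized: bool = True):
    """Overlay ring profiles (label -> RadialProfile), surface-normalised."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, prof in profiles.items():
        p = prof.normalized("surface=1") if normalized else prof
        ax.plot(p.ring_centers, p.ring_max, marker="o", label=str(label))
    ax.set_xlabel("distance from nerve axis (mm)")
    ax.set_ylabel("ring max intensity"
                  + (" (surface = 1)" if normalized else ""))
    ax.legend()
    return ax


def plot_sweep(sweep, ax=None):
    """Focal gain vs swept parameter with the zero (surface) baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(sweep.values, sweep.focal_gain_percent, marker="o")
    ax.axhline(0.0, color="red", lw=1, label="nerve surface")
    ax.set_xlabel(sweep.parameter.replace("_", " "))
    ax.set_ylabel("focal gain vs surface (%)")
    ax.legend()
    return ax


def plot_cross_section(matrix: np.ndarray, pixel_size: float, radius: float,
                       ax=None):
    """Internodal cross-section image with the nerve outline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [0, matrix.shape[0] * pixel_size, 0, matrix.shape[1] * pixel_size]
    ax.imshow(np.log10(matrix.T + matrix.max() * 1e-6), origin="lower",
              extent=extent, cmap="inferno")
    theta = np.linspace(0, 2 * np.pi, 256)
    cx = matrix.shape[0] * pixel_size / 2.0
    cy = matrix.shape[1] * pixel_size / 2.0
    ax.plot(cx + radius * np.cos(theta), cy + radius * np.sin(theta),
            "w--", lw=0.8)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax
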