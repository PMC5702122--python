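"""Closed-form reference profiles for the cell-free semi-infinite domain.

For a particle released at the origin of a half line x ≥ 0 with a reflecting
origin, the depth distribution after time t under pure diffusion is

    G(x, t) = (1 / sqrt(π D t)) · exp(−x² / 4 D t),    x ≥ 0,

i.e. a Gaussian folded at the origin: twice the free-space peak height
1/sqrt(4 π D t), unit area on [0, ∞). With a small constant drift v toward
positive x the distribution is the same Gaussian translated by vt,

    G(x, t) = (1 / sqrt(π D t)) · exp(−(x − vt)² / 4 D t).

The drifting form keeps the folded prefactor and is therefore only an
approximation near the origin while vt ≲ sqrt(2 D t); it becomes exact (up to
normalization 1/2) once the peak has moved several widths into the domain.
These profiles validate the cell-free ensembles of the BD engine.
"""

from __future__ import annotations

import numpy as np

__all__ = ["diffusion_profile", "advection_diffusion_profile", "profile_table"]


def diffusion_profile(x, t: float, D: float):
    """Half-plane pure-diffusion profile; peak height 1/sqrt(π D t) at x = 0."""
    if t <= 0 or D <= 0:
        raise ValueError("t and D must be positive")
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise ValueError("profile is defined only for x >= 0")
    return np.exp(-(x**2) / (4 * D * t)) / np.sqrt(np.pi * D * t)


def advection_diffusion_profile(x, t: float, D: float, v: float):
    """Drifting profile: Gaussian of width sqrt(2 D t) centered at x = vt.

    Reduces to :func:`diffusion_profile` at v = 0.
    """
    if t <= 0 or D <= 0:
        raise ValueError("t and D must be positive")
    x = np.asarray(x, float)
    return np.exp(-((x - v * t) ** 2) / (4 * D * t)) / np.sqrt(np.pi * D * t)


def profile_table(t: float, D: float, v: float = 0.0, x_max: float | None = None, n: int = 500):
    """(x, G) table for overlay plotting; x spans [0, x_max]."""
    if x_max is None:
        x_max = v * t + 6 * np.sqrt(2 * D * t)
    x = np.linspace(0, x_max, n)
    g = advection_diffusion_profile(x, t, D, v) if v else diffusion_profile(x, t, D)
    return np.column_stack([x, g])
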