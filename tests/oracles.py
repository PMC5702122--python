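"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's own machinery: the half-line
advection-diffusion problem is solved by a conservative finite-volume
Crank-Nicolson scheme, so ensemble statistics from the Brownian dynamics
engine can be checked against an exact (discretized-PDE) solution rather
than against the engine itself.
"""

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu


def reflected_drift_profile(D, v, t_end, L=1200.0, nx=2400, nt=2500):
    """Density G(x, t_end) for dG/dt = -(d/dx)(v G - D dG/dx) on [0, L].

    Zero-flux (reflecting) wall at x = 0, source delta(x) at t = 0; the right
    end is closed but L is chosen far beyond the support. The finite-volume
    form conserves mass to machine precision. Returns (cell centers, G).
    """
    dx = L / nx
    xc = (np.arange(nx) + 0.5) * dx
    lo = np.zeros(nx - 1)
    mid = np.zeros(nx)
    up = np.zeros(nx - 1)
    for i in range(nx):
        if i < nx - 1:  # flux through the right face of cell i
            mid[i] -= (v / 2 + D / dx) / dx
            up[i] -= (v / 2 - D / dx) / dx
        if i > 0:  # flux through the left face
            mid[i] += (v / 2 - D / dx) / dx
            lo[i - 1] += (v / 2 + D / dx) / dx
    A = sparse.diags([lo, mid, up], [-1, 0, 1], format="csc")
    I = sparse.identity(nx, format="csc")
    dt = t_end / nt
    lu = splu((I - dt / 2 * A).tocsc())
    M2 = (I + dt / 2 * A).tocsc()
    G = np.zeros(nx)
    G[0] = 1.0 / dx
    for _ in range(nt):
        G = lu.solve(M2 @ G)
    return xc, G


def profile_mean(xc, G):
    dx = xc[1] - xc[0]
    return float((xc * G).sum() / G.sum())


def brute_force_nearest(x, cells, domain):
    """Exhaustive nearest-solid-feature search mirroring the documented
    feature ordering (edges 0-2, then cells)."""
    cands = [x[0], x[1], domain.height - x[1]]
    for c in cells.centers:
        cands.append(np.hypot(*(np.asarray(x) - c)) - cells.cell_radius)
    cands = np.asarray(cands)
    idx = int(np.argmin(cands))
    return float(cands[idx]), idx
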