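"""Interstitial Stokes flow by the Method of Regularized Stokeslets (MRS).

Creeping flow past the stationary cells is represented by point forces
spread over a radially symmetric blob of radius ``ε`` placed at collocation
points on every solid boundary. With the blob

    φ_ε(r) = 2ε⁴ / (π (r² + ε²)³),

the velocity at ``x`` due to a regularized point force ``f`` at ``x_k`` is

    u(x) = −f/(8πμ) · (ln(r² + ε²) − 2ε²/(r² + ε²))
           + (f · d) d / (4πμ (r² + ε²)),      d = x − x_k,  r = |d|,

which is smooth everywhere, including at the force location. Prescribing the
boundary velocities at all N collocation points (inlet speed on the left
edge, zero on walls and cell rims) gives a dense 2N×2N linear system for the
unknown forces; the interstitial velocity anywhere is then the superposition
of the N kernel contributions.

Units: lengths in μm, velocities in μm/s, viscosity supplied in centipoise
and converted internally to Pa·s; the solved forces are in the consistent
derived unit (Pa·s·μm²/s per unit depth) and only ever re-enter through the
kernel, so no further conversion is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import BoundaryDiscretization, CellField, DomainSpec

__all__ = [
    "CP_TO_PAS",
    "blob",
    "stokeslet_velocity",
    "StokesletSystem",
    "solve_forces",
    "velocity_at",
    "VelocityGrid",
    "build_velocity_grid",
]

CP_TO_PAS = 1e-3  # 1 centipoise = 1e-3 Pa·s


def blob(r, eps: float):
    """Regularizing cutoff φ_ε(r) = 2ε⁴/(π(r²+ε²)³); integrates to 1 over the plane."""
    if eps <= 0:
        raise ValueError("blob radius eps must be positive")
    r = np.asarray(r, float)
    return 2 * eps**4 / (np.pi * (r**2 + eps**2) ** 3)


def stokeslet_velocity(f_k, x, x_k, eps: float, mu_cp: float):
    """Velocity at ``x`` from a regularized point force ``f_k`` at ``x_k``.

    Finite at ``x == x_k``, where it reduces to −f_k/(8πμ)·(ln ε² − 2).
    """
    if eps <= 0 or mu_cp <= 0:
        raise ValueError("eps and viscosity must be positive")
    mu = mu_cp * CP_TO_PAS
    f_k = np.asarray(f_k, float)
    d = np.asarray(x, float) - np.asarray(x_k, float)
    r2e = d @ d + eps**2
    term1 = -f_k / (8 * np.pi * mu) * (np.log(r2e) - 2 * eps**2 / r2e)
    term2 = (f_k @ d) * d / (4 * np.pi * mu * r2e)
    return term1 + term2


@dataclass(frozen=True)
class StokesletSystem:
    """Solved MRS collocation system: forces reproducing the prescribed BCs."""

    discretization: BoundaryDiscretization
    eps: float  # blob radius, μm
    mu_cp: float  # viscosity, centipoise
    forces: np.ndarray  # (N, 2)
    residual: float  # relative residual of the linear solve

    @property
    def n_points(self) -> int:
        return self.discretization.n_points


def _kernel_blocks(targets: np.ndarray, sources: np.ndarray, eps: float, mu: float):
    """A (isotropic) and B (dyadic) kernel coefficients for all target/source pairs."""
    dx = targets[:, None, 0] - sources[None, :, 0]
    dy = targets[:, None, 1] - sources[None, :, 1]
    r2e = dx * dx + dy * dy + eps**2
    A = -(np.log(r2e) - 2 * eps**2 / r2e) / (8 * np.pi * mu)
    B = 1.0 / (4 * np.pi * mu * r2e)
    return dx, dy, A, B


def solve_forces(
    discretization: BoundaryDiscretization,
    eps: float = 0.5,
    mu_cp: float = 2.5,
    residual_tol: float = 1e-8,
) -> StokesletSystem:
    """Solve the dense 2N×2N collocation system for the boundary point forces.

    Row block j enforces that the superposed kernel velocity at collocation
    point x_j equals its prescribed boundary velocity. Direct LU solve; the
    relative residual is checked against ``residual_tol`` and an
    ill-conditioned system (e.g. coincident collocation points) raises with a
    condition-number estimate.
    """
    pts = discretization.points
    u = discretization.velocities
    n = len(pts)
    if n < 1:
        raise ValueError("empty discretization")
    mu = mu_cp * CP_TO_PAS

    dx, dy, A, B = _kernel_blocks(pts, pts, eps, mu)
    M = np.empty((2 * n, 2 * n))
    M[0::2, 0::2] = A + B * dx * dx
    M[0::2, 1::2] = B * dx * dy
    M[1::2, 0::2] = B * dx * dy
    M[1::2, 1::2] = A + B * dy * dy

    rhs = u.reshape(-1)
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular MRS collocation matrix (cond≈{np.linalg.cond(M):.2e}); "
            "check for coincident collocation points"
        ) from exc
    scale = np.abs(rhs).max()
    residual = float(np.abs(M @ sol - rhs).max() / (scale if scale > 0 else 1.0))
    if residual > residual_tol:
        raise np.linalg.LinAlgError(
            f"MRS solve residual {residual:.2e} exceeds {residual_tol:.1e} "
            f"(cond≈{np.linalg.cond(M):.2e})"
        )
    return StokesletSystem(discretization, eps, mu_cp, sol.reshape(n, 2), residual)


def velocity_at(system: StokesletSystem, x) -> np.ndarray:
    """Exact superposed velocity at one or many positions (μm/s)."""
    x = np.atleast_2d(np.asarray(x, float))
    mu = system.mu_cp * CP_TO_PAS
    pts = system.discretization.points
    f = system.forces
    dx, dy, A, B = _kernel_blocks(x, pts, system.eps, mu)
    fd = f[:, 0] * dx + f[:, 1] * dy  # (m, N)
    vx = (A @ f[:, 0]) + np.sum(B * fd * dx, axis=1)
    vy = (A @ f[:, 1]) + np.sum(B * fd * dy, axis=1)
    out = np.column_stack([vx, vy])
    return out[0] if out.shape[0] == 1 else out


@njit(cache=True)
def _eval_grid(xs, ys, pts, forces, eps, mu):  # pragma: no cover - numba
    nx, ny = xs.size, ys.size
    vx = np.empty((ny, nx))
    vy = np.empty((ny, nx))
    e2 = eps * eps
    c1 = 1.0 / (8.0 * np.pi * mu)
    c2 = 1.0 / (4.0 * np.pi * mu)
    for iy in range(ny):
        for ix in range(nx):
            sx = 0.0
            sy = 0.0
            for k in range(pts.shape[0]):
                dx = xs[ix] - pts[k, 0]
                dy = ys[iy] - pts[k, 1]
                r2e = dx * dx + dy * dy + e2
                a = -c1 * (np.log(r2e) - 2.0 * e2 / r2e)
                fd = forces[k, 0] * dx + forces[k, 1] * dy
                b = c2 * fd / r2e
                sx += a * forces[k, 0] + b * dx
                sy += a * forces[k, 1] + b * dy
            vx[iy, ix] = sx
            vy[iy, ix] = sy
    return vx, vy


@dataclass(frozen=True)
class VelocityGrid:
    """Bilinear-interpolated cache of the static MRS velocity field.

    The field is smooth across cell rims (the superposition is defined
    everywhere), so nodes inside cells hold the analytic continuation and
    interpolation near a rim stays well behaved; fluid-side queries through
    :meth:`velocity` flag positions inside a cell as invalid.
    """

    xs: np.ndarray  # (nx,) node coordinates
    ys: np.ndarray  # (ny,)
    vx: np.ndarray  # (ny, nx)
    vy: np.ndarray  # (ny, nx)
    cells: CellField

    def interpolate(self, x) -> np.ndarray:
        """Raw bilinear interpolation, no fluid-region check."""
        x = np.asarray(x, float)
        dx = self.xs[1] - self.xs[0]
        dy = self.ys[1] - self.ys[0]
        fx = np.clip((x[0] - self.xs[0]) / dx, 0, len(self.xs) - 1 - 1e-12)
        fy = np.clip((x[1] - self.ys[0]) / dy, 0, len(self.ys) - 1 - 1e-12)
        i, j = int(fx), int(fy)
        tx, ty = fx - i, fy - j
        w = np.array(
            [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
        )
        vx = np.array([self.vx[j, i], self.vx[j, i + 1], self.vx[j + 1, i], self.vx[j + 1, i + 1]])
        vy = np.array([self.vy[j, i], self.vy[j, i + 1], self.vy[j + 1, i], self.vy[j + 1, i + 1]])
        return np.array([w @ vx, w @ vy])

    def velocity(self, x) -> np.ndarray:
        """Interpolated fluid velocity; raises for a query inside a cell."""
        if self.cells.contains(x):
            raise ValueError(f"query point {x} lies inside a cell (not fluid)")
        return self.interpolate(x)


def build_velocity_grid(
    system: StokesletSystem, domain: DomainSpec, cells: CellField, resolution: float = 1.0
) -> VelocityGrid:
    """Precompute the velocity on a regular node grid covering the domain.

    Exact summation via :func:`velocity_at` remains available; the cache
    trades a one-off O(grid × N) evaluation for O(1) bilinear queries in the
    particle loop.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nx = max(2, int(np.ceil(domain.width / resolution)) + 1)
    ny = max(2, int(np.ceil(domain.height / resolution)) + 1)
    xs = np.linspace(0.0, domain.width, nx)
    ys = np.linspace(0.0, domain.height, ny)
    mu = system.mu_cp * CP_TO_PAS
    vx, vy = _eval_grid(xs, ys, system.discretization.points, system.forces, system.eps, mu)
    return VelocityGrid(xs, ys, vx, vy, cells)


def export_flow_field(path, grid: VelocityGrid) -> None:
    """Write the cached field as a plain (x, y, vx, vy) CSV table."""
    with open(path, "w") as fh:
        fh.write("x,y,vx,vy\n")
        for j, y in enumerate(grid.ys):
            for i, x in enumerate(grid.xs):
                fh.write(f"{x:.6g},{y:.6g},{grid.vx[j, i]:.9g},{grid.vy[j, i]:.9g}\n")


def export_forces(path, system: StokesletSystem) -> None:
    """Write solved collocation forces as (x, y, fx, fy) for quiver plots."""
    pts = system.discretization.points
    with open(path, "w") as fh:
        fh.write("x,y,fx,fy\n")
        for (x, y), (fx, fy) in zip(pts, system.forces):
            fh.write(f"{x:.6g},{y:.6g},{fx:.9g},{fy:.9g}\n")
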