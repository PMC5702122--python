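"""Time-adaptive Brownian dynamics of nanoparticles in the interstitial space.

Each particle is an independent circle of radius ``a`` advected by the local
fluid velocity and diffusing with the Einstein–Stokes coefficient
``D = k_B T / (6 π μ a)``. A BD step proposes the jump

    S = v·Δt + sqrt(4 D Δt) · e,

with ``e`` a uniformly random unit vector (the diffusive magnitude is
deterministic; only its direction is random). The step size adapts in three
tiers to the distance ``R`` between the particle center and the nearest
solid feature (inlet, walls, or a cell rim):

1. try the largest step ``Δt_max``; accept if ``|S| < R − a`` (the particle
   cannot reach any boundary);
2. otherwise solve ``|v|·Δt_a + sqrt(4 D Δt_a) = R − a`` for the largest
   boundary-safe step and accept the jump if ``|S| > 4a``;
3. otherwise move with the finest fixed step ``δt`` (default 1e−3 s), which
   resolves wall reflection and cell contact. A cell rim is a sticky wall:
   a contacting particle is captured with probability ρ or specularly
   reflected (the rim is treated as flat at the contact point) with
   probability 1 − ρ. The clock advances by δt whether the fine move is
   accepted, reflected, or rejected.

The public per-step functions here are plain Python for clarity and unit
testing; :func:`simulate_ensemble` delegates whole trajectories to the
compiled kernels in :mod:`stokesbd._kernels`, which implement the identical
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import _kernels as K
from .config import RunConfig
from .geometry import CellField, DomainSpec, nearest_boundary_distance, pack_cells
from .stokes import VelocityGrid

__all__ = [
    "BOLTZMANN",
    "diffusion_coefficient",
    "ParticleSpec",
    "ParticleState",
    "StepPolicy",
    "ZeroField",
    "UniformField",
    "propose_jump",
    "solve_intermediate_dt",
    "advance_particle",
    "handle_collision",
    "EnsembleResult",
    "simulate_ensemble",
    "simulate_fixed_step",
]

BOLTZMANN = 1.380649e-23  # J/K (SI CODATA)

_STATUS = {K.STATUS_MOBILE: "mobile", K.STATUS_CAPTURED: "captured", K.STATUS_EXITED: "exited_right"}


def diffusion_coefficient(a: float, temperature: float = 310.0, mu_cp: float = 2.5) -> float:
    """Einstein–Stokes diffusion coefficient in μm²/s.

    Parameters: particle radius ``a`` in μm, temperature in K, viscosity in
    centipoise. For a 100 nm particle at 310 K in 2.5 cP fluid this gives
    ≈ 0.91 μm²/s.
    """
    if a <= 0 or temperature <= 0 or mu_cp <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    d_si = BOLTZMANN * temperature / (6 * np.pi * (mu_cp * 1e-3) * (a * 1e-6))  # m²/s
    return d_si * 1e12  # μm²/s


@dataclass(frozen=True)
class ParticleSpec:
    """Mobile nanoparticle: radius (μm), diffusion constant (μm²/s), capture ρ."""

    radius: float
    diffusion: float
    capture_probability: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("particle radius must be positive")
        if not 0 <= self.capture_probability <= 1:
            raise ValueError("capture probability must lie in [0, 1]")

    @classmethod
    def from_physics(
        cls, radius: float, temperature: float = 310.0, mu_cp: float = 2.5, rho: float = 0.01
    ) -> "ParticleSpec":
        return cls(radius, diffusion_coefficient(radius, temperature, mu_cp), rho)


@dataclass(frozen=True)
class StepPolicy:
    """Adaptive step bounds: Δt_max ≥ Δt ≥ δt, plus the near-wall 4a gate."""

    dt_max: float = 0.1
    dt_min: float = 1e-3

    def __post_init__(self) -> None:
        if not self.dt_max >= self.dt_min > 0:
            raise ValueError("need dt_max >= dt_min > 0")


@dataclass
class ParticleState:
    position: np.ndarray
    status: str = "mobile"  # mobile | captured | exited_right
    time: float = 0.0
    collisions: int = 0
    capture_cell: int = -1
    last_tier: int = 0  # 1, 2 or 3 after a step


class ZeroField:
    """Quiescent fluid (pure diffusion)."""

    def velocity(self, x) -> np.ndarray:
        return np.zeros(2)


class UniformField:
    """Spatially uniform flow, e.g. the cell-free plug-flow limit."""

    def __init__(self, v) -> None:
        self.v = np.asarray(v, float)

    def velocity(self, x) -> np.ndarray:
        return self.v


def propose_jump(x, dt: float, v, D: float, rng: np.random.Generator) -> np.ndarray:
    """One BD jump S = v·dt + sqrt(4 D dt)·e with random unit direction e."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    th = rng.uniform(0, 2 * np.pi)
    e = np.array([np.cos(th), np.sin(th)])
    return np.asarray(v, float) * dt + np.sqrt(4 * D * dt) * e


def solve_intermediate_dt(R: float, a: float, speed: float, D: float) -> float:
    """Largest Δt_a with |v|·Δt_a + sqrt(4 D Δt_a) = R − a.

    The quadratic in u = sqrt(Δt_a) has a single positive root; by
    construction the maximum possible jump over Δt_a equals the gap R − a,
    so the particle cannot cross its nearest boundary within the step.
    """
    if R <= a:
        raise ValueError("particle already at or inside contact (R <= a)")
    if D < 0 or speed < 0 or (D == 0 and speed == 0):
        raise ValueError("need D >= 0, speed >= 0, not both zero")
    return K._solve_dt_intermediate(R - a, speed, D)


def _reflect_edges(p: np.ndarray, a: float, domain: DomainSpec) -> np.ndarray:
    q = p.copy()
    if q[0] < a:
        q[0] = 2 * a - q[0]
    if q[1] < a:
        q[1] = 2 * a - q[1]
    if q[1] > domain.height - a:
        q[1] = 2 * (domain.height - a) - q[1]
    return q


def _is_clear(p: np.ndarray, a: float, domain: DomainSpec, cells: CellField) -> bool:
    if not (a <= p[0] <= domain.width and a <= p[1] <= domain.height - a):
        return False
    if cells.n_cells == 0:
        return True
    d = np.hypot(*(p - cells.centers).T)
    return bool(np.all(d >= cells.cell_radius + a))


def handle_collision(
    state: ParticleState,
    attempted: np.ndarray,
    cell_index: int,
    cells: CellField,
    spec: ParticleSpec,
    rng: np.random.Generator,
    domain: DomainSpec,
) -> ParticleState:
    """Resolve a fine-step move that penetrates cell ``cell_index``.

    With probability ρ the particle is captured at the contact point (center
    placed at distance r + a from the cell center); otherwise the penetrating
    remainder of the displacement is mirrored about the local tangent. If the
    mirrored position is itself invalid the move is rejected and the particle
    stays put. Either way the contact counts as one collision.
    """
    c = cells.centers[cell_index]
    contact = cells.cell_radius + spec.radius
    p = state.position
    d = attempted - p
    # first crossing of the contact circle along the move
    A = d @ d
    Bq = 2 * d @ (p - c)
    Cq = (p - c) @ (p - c) - contact**2
    disc = Bq**2 - 4 * A * Cq
    q = None
    if disc >= 0 and A > 0:
        s = (-Bq - np.sqrt(disc)) / (2 * A)
        if 0 <= s <= 1:
            q = p + s * d
    if q is None:
        dn = np.hypot(*(attempted - c))
        if dn == 0:
            state.collisions += 1
            return state  # degenerate move rejected
        q = c + contact * (attempted - c) / dn

    state.collisions += 1
    if rng.random() < spec.capture_probability:
        state.position = q
        state.status = "captured"
        state.capture_cell = cell_index
        return state
    normal = (q - c) / contact
    rest = attempted - q
    mirrored = q + rest - 2 * (rest @ normal) * normal
    if _is_clear(mirrored, spec.radius, domain, cells):
        state.position = mirrored
    return state


def advance_particle(
    state: ParticleState,
    spec: ParticleSpec,
    policy: StepPolicy,
    field,
    domain: DomainSpec,
    cells: CellField,
    rng: np.random.Generator,
) -> ParticleState:
    """Apply one three-tier adaptive BD step to a mobile particle."""
    if state.status != "mobile":
        raise ValueError(f"cannot advance a particle with status {state.status!r}")
    if cells.contains(state.position):
        raise RuntimeError("inconsistent geometry: mobile particle inside a cell")

    x = state.position
    a = spec.radius
    D = spec.diffusion
    v = np.asarray(field.velocity(x), float)
    speed = float(np.hypot(*v))
    R, _ = nearest_boundary_distance(x, cells, domain)

    # tier 1
    S = propose_jump(x, policy.dt_max, v, D, rng)
    if np.hypot(*S) < R - a:
        state.position = x + S
        state.time += policy.dt_max
        state.last_tier = 1
        if state.position[0] > domain.width:
            state.status = "exited_right"
        return state

    # tier 2
    if R - a > 0 and (D > 0 or speed > 0):
        dta = solve_intermediate_dt(R, a, speed, D)
        S = propose_jump(x, dta, v, D, rng)
        if np.hypot(*S) > 4 * a:
            state.position = x + S
            state.time += dta
            state.last_tier = 2
            if state.position[0] > domain.width:
                state.status = "exited_right"
            return state

    # tier 3
    attempted = x + propose_jump(x, policy.dt_min, v, D, rng)
    state.time += policy.dt_min
    state.last_tier = 3
    attempted = _reflect_edges(attempted, a, domain)
    if attempted[0] > domain.width:
        state.position = attempted
        state.status = "exited_right"
        return state
    if cells.n_cells:
        dists = np.hypot(*(attempted - cells.centers).T) - cells.cell_radius
        j = int(np.argmin(dists))
        if dists[j] < a:
            return handle_collision(state, attempted, j, cells, spec, rng, domain)
    state.position = attempted
    return state


@dataclass
class EnsembleResult:
    """Final records of an independent-particle ensemble.

    ``data`` has one row per particle: entry point, final position, status,
    capture cell, collision count, final clock time, and per-tier step
    counts (adaptive engine only).
    """

    data: pd.DataFrame
    config: dict = dc_field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.data)

    @property
    def captured_fraction(self) -> float:
        if not len(self.data):
            return 0.0
        return float((self.data["status"] == "captured").mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _field_args(field):
    """Map a Python field object onto the kernel's (mode, scalars, arrays)."""
    dummy_ax = np.zeros(2)
    dummy_m = np.zeros((2, 2))
    if field is None or isinstance(field, ZeroField):
        return K.FIELD_ZERO, 0.0, 0.0, dummy_ax, dummy_ax, dummy_m, dummy_m
    if isinstance(field, UniformField):
        return K.FIELD_UNIFORM, float(field.v[0]), float(field.v[1]), dummy_ax, dummy_ax, dummy_m, dummy_m
    if isinstance(field, VelocityGrid):
        return K.FIELD_GRID, 0.0, 0.0, field.xs, field.ys, field.vx, field.vy
    raise TypeError(f"unsupported velocity field type {type(field)!r}")


def _prepare(config: RunConfig, cells, field, entry_positions):
    domain = DomainSpec(config.domain_width, config.domain_height)
    seeds = config.child_seeds("packing", "entry", "particles")
    if cells is None:
        cells = pack_cells(
            domain, config.cell_radius, config.cell_area_fraction, rng_seed=seeds["packing"]
        )
    if field is None:
        if config.v_in == 0:
            field = ZeroField()
        elif cells.n_cells == 0:
            field = UniformField([config.v_in, 0.0])
        else:
            raise ValueError(
                "advection with cells requires a solved velocity field; build one "
                "with stokes.solve_forces + stokes.build_velocity_grid (see "
                "cli_io.run_experiment) or pass v_in=0"
            )
    n = config.n_particles
    if entry_positions is None:
        entry_rng = np.random.default_rng(seeds["entry"])
        x0 = np.zeros(n)
        y0 = entry_rng.uniform(0.0, domain.height, n)
    else:
        entry_positions = np.atleast_2d(np.asarray(entry_positions, float))
        if len(entry_positions) != n:
            raise ValueError("entry_positions length must equal n_particles")
        x0 = entry_positions[:, 0].copy()
        y0 = entry_positions[:, 1].copy()
    pseeds = (
        np.random.SeedSequence(seeds["particles"]).generate_state(max(n, 1), dtype=np.uint32)
        & 0x7FFFFFFF
    ).astype(np.int64)[:n]
    return domain, cells, field, x0, y0, pseeds


def _as_result(config, x0, y0, out, tiers=None) -> EnsembleResult:
    xf, yf, tf, status, ncol, cap = out
    df = pd.DataFrame(
        {
            "particle": np.arange(len(xf)),
            "y_entry": y0,
            "x": xf,
            "y": yf,
            "status": pd.Categorical(
                [_STATUS[int(s)] for s in status], categories=list(_STATUS.values())
            ),
            "capture_cell": cap,
            "collisions": ncol,
            "t_final": tf,
        }
    )
    if tiers is not None:
        df["tier1_steps"] = tiers[:, 0]
        df["tier2_steps"] = tiers[:, 1]
        df["tier3_steps"] = tiers[:, 2]
    return EnsembleResult(df, config.to_dict())


def simulate_ensemble(
    config: RunConfig,
    cells: CellField | None = None,
    field=None,
    entry_positions=None,
) -> EnsembleResult:
    """Simulate ``config.n_particles`` independent particles with the adaptive engine.

    Particles enter at t = 0 from uniform-random points on the inlet edge
    (or from ``entry_positions``) and run until capture, right-edge exit, or
    the horizon ``t_end``. Geometry and flow are packed/derived from the
    config unless supplied. Fully reproducible: the master seed spawns named
    child streams for packing, entry sampling, and one stream per particle,
    so particle order never affects results.
    """
    domain, cells, field, x0, y0, pseeds = _prepare(config, cells, field, entry_positions)
    spec = ParticleSpec.from_physics(
        config.particle_radius, config.temperature, config.viscosity_cp,
        config.capture_probability,
    )
    fmode, ufx, ufy, gxs, gys, gvx, gvy = _field_args(field)
    out = K.simulate_adaptive(
        x0, y0, pseeds, spec.radius, spec.diffusion, spec.capture_probability,
        config.dt_max, config.dt_min, config.t_end,
        domain.width, domain.height,
        cells.centers[:, 0].copy(), cells.centers[:, 1].copy(), cells.cell_radius,
        fmode, ufx, ufy, gxs, gys, gvx, gvy,
    )
    return _as_result(config, x0, y0, out[:6], out[6])


def simulate_fixed_step(
    config: RunConfig,
    dt: float | None = None,
    layer: float | None = None,
    rho: float | None = None,
    cells: CellField | None = None,
    field=None,
    entry_positions=None,
) -> EnsembleResult:
    """Non-adaptive reference engine (constant step, interaction-layer capture).

    Moves that would overlap a cell interior are rejected outright; arrival
    of the particle circle within ``layer`` of a cell rim triggers a capture
    attempt with probability ρ. Used to demonstrate the step-size sensitivity
    that the adaptive engine avoids.
    """
    dt = config.fixed_dt if dt is None else dt
    layer = config.interaction_layer if layer is None else layer
    rho = config.capture_probability if rho is None else rho
    if dt <= 0 or layer <= 0:
        raise ValueError("dt and layer must be positive")
    domain, cells, field, x0, y0, pseeds = _prepare(config, cells, field, entry_positions)
    spec = ParticleSpec.from_physics(
        config.particle_radius, config.temperature, config.viscosity_cp, rho
    )
    fmode, ufx, ufy, gxs, gys, gvx, gvy = _field_args(field)
    out = K.simulate_fixed(
        x0, y0, pseeds, spec.radius, spec.diffusion, rho, dt, layer, config.t_end,
        domain.width, domain.height,
        cells.centers[:, 0].copy(), cells.centers[:, 1].copy(), cells.cell_radius,
        fmode, ufx, ufy, gxs, gys, gvx, gvy,
    )
    return _as_result(config, x0, y0, out)
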