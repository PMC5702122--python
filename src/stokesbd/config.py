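"""Run configuration: physical parameters, numerics, and reproducibility.

Defaults follow the model's reference parameter set: 10 μm cells occupying
40% of the domain area (porosity 0.6), 100 nm particles, per-contact capture
probability ρ = 0.01, interstitial fluid viscosity 2.5 cP at 310 K, inlet
speed 1 μm/s, blob radius ε = 0.5 μm, adaptive steps between δt = 1e−3 s and
Δt_max = 0.1 s. The domain rectangle (1000 × 500 μm) is chosen so that
penetration over a 1e4 s horizon stays well inside the open right edge.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # geometry
    domain_width: float = 1000.0  # μm, tissue depth direction
    domain_height: float = 500.0  # μm
    cell_radius: float = 10.0  # μm
    porosity: float = 0.6  # interstitial area fraction; cells fill 1 − porosity

    # particle physics
    particle_radius: float = 0.1  # μm (100 nm)
    capture_probability: float = 0.01  # ρ, per cell contact
    viscosity_cp: float = 2.5  # interstitial fluid viscosity, centipoise
    temperature: float = 310.0  # K

    # flow solver
    v_in: float = 1.0  # μm/s inlet speed on the left edge
    eps: float = 0.5  # μm, regularized-Stokeslet blob radius
    n_boundary_points: int = 6700
    grid_resolution: float = 0.25  # μm, velocity-cache node spacing

    # time stepping
    dt_max: float = 0.1  # s, largest adaptive step
    dt_min: float = 1e-3  # s, finest (near-boundary) step
    engine: str = "adaptive"  # "adaptive" | "fixed"
    fixed_dt: float = 1e-3  # s, step of the non-adaptive reference engine
    interaction_layer: float = 0.25  # μm, capture shell of the fixed engine

    # ensemble
    n_particles: int = 16000
    t_end: float = 1e4  # s
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.domain_width > 0 and self.domain_height > 0, "domain size"),
            (0 < self.cell_radius < min(self.domain_width, self.domain_height) / 2, "cell_radius"),
            (0 < self.porosity <= 1, "porosity"),
            (self.particle_radius > 0, "particle_radius"),
            (0 <= self.capture_probability <= 1, "capture_probability"),
            (self.viscosity_cp > 0, "viscosity_cp"),
            (self.temperature > 0, "temperature"),
            (self.v_in >= 0, "v_in"),
            (self.eps > 0, "eps"),
            (self.dt_max >= self.dt_min > 0, "time steps (need dt_max >= dt_min > 0)"),
            (self.fixed_dt > 0, "fixed_dt"),
            (self.interaction_layer > 0, "interaction_layer"),
            (self.n_particles >= 0, "n_particles"),
            (self.t_end > 0, "t_end"),
            (self.engine in ("adaptive", "fixed"), "engine"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"invalid configuration value for {name}")

    @property
    def cell_area_fraction(self) -> float:
        return 1.0 - self.porosity

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def child_seeds(self, *names: str) -> dict[str, int]:
        """Named reproducible sub-seeds (< 2^31) derived from the master seed.

        Each consumer (packing, entry sampling, per-particle streams) draws
        its own child so partial reruns stay stable.
        """
        ss = np.random.SeedSequence(self.seed)
        state = ss.generate_state(len(names), dtype=np.uint32)
        return {name: int(s & 0x7FFFFFFF) for name, s in zip(names, state)}

    def to_dict(self) -> dict:
        return asdict(self)


def save_config(path, config: RunConfig) -> None:
    """Write the configuration as a flat key-value YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
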