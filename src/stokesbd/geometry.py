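"""Tissue domain geometry: rectangular section, packed cells, boundary points.

The computational domain is a 2D rectangle representing a tissue section.
The left edge (``OMEGA1``) is a porous capillary wall where nanoparticles
enter and fluid is driven in; the bottom (``OMEGA2``) and top (``OMEGA3``)
edges are stationary no-slip walls; the right edge is open and is chosen far
enough away that particles do not reach it. Cells are stationary discs of a
common radius packed at non-overlapping random positions to a target area
fraction; the remaining area is the interstitial space through which
particles move.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OMEGA1",
    "OMEGA2",
    "OMEGA3",
    "DomainSpec",
    "CellField",
    "BoundaryDiscretization",
    "PackingError",
    "pack_cells",
    "discretize_boundaries",
    "nearest_boundary_distance",
    "save_geometry",
    "load_geometry",
]

# Feature indices for the three solid domain edges; cell i is feature 3 + i.
OMEGA1 = 0  # left edge, inlet
OMEGA2 = 1  # bottom edge, no-slip wall
OMEGA3 = 2  # top edge, no-slip wall


class PackingError(RuntimeError):
    """Raised when random sequential addition cannot reach the target fraction."""


@dataclass(frozen=True)
class DomainSpec:
    """Rectangular tissue section, origin at the bottom-left corner.

    ``width`` is the X extent (tissue depth direction, away from the inlet),
    ``height`` the Y extent, both in micrometres.
    """

    width: float = 1000.0
    height: float = 500.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain width and height must be positive")


@dataclass(frozen=True)
class CellField:
    """Non-overlapping stationary circular cells inside a domain."""

    centers: np.ndarray  # (n, 2) positions, μm
    cell_radius: float  # μm
    achieved_area_fraction: float

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def contains(self, x: np.ndarray) -> bool:
        """True if point ``x`` lies inside (or on) any cell disc."""
        if self.n_cells == 0:
            return False
        d2 = np.sum((self.centers - np.asarray(x, float)) ** 2, axis=1)
        return bool(np.any(d2 <= self.cell_radius**2))


@dataclass(frozen=True)
class BoundaryDiscretization:
    """Collocation points on all solid boundaries with prescribed velocities."""

    points: np.ndarray  # (N, 2) μm
    velocities: np.ndarray  # (N, 2) μm/s, prescribed boundary values
    labels: np.ndarray  # (N,) feature index (0,1,2 edges; 3+i cell i)

    @property
    def n_points(self) -> int:
        return len(self.points)


def _cell_count(domain: DomainSpec, cell_radius: float, target_fraction: float) -> int:
    return int(round(target_fraction * domain.width * domain.height / (np.pi * cell_radius**2)))


def pack_cells(
    domain: DomainSpec,
    cell_radius: float,
    target_fraction: float = 0.40,
    rng_seed: int = 0,
    inlet_margin: float | None = None,
    max_attempts_per_cell: int = 20000,
) -> CellField:
    """Pack non-overlapping cell discs by random sequential addition.

    Centers are proposed uniformly and rejected on overlap with an existing
    cell or protrusion outside the rectangle. A clear margin of
    ``inlet_margin`` (default: one cell radius) is kept between the inlet
    edge and the nearest cell surface so the entry edge stays porous; cells
    may touch the top/bottom walls tangentially.

    The number of cells is fixed up front as
    ``n = round(target_fraction * area / (pi r^2))`` so the achieved area
    fraction matches the target up to one-disc quantization.
    """
    if not (0 <= target_fraction < 0.55):
        raise ValueError(
            "target_fraction must be in [0, ~0.55); random sequential addition "
            "of discs jams near 0.55"
        )
    if cell_radius <= 0 or cell_radius >= min(domain.width, domain.height) / 2:
        raise ValueError("cell_radius must be positive and fit inside the domain")
    if inlet_margin is None:
        inlet_margin = cell_radius

    n = _cell_count(domain, cell_radius, target_fraction)
    area = domain.width * domain.height
    if n == 0:
        return CellField(np.empty((0, 2)), cell_radius, 0.0)

    r = cell_radius
    lo_x, hi_x = r + inlet_margin, domain.width - r
    lo_y, hi_y = r, domain.height - r
    if lo_x >= hi_x or lo_y > hi_y:
        raise PackingError("domain too small for even one cell with the inlet margin")

    rng = np.random.default_rng(rng_seed)
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_cell * n
    min_d2 = (2 * r) ** 2
    while placed < n:
        if attempts >= budget:
            achieved = placed * np.pi * r**2 / area
            raise PackingError(
                f"packing stalled: achieved fraction {achieved:.3f} of target "
                f"{target_fraction:.3f} after {attempts} attempts"
            )
        attempts += 1
        c = rng.uniform((lo_x, lo_y), (hi_x, hi_y))
        if placed and np.min(np.sum((centers[:placed] - c) ** 2, axis=1)) < min_d2:
            continue
        centers[placed] = c
        placed += 1

    achieved = n * np.pi * r**2 / area
    return CellField(centers, r, achieved)


def _allocate_points(lengths: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` points by segment length."""
    quota = lengths / lengths.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return counts


def discretize_boundaries(
    domain: DomainSpec,
    cells: CellField,
    n_points: int = 6700,
    v_in: float = 1.0,
) -> BoundaryDiscretization:
    """Place collocation points on the three solid edges and every cell rim.

    The point budget is split proportionally to segment length (edge length
    or cell perimeter) with largest-remainder rounding. Edge points sit at
    midpoints of equal subintervals (no corner duplicates); cell points are
    equispaced in angle. Prescribed velocities are ``(v_in, 0)`` on the inlet
    and zero on the walls and every cell.
    """
    if v_in < 0:
        raise ValueError("v_in must be non-negative")
    n_seg = 3 + cells.n_cells
    if n_points < n_seg:
        raise ValueError(f"n_points={n_points} is fewer than the {n_seg} boundary segments")

    lengths = np.concatenate(
        [
            [domain.height, domain.width, domain.width],
            np.full(cells.n_cells, 2 * np.pi * cells.cell_radius),
        ]
    )
    counts = _allocate_points(lengths, n_points)
    if cells.n_cells and counts[3:].min() < 3:
        raise ValueError(
            "n_points too small: some cell received fewer than 3 collocation points"
        )

    pts, vels, labs = [], [], []

    def edge_points(m, start, end):
        s = (np.arange(m) + 0.5) / m
        return start + s[:, None] * (np.asarray(end) - np.asarray(start))

    # Ω1: left edge, inlet
    p = edge_points(counts[0], np.array([0.0, 0.0]), np.array([0.0, domain.height]))
    pts.append(p)
    vels.append(np.tile([v_in, 0.0], (counts[0], 1)))
    labs.append(np.full(counts[0], OMEGA1))
    # Ω2: bottom wall
    p = edge_points(counts[1], np.array([0.0, 0.0]), np.array([domain.width, 0.0]))
    pts.append(p)
    vels.append(np.zeros((counts[1], 2)))
    labs.append(np.full(counts[1], OMEGA2))
    # Ω3: top wall
    p = edge_points(counts[2], np.array([0.0, domain.height]), np.array([domain.width, domain.height]))
    pts.append(p)
    vels.append(np.zeros((counts[2], 2)))
    labs.append(np.full(counts[2], OMEGA3))
    # cell rims
    for i in range(cells.n_cells):
        m = counts[3 + i]
        th = 2 * np.pi * np.arange(m) / m
        p = cells.centers[i] + cells.cell_radius * np.column_stack([np.cos(th), np.sin(th)])
        pts.append(p)
        vels.append(np.zeros((m, 2)))
        labs.append(np.full(m, 3 + i))

    return BoundaryDiscretization(
        np.concatenate(pts), np.concatenate(vels), np.concatenate(labs)
    )


def nearest_boundary_distance(
    x: np.ndarray, cells: CellField, domain: DomainSpec
) -> tuple[float, int]:
    """Distance from ``x`` to the nearest solid feature and that feature's index.

    Candidate features are the inlet, the two walls, and every cell rim
    (distance ``|x − c| − r``). Ties break to the lowest feature index
    (edges 0–2 before cells 3+i). ``x`` must be interstitial.
    """
    x = np.asarray(x, float)
    if not (0 <= x[0] <= domain.width and 0 <= x[1] <= domain.height):
        raise ValueError(f"point {x} is outside the domain")
    if cells.contains(x):
        raise ValueError(f"point {x} is inside a cell")
    dists = [x[0], x[1], domain.height - x[1]]
    if cells.n_cells:
        dists = np.concatenate(
            [dists, np.hypot(*(x - cells.centers).T) - cells.cell_radius]
        )
    else:
        dists = np.asarray(dists)
    idx = int(np.argmin(dists))  # argmin takes the first minimum: lowest index wins ties
    return float(dists[idx]), idx


# -- serialization ------------------------------------------------------------

_FMT = "%.17g"  # round-trips float64 exactly


def save_geometry(path, domain: DomainSpec, cells: CellField) -> None:
    """Write domain fields and one (x, y) row per cell to a plain CSV."""
    with open(path, "w") as fh:
        fh.write(f"# width={_FMT % domain.width}\n")
        fh.write(f"# height={_FMT % domain.height}\n")
        fh.write(f"# cell_radius={_FMT % cells.cell_radius}\n")
        fh.write("x,y\n")
        for cx, cy in cells.centers:
            fh.write(f"{_FMT % cx},{_FMT % cy}\n")


def load_geometry(path) -> tuple[DomainSpec, CellField]:
    """Reload a geometry written by :func:`save_geometry`, bit-exactly."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, val = line[1:].split("=")
                header[key.strip()] = float(val)
            elif line and line != "x,y":
                rows.append(tuple(float(v) for v in line.split(",")))
    domain = DomainSpec(header["width"], header["height"])
    centers = np.asarray(rows, float).reshape(-1, 2)
    r = header["cell_radius"]
    frac = len(centers) * np.pi * r**2 / (domain.width * domain.height)
    return domain, CellField(centers, r, frac if len(centers) else 0.0)
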