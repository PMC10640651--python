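"""Synthesis of the idealized study domain.

Builds the back-barrier basin grid (role mask, bathymetry, river placement)
and the tidal/river forcing objects that the flow and morphodynamics modules
consume.  The footprint is resolution independent: a 4 km x 2 km estuarine
basin behind two non-erodible barriers, connected through a central inlet to
a 2 km x 2 km offshore block whose bed drops to -100 m at the open boundary.

Array convention: scalar fields are cell centred with shape ``(ny, nx)``,
0-based indices, x (axis 1) running seaward -> landward, y (axis 0) across
the estuary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .config import GridConfig, RiverConfig, TideConfig

# cell roles
ROLE_SEA = 0            # offshore water
ROLE_BASIN = 1          # estuarine basin
ROLE_BARRIER = 2        # non-erodible barrier, never wet
ROLE_RIVER = 3          # basin-edge cell carrying a river inflow
ROLE_OPEN_BOUNDARY = 4  # seaward column with the prescribed tidal level

#: elevation assigned to barrier cells; high enough to stay dry forever
BARRIER_ELEVATION = 10.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def river_width_from_discharge(q: float) -> float:
    """Hydraulic-geometry width W = 7.2 Q^0.5 (m) for discharge Q (m3/s)."""
    if q < 0:
        raise ValueError("river discharge must be non-negative")
    return 7.2 * math.sqrt(q)


@dataclass(frozen=True)
class RiverSpec:
    """One fluvial inflow discharging into the basin edge."""

    location: str                 # "north", "head" or "south"
    discharge: float              # m3/s
    width: float                  # m
    cells: Tuple[Tuple[int, int], ...]  # (j, i) source cells


@dataclass(frozen=True)
class TidalForcing:
    """Single-constituent tide imposed at the open-sea boundary."""

    amplitude: float              # m (= range / 2)
    omega: float                  # rad/s
    phase: float = 0.0

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    def level(self, t):
        """Water level (m MSL) at time t (s); starts at MSL rising."""
        return self.amplitude * np.sin(self.omega * t + self.phase)

    @classmethod
    def from_config(cls, cfg: TideConfig) -> "TidalForcing":
        return cls(amplitude=cfg.amplitude, omega=cfg.omega)


@dataclass
class GridSpec:
    """Structured grid with the cell-role mask of the idealized basin."""

    nx: int
    ny: int
    dx: float
    dy: float
    role: np.ndarray                      # (ny, nx) int8
    ix_barrier: int                       # column index of the barrier strip
    inlet_rows: Tuple[int, int]           # [j0, j1) rows forming the inlet
    rivers: Tuple[RiverSpec, ...] = field(default_factory=tuple)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def basin_mask(self) -> np.ndarray:
        """Basin cells (river inflow cells included)."""
        return (self.role == ROLE_BASIN) | (self.role == ROLE_RIVER)

    @property
    def barrier_mask(self) -> np.ndarray:
        return self.role == ROLE_BARRIER

    @property
    def forced_mask(self) -> np.ndarray:
        """Cells with a prescribed (tidal) water level."""
        return self.role == ROLE_OPEN_BOUNDARY

    @property
    def basin_area(self) -> float:
        return float(self.basin_mask.sum()) * self.cell_area

    def river_source_field(self) -> np.ndarray:
        """Volumetric source (m3/s) per cell from all rivers."""
        q = np.zeros((self.ny, self.nx))
        for r in self.rivers:
            per_cell = r.discharge / len(r.cells)
            for (j, i) in r.cells:
                q[j, i] += per_cell
        return q


def build_grid(resolution_m: float, grid_cfg: GridConfig | None = None,
               river_cfg: RiverConfig | None = None) -> GridSpec:
    """Construct the role mask of the idealized domain at a given resolution.

    Two barrier strips flank a central inlet at the basin/offshore junction;
    three river inflow segments sit on the north, head (landward) and south
    sides of the basin.  Rejects resolutions at which the inlet would span
    fewer than two cells.
    """
    cfg = grid_cfg or GridConfig()
    rcfg = river_cfg or RiverConfig()
    dx = float(resolution_m)
    if dx <= 0:
        raise ValueError("resolution must be positive")

    nx_off = _round_half_up(cfg.offshore_length / dx)
    nx_basin = _round_half_up(cfg.basin_length / dx)
    ny = _round_half_up(cfg.basin_width / dx)
    nx = nx_off + nx_basin

    n_inlet = _round_half_up(cfg.inlet_width / dx)
    if n_inlet < 2:
        raise ValueError(
            f"inlet ({cfg.inlet_width} m) must span at least 2 cells; "
            f"resolution {dx} m is too coarse"
        )

    role = np.full((ny, nx), ROLE_BASIN, dtype=np.int8)
    role[:, :nx_off] = ROLE_SEA
    role[:, 0] = ROLE_OPEN_BOUNDARY

    # barrier strip with a centred inlet gap occupies the first basin column
    ix_b = nx_off
    j0 = (ny - n_inlet) // 2
    j1 = j0 + n_inlet
    role[:, ix_b] = ROLE_BARRIER
    role[j0:j1, ix_b] = ROLE_BASIN

    # river inflow segments: head (east edge, centred), north and south edges
    n_riv = max(1, _round_half_up(rcfg.width / dx))
    rivers = []

    jc = ny // 2 - n_riv // 2
    head_cells = tuple((j, nx - 1) for j in range(jc, jc + n_riv))
    i_north = ix_b + _round_half_up(2.0 / 3.0 * nx_basin)
    north_cells = tuple((ny - 1, i) for i in range(i_north, i_north + n_riv))
    i_south = ix_b + _round_half_up(1.0 / 3.0 * nx_basin)
    south_cells = tuple((0, i) for i in range(i_south, i_south + n_riv))

    for loc, cells in (("north", north_cells), ("head", head_cells),
                       ("south", south_cells)):
        for (j, i) in cells:
            role[j, i] = ROLE_RIVER
        rivers.append(RiverSpec(location=loc, discharge=rcfg.discharge,
                                width=rcfg.width, cells=cells))

    return GridSpec(nx=nx, ny=ny, dx=dx, dy=dx, role=role, ix_barrier=ix_b,
                    inlet_rows=(j0, j1), rivers=tuple(rivers))


def initial_elevation(grid: GridSpec, grid_cfg: GridConfig | None = None) -> np.ndarray:
    """Initial bed elevation (m MSL).

    Basin cells sit at the prescribed platform level (-1.5 m); the offshore
    block slopes linearly from that level at the barrier line down to the
    open-boundary depth (-100 m); barrier cells are set high and dry.
    """
    cfg = grid_cfg or GridConfig()
    z = np.full((grid.ny, grid.nx), cfg.basin_elevation)
    ix_b = grid.ix_barrier
    for i in range(ix_b):
        frac = (ix_b - i) / ix_b  # 0 at barrier line -> 1 at open boundary
        z[:, i] = cfg.basin_elevation + frac * (cfg.offshore_depth - cfg.basin_elevation)
    z[grid.barrier_mask] = BARRIER_ELEVATION
    return z
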