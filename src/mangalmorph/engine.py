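"""Coupled scenario engine.

Advances the estuary through seasonal coupling steps: each season simulates
a short burst of tidal cycles with the current vegetation roughness, applies
morphological change with the acceleration factor (so that accelerated
hydrodynamic time covers one season), then performs the season's vegetation
update (colonization at season 1, growth every season, mortality at season
4) and refreshes the roughness for the next burst.  Scenario plans branch
from shared checkpoints simply by copying a :class:`RunState`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

from . import _kernels as K
from . import metrics as M
from . import vegetation as V
from .config import RunConfig, SEASONS_PER_YEAR, YEAR_SECONDS
from .domain import GridSpec, TidalForcing, build_grid
from .hydro import FlowState
from .scenarios import ScenarioPlan, make_scenario
from .sediment import BedState, init_bathymetry


@dataclass
class RunState:
    """Complete mutable state of one simulation (branch-copyable)."""

    year: float
    season: int                      # 0..3 within the ecological year
    t: float                         # hydrodynamic clock (s)
    parity: int                      # ADI sweep-order alternation
    flow: FlowState
    bed: BedState
    veg: V.VegetationState
    m_mud: np.ndarray                # suspended mud (kg/m2)
    m_sand: np.ndarray               # suspended sand (kg/m2)
    hp: np.ndarray                   # relative hydroperiod, last cycle
    tau_max: np.ndarray              # max bed shear stress, last cycle (N/m2)
    tau_mean: np.ndarray
    tp: float = 0.0                  # tidal prism, last cycle (m3)
    applied_events: Set[int] = dc_field(default_factory=set)
    metrics: List[dict] = dc_field(default_factory=list)
    snapshots: Dict[float, dict] = dc_field(default_factory=dict)
    residuals: List[float] = dc_field(default_factory=list)
    year_acc: Dict[str, float] = dc_field(default_factory=dict)

    def copy(self) -> "RunState":
        return RunState(
            year=self.year, season=self.season, t=self.t, parity=self.parity,
            flow=FlowState(self.flow.eta.copy(), self.flow.u.copy(),
                           self.flow.v.copy()),
            bed=self.bed.copy(), veg=self.veg.copy(),
            m_mud=self.m_mud.copy(), m_sand=self.m_sand.copy(),
            hp=self.hp.copy(), tau_max=self.tau_max.copy(),
            tau_mean=self.tau_mean.copy(), tp=self.tp,
            applied_events=set(self.applied_events),
            metrics=[dict(r) for r in self.metrics],
            snapshots={k: {n: a.copy() for n, a in v.items()}
                       for k, v in self.snapshots.items()},
            residuals=list(self.residuals),
            year_acc=dict(self.year_acc),
        )


class Engine:
    """Drives one grid/config combination through scenario plans."""

    def __init__(self, config: Optional[RunConfig] = None):
        self.cfg = config or RunConfig()
        c = self.cfg
        self.grid: GridSpec = build_grid(c.grid.resolution, c.grid, c.river)
        self.tide = TidalForcing.from_config(c.tide)
        self.qsrc = self.grid.river_source_field()
        self.forced = np.ascontiguousarray(self.grid.forced_mask)
        self.basin = self.grid.basin_mask
        self.high_water = self.tide.amplitude
        self.low_water = -self.tide.amplitude
        self.rng = np.random.default_rng(c.seed)

        season_s = YEAR_SECONDS / SEASONS_PER_YEAR
        self.steps_per_season = max(1, int(round(
            season_s / c.sediment.morfac / c.hydro.dt)))
        self.cycle_steps = max(1, int(round(self.tide.period / c.hydro.dt)))
        self.diag_start = max(0, self.steps_per_season - self.cycle_steps)
        # inlet section: x-faces at the barrier column, inlet rows
        self.inlet_i = self.grid.ix_barrier
        self.inlet_j0, self.inlet_j1 = self.grid.inlet_rows
        self.c_sand_river = c.sediment.river_sand_concentration

    # -- state construction ------------------------------------------------
    def new_state(self) -> RunState:
        ny, nx = self.grid.ny, self.grid.nx
        bed = init_bathymetry(self.grid, self.cfg.grid, self.cfg.sediment)
        flow = FlowState.at_rest(ny, nx)
        flow.eta[:] = np.maximum(0.0, bed.z)  # dry land keeps zero depth
        return RunState(
            year=0.0, season=0, t=0.0, parity=0, flow=flow, bed=bed,
            veg=V.VegetationState.empty(ny, nx),
            m_mud=np.zeros((ny, nx)), m_sand=np.zeros((ny, nx)),
            hp=np.zeros((ny, nx)), tau_max=np.zeros((ny, nx)),
            tau_mean=np.zeros((ny, nx)),
        )

    # -- one seasonal coupling step ---------------------------------------
    def run_season(self, state: RunState, mud_mg_l: float,
                   vegetation_on: bool) -> None:
        c = self.cfg
        hcfg, scfg, vcfg = c.hydro, c.sediment, c.vegetation
        grid = self.grid
        area = grid.cell_area
        ny, nx = grid.ny, grid.nx

        if vegetation_on and vcfg.enabled:
            hv1, n1, hv2, n2 = V.to_roughness_summary(state.veg, area, vcfg)
        else:
            hv1 = n1 = hv2 = n2 = np.zeros((ny, nx))

        frac_mud, avail_mud, avail_sand, _ = state.bed.summaries(scfg.active_layer)
        frac_sand = 1.0 - frac_mud
        acc_dmud = np.zeros((ny, nx))
        acc_emud = np.zeros((ny, nx))
        acc_dsand = np.zeros((ny, nx))
        acc_esand = np.zeros((ny, nx))
        acc_bl = np.zeros((ny, nx))
        acc_blm = np.zeros((ny, nx))
        hp_time = np.zeros((ny, nx))
        tau_max = np.zeros((ny, nx))
        tau_sum = np.zeros((ny, nx))
        ledger = np.zeros(K.LED_N)

        susp_mud0 = state.m_mud.sum() * area
        susp_sand0 = state.m_sand.sum() * area

        state.t = K.simulate_burst(
            state.flow.eta, state.flow.u, state.flow.v, state.bed.z,
            self.forced, self.qsrc,
            hv1, n1, hv2, n2,
            state.m_mud, state.m_sand,
            frac_mud, frac_sand, avail_mud, avail_sand,
            state.bed.non_erodible,
            acc_dmud, acc_emud, acc_dsand, acc_esand, acc_bl, acc_blm,
            self.steps_per_season, hcfg.dt, state.t,
            self.tide.amplitude, self.tide.omega, grid.dx, grid.dy,
            hcfg.g, hcfg.kappa, hcfg.chezy_bare, hcfg.drag_coefficient,
            hcfg.rho_water, hcfg.dry_depth, hcfg.theta,
            hcfg.velocity_smoothing, hcfg.diffusivity,
            scfg.m_erosion, scfg.tau_ce, scfg.tau_cd, scfg.ws_mud,
            scfg.ws_sand, scfg.sand_capacity_coeff, scfg.sand_ucrit**2,
            scfg.bedload_coeff, scfg.slope_transverse, scfg.slope_longitudinal,
            scfg.rho_dry_mud, scfg.rho_dry_sand,
            scfg.morfac, mud_mg_l * 1e-3, self.c_sand_river, 0.0,
            scfg.max_bed_change_per_step,
            self.high_water + scfg.deposition_ceiling_above_hw,
            scfg.critical_slope,
            self.inlet_i, self.inlet_j0, self.inlet_j1,
            self.diag_start, hcfg.dry_depth, scfg.transport_stride, True,
            hp_time, tau_max, tau_sum, ledger)

        # --- sediment mass closure (hydrodynamic-time budget) -------------
        morfac = scfg.morfac
        exch_mud = (acc_emud.sum() - acc_dmud.sum()) * area / morfac
        exch_sand = (acc_esand.sum() - acc_dsand.sum()) * area / morfac
        dsusp_mud = state.m_mud.sum() * area - susp_mud0
        dsusp_sand = state.m_sand.sum() * area - susp_sand0
        rhs_mud = ledger[K.LED_MUD_RIV] + ledger[K.LED_MUD_BND] + exch_mud
        rhs_sand = ledger[K.LED_SAND_RIV] + ledger[K.LED_SAND_BND] + exch_sand
        scale = max(1.0, abs(ledger[K.LED_MUD_RIV]), abs(exch_mud),
                    abs(exch_sand), abs(dsusp_mud), abs(dsusp_sand))
        res = max(abs(dsusp_mud - rhs_mud), abs(dsusp_sand - rhs_sand)) / scale
        state.residuals.append(res)
        if res > 1e-5:
            raise RuntimeError(
                f"sediment mass closure failed at year {state.year:.2f} "
                f"(relative residual {res:.3e}); state retained for inspection")

        # --- stratigraphy bookkeeping -------------------------------------
        dvol_mud = (acc_dmud - acc_emud) / scfg.rho_dry_mud + acc_blm
        dvol_sand = (acc_dsand - acc_esand) / scfg.rho_dry_sand + acc_bl
        state.bed.apply_season(dvol_mud, dvol_sand, scfg)

        # --- cycle diagnostics --------------------------------------------
        denom = self.cycle_steps * hcfg.dt
        state.hp = hp_time / denom
        state.tau_max = tau_max
        state.tau_mean = tau_sum / self.cycle_steps
        state.tp = max(ledger[K.LED_TP_FLOOD], ledger[K.LED_TP_EBB])

        acc = state.year_acc
        acc["mud_in"] = acc.get("mud_in", 0.0) + morfac * ledger[K.LED_MUD_RIV]
        acc["mud_bnd"] = acc.get("mud_bnd", 0.0) + morfac * ledger[K.LED_MUD_BND]
        acc["sand_in"] = acc.get("sand_in", 0.0) + morfac * ledger[K.LED_SAND_RIV]
        acc["sand_bnd"] = acc.get("sand_bnd", 0.0) + morfac * ledger[K.LED_SAND_BND]

        # --- seasonal vegetation update -----------------------------------
        veg = state.veg
        if vegetation_on and vcfg.enabled:
            tau_stat = state.tau_max if vcfg.tau_statistic == "max" else state.tau_mean
            if state.season == 0:
                V.attempt_colonization(veg, state.hp, tau_stat, self.basin,
                                       area, vcfg)
            f, comp = V.compute_stress(veg, state.hp, area, vcfg)
            V.grow_cohorts(veg, f, comp, 1.0 / SEASONS_PER_YEAR, vcfg)
            if state.season == SEASONS_PER_YEAR - 1:
                f, comp = V.compute_stress(veg, state.hp, area, vcfg)
                V.apply_mortality(veg, f, comp, area, vcfg)
                V.elevation_taper(veg, state.bed.z, self.high_water, vcfg)
        if state.season == SEASONS_PER_YEAR - 1:
            V.tick_root_persistence(veg)

        state.season = (state.season + 1) % SEASONS_PER_YEAR
        state.year = round((state.year + 1.0 / SEASONS_PER_YEAR)
                           * SEASONS_PER_YEAR) / SEASONS_PER_YEAR

    # -- annual bookkeeping ------------------------------------------------
    def _record_year(self, state: RunState, plan: ScenarioPlan) -> None:
        c = self.cfg
        grid = self.grid
        top1m = state.bed.summaries(c.sediment.active_layer)[3]
        acc_space = M.accommodation_space(state.bed.z, self.basin,
                                          self.high_water, grid.cell_area)
        row = {
            "year": round(state.year),
            "scenario": plan.name,
            "accommodation_m3": acc_space,
            "muddy_fraction": M.muddy_region_fraction(top1m, self.basin),
            "coverage": M.mangrove_coverage(state.veg.mask, self.basin),
            "amsl": M.relative_area_amsl(state.bed.z, self.basin,
                                         self.high_water),
            "sy_kg": state.year_acc.get("mud_in", 0.0),
            "mud_export_kg": -state.year_acc.get("mud_bnd", 0.0),
            "tp_m3": state.tp,
        }
        sy = M.sediment_yield_and_prism(row["sy_kg"], state.tp, c.sediment)
        row["sy_tp"] = sy["SY_TP"]
        state.metrics.append(row)
        state.year_acc = {}
        if any(abs(state.year - e) < 1e-9 for e in plan.output_epochs):
            top1m = top1m.copy()
            state.snapshots[state.year] = {
                "elevation": state.bed.z.copy(),
                "mud_fraction_top1m": top1m,
                "stems": state.veg.stems.copy(),
                "stem_diameter_cm": state.veg.d_cm.copy(),
                "hydroperiod": state.hp.copy(),
                "tau_max": state.tau_max.copy(),
            }

    # -- scenario driver ---------------------------------------------------
    def run(self, plan: ScenarioPlan, state: Optional[RunState] = None,
            stop_year: Optional[float] = None) -> RunState:
        """Advance a (possibly branched) state to ``stop_year``.

        Identical configuration and seed give bit-identical trajectories;
        management branches share a disturbance trajectory by copying the
        state at the branch year and resuming under a different plan.
        """
        state = state if state is not None else self.new_state()
        stop = plan.horizon if stop_year is None else min(stop_year, plan.horizon)
        while state.year < stop - 1e-9:
            if state.season == 0:
                for idx, ev in enumerate(plan.events):
                    if idx in state.applied_events:
                        continue
                    if abs(ev.year - state.year) < 1e-9:
                        if ev.kind == "remove_vegetation":
                            V.remove_mangroves(
                                state.veg, ev.fraction, self.grid.cell_area,
                                self.cfg.vegetation,
                                ev.root_persistence_years, self.rng)
                        state.applied_events.add(idx)
            phase = plan.phase_at(state.year + 1e-6)
            self.run_season(state, phase.mud_mg_l, phase.vegetation)
            if state.season == 0:
                self._record_year(state, plan)
        return state


def run_scenario(plan_name: str, config: Optional[RunConfig] = None,
                 stop_year: Optional[float] = None):
    """Run a catalogue scenario end to end; returns (state, metrics frame)."""
    cfg = config or RunConfig()
    plan = make_scenario(plan_name, cfg.river, cfg.scenario)
    eng = Engine(cfg)
    state = eng.run(plan, stop_year=stop_year)
    return state, metrics_frame(state)


def metrics_frame(state: RunState) -> pd.DataFrame:
    """Annual metrics as a tidy DataFrame (one row per year)."""
    return pd.DataFrame(state.metrics)
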