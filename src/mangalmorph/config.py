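"""Run configuration: every physical and numerical parameter of the model.

All values carry SI units unless noted.  Defaults reproduce the idealized
New-Zealand back-barrier basin setup (4 km x 2 km basin, M2 tide of 1.5 m
range, three 18 m3/s rivers) at the desk-scale reference resolution of 60 m.
Configurations serialize losslessly to YAML; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
from typing import List

import yaml
from pydantic import BaseModel, ConfigDict, Field

#: seconds in one morphological year (Julian year)
YEAR_SECONDS = 365.25 * 86400.0
#: vegetation updates per morphological year (seasonal coupling)
SEASONS_PER_YEAR = 4


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Strict):
    """Idealized domain geometry."""

    resolution: float = 60.0          # cell size dx = dy (m)
    basin_length: float = 4000.0      # estuarine basin, along-estuary (m)
    basin_width: float = 2000.0       # across-estuary (m)
    offshore_length: float = 2000.0   # offshore block, along-estuary (m)
    inlet_width: float = 300.0        # gap between the two barriers (m)
    basin_elevation: float = -1.5     # initial basin bed (m MSL)
    offshore_depth: float = -100.0    # bed at the open-sea boundary (m MSL)


class TideConfig(_Strict):
    """Single-constituent (M2-type) tidal forcing at the seaward boundary."""

    tidal_range: float = 1.5          # m
    frequency_deg_per_hr: float = 30.0

    @property
    def amplitude(self) -> float:
        return self.tidal_range / 2.0

    @property
    def omega(self) -> float:
        """Angular frequency (rad/s)."""
        import math

        return math.radians(self.frequency_deg_per_hr) / 3600.0

    @property
    def period(self) -> float:
        import math

        return 2.0 * math.pi / self.omega


class RiverConfig(_Strict):
    """The three fluvial inflows (north, head, south)."""

    discharge: float = 18.0           # m3/s per river
    width: float = 30.0               # m; consistent with W = 7.2 Q^0.5
    mud_low: float = 5.0              # mg/L, pre-disturbance supply
    mud_high: float = 15.0            # mg/L, post-disturbance supply
    mud_intermediate: float = 10.0    # mg/L, midpoint management level


class HydroConfig(_Strict):
    """Depth-averaged flow solver parameters."""

    dt: float = 300.0                 # hydrodynamic time step (s)
    theta: float = 0.55               # implicitness of the free-surface terms
    velocity_smoothing: float = 0.1   # lateral momentum-exchange filter weight
    chezy_bare: float = 65.0          # C_b, unvegetated bed Chezy (m^1/2/s)
    drag_coefficient: float = 1.0     # C_D of vegetation objects (-)
    kappa: float = 0.41               # Von Karman constant
    g: float = 9.81                   # m/s2
    rho_water: float = 1025.0         # kg/m3
    dry_depth: float = 0.05           # wetting/drying threshold (m)
    diffusivity: float = 1.0          # horizontal mixing of suspended load (m2/s)


class SedimentConfig(_Strict):
    """Sand and mud transport parameters.

    Mud (Partheniades-Krone) values are calibration knobs chosen in the range
    reported for muddy intertidal systems; they are deliberately
    config-exposed.
    """

    d50_sand: float = 250e-6          # m
    m_erosion: float = 1e-4           # mud erosion rate M (kg/m2/s)
    tau_ce: float = 0.2               # critical erosion stress (N/m2)
    tau_cd: float = 1000.0            # critical deposition stress (N/m2); large
    #                                   value means deposition is never shut off
    ws_mud: float = 5e-4              # mud settling velocity (m/s)
    ws_sand: float = 0.03             # sand settling velocity for 250 um (m/s)
    sand_capacity_coeff: float = 0.4  # c_eq = k (u^2 - u_cr^2)^1.5 (kg s3/m6)
    sand_ucrit: float = 0.35          # critical depth-averaged speed for 250 um
    #                                   sand (Van Rijn-consistent at 1-3 m depth)
    bedload_coeff: float = 3e-4       # q_b = a (u^2 - u_cr^2)^1.5 (m3 s2/m4)
    slope_transverse: float = 2.0     # Koch-Flokstra transverse slope coefficient
    slope_longitudinal: float = 1.0   # damping of upslope bed-load
    morfac: float = 90.0              # morphological acceleration factor
    max_bed_change_per_step: float = 0.1   # cap on each accelerated flux (m/step)
    transport_stride: int = 2         # flow steps between sediment updates
    deposition_ceiling_above_hw: float = 0.0   # deposition stops above high
    #                                   water (tidal deposition needs inundation)
    critical_slope: float = 0.06      # avalanching threshold (m/m)
    river_sand_concentration: float = 0.0  # kg/m3; rivers carry mud only by
    #                                   default — sand cannot leave the mouth
    #                                   cell at desk scale and would pile up
    rho_dry_mud: float = 500.0        # dry bed density of mud (kg/m3)
    rho_dry_sand: float = 1600.0      # dry bed density of sand (kg/m3)
    layer_thickness: float = 0.1      # nominal stratigraphy layer (m)
    active_layer: float = 0.2         # surface layer governing erodible mix (m)
    substrate_depth: float = 25.0     # initial sandy substrate below the bed (m)
    max_layers: int = 48


class VegetationConfig(_Strict):
    """Mangrove (*Avicennia marina*) life-cycle parameters.

    Growth follows the classic diameter increment law
    dD/dt = G D (1 - D H / (Dmax Hmax)) / (274 + 3 b2 D - 4 b3 D^2) * f * C
    with the allometry H = 137 + b2 D - b3 D^2 (D, H in cm).  b2 and b3 are
    constrained so that H(D_max) = H_max with a vertex at D_max.
    """

    enabled: bool = True
    growth_g: float = 162.0           # G (cm/yr)
    b2: float = 20.333333333333332    # cm/cm
    b3: float = 0.5648148148148148    # cm/cm2
    d_max: float = 18.0               # maximum stem diameter (cm)
    h_max: float = 320.0              # maximum tree height (cm)
    seedling_diameter: float = 0.5    # cm
    seedling_density_ha: float = 3000.0   # individuals per hectare at settling
    hp_min: float = 0.0               # colonization window on relative hydroperiod
    hp_max: float = 0.5
    tau_settle: float = 0.2           # max bed shear stress for settling (N/m2)
    tau_statistic: str = "max"        # "max" or "mean" over the tidal cycle
    fitness_ramp: float = 0.1         # f rises linearly to 1 over this hp range
    biomass_a: float = 0.308          # stem biomass = a D^b (kg, D in cm)
    biomass_b: float = 2.11
    biomass_half: float = 40.0        # competition half-saturation (kg/m2)
    viability: float = 0.5            # f*C threshold for suppression/colonization
    suppression_years: int = 5        # consecutive years before self-thinning
    pneu_height: float = 0.10         # pneumatophore height (m)
    pneu_diameter: float = 0.01       # pneumatophore diameter (m)
    pneu_per_stem_coeff: float = 1e4  # pneumatophores per tree = coeff * D(m)^2
    taper_scale: float = 0.5          # density taper above MHW (m)
    removal_mode: str = "seaward"     # "seaward" or "random"
    multi_class: str = "sequential"   # Baptist combination of stem/root classes


class ScenarioConfig(_Strict):
    name: str = "high_forever"
    spinup_years: float = 200.0
    horizon_years: float = 600.0
    cycles_per_season: int = 2        # representative M2 cycles per seasonal burst
    output_epochs: List[float] = Field(
        default_factory=lambda: [200.0, 400.0, 430.0, 450.0, 500.0, 600.0]
    )


class RunConfig(_Strict):
    """Complete, self-contained description of one simulation."""

    grid: GridConfig = Field(default_factory=GridConfig)
    tide: TideConfig = Field(default_factory=TideConfig)
    river: RiverConfig = Field(default_factory=RiverConfig)
    hydro: HydroConfig = Field(default_factory=HydroConfig)
    sediment: SedimentConfig = Field(default_factory=SedimentConfig)
    vegetation: VegetationConfig = Field(default_factory=VegetationConfig)
    scenario: ScenarioConfig = Field(default_factory=ScenarioConfig)
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable digest identifying the run setup (used for safe resume)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
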