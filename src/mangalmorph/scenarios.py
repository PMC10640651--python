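"""Scenario plans: the management-experiment catalogue.

Every plan shares the same backbone: a 200-year sand-only spin-up without
vegetation, a pre-disturbance period with low river mud supply (5 mg/L,
years 200-400) and a disturbance period with high supply (15 mg/L, years
400-500), after which the named management branch applies (mangrove removal,
mud-supply reduction, or continued supply).  Forcing is piecewise constant
per phase and fully reproducible from the plan alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

from .config import RiverConfig, ScenarioConfig


@dataclass(frozen=True)
class Phase:
    start: float                 # year (inclusive)
    end: float                   # year (exclusive)
    mud_mg_l: float              # river mud concentration
    vegetation: bool             # dynamic vegetation active


@dataclass(frozen=True)
class Event:
    year: float
    kind: str                    # "remove_vegetation"
    fraction: float = 1.0        # vegetated-area fraction cleared
    root_persistence_years: float = 0.0


@dataclass(frozen=True)
class ScenarioPlan:
    name: str
    phases: tuple                # ordered, contiguous Phase tuple
    events: tuple = ()
    horizon: float = 600.0
    output_epochs: tuple = (200.0, 400.0, 430.0, 450.0, 500.0, 600.0)

    def __post_init__(self):
        prev_end = 0.0
        for ph in self.phases:
            if abs(ph.start - prev_end) > 1e-9:
                raise ValueError("phases must be contiguous and ordered")
            prev_end = ph.end
        if abs(prev_end - self.horizon) > 1e-9:
            raise ValueError("phase durations must sum to the horizon")
        for ev in self.events:
            if not (0.0 <= ev.year <= self.horizon):
                raise ValueError("event outside the simulated horizon")

    def phase_at(self, year: float) -> Phase:
        for ph in self.phases:
            if ph.start <= year < ph.end:
                return ph
        return self.phases[-1]

    def mud_series(self, years) -> List[float]:
        return [self.phase_at(y).mud_mg_l for y in years]


def _backbone(river: RiverConfig, spinup: float, vegetation: bool = True):
    return [
        Phase(0.0, spinup, 0.0, False),
        Phase(spinup, 400.0, river.mud_low, vegetation),
        Phase(400.0, 500.0, river.mud_high, vegetation),
    ]


def make_scenario(plan_name: str, river: Optional[RiverConfig] = None,
                  scenario_cfg: Optional[ScenarioConfig] = None) -> ScenarioPlan:
    """Build a named plan from the catalogue.

    Catalogue: ``control_low``, ``high_forever``, ``remove_25``, ``remove_50``,
    ``remove_100``, ``reduce_at_430``, ``reduce_at_450``, ``reduce_at_500``,
    ``reduce_intermediate``, ``no_vegetation_control``.
    """
    river = river or RiverConfig()
    cfg = scenario_cfg or ScenarioConfig()
    spinup, horizon = cfg.spinup_years, cfg.horizon_years
    epochs = tuple(cfg.output_epochs)

    def plan(phases, events=()):
        return ScenarioPlan(name=plan_name, phases=tuple(phases),
                            events=tuple(events), horizon=horizon,
                            output_epochs=epochs)

    low, high, mid = river.mud_low, river.mud_high, river.mud_intermediate

    if plan_name == "control_low":
        return plan([Phase(0.0, spinup, 0.0, False),
                     Phase(spinup, horizon, low, True)])
    if plan_name == "high_forever":
        return plan(_backbone(river, spinup) + [Phase(500.0, horizon, high, True)])
    if plan_name in ("remove_25", "remove_50", "remove_100"):
        frac = {"remove_25": 0.25, "remove_50": 0.5, "remove_100": 1.0}[plan_name]
        return plan(_backbone(river, spinup) + [Phase(500.0, horizon, high, True)],
                    events=[Event(500.0, "remove_vegetation", fraction=frac)])
    if plan_name in ("reduce_at_430", "reduce_at_450", "reduce_at_500"):
        yr = float(plan_name.rsplit("_", 1)[1])
        phases = [Phase(0.0, spinup, 0.0, False),
                  Phase(spinup, 400.0, low, True),
                  Phase(400.0, yr, high, True),
                  Phase(yr, horizon, low, True)]
        return plan(phases)
    if plan_name == "reduce_intermediate":
        return plan(_backbone(river, spinup) + [Phase(500.0, horizon, mid, True)])
    if plan_name == "no_vegetation_control":
        phases = [replace(ph, vegetation=False)
                  for ph in _backbone(river, spinup, vegetation=False)]
        return plan(phases + [Phase(500.0, horizon, high, False)])
    raise KeyError(f"unknown scenario plan: {plan_name!r}")


CATALOGUE = ("control_low", "high_forever", "remove_25", "remove_50",
             "remove_100", "reduce_at_430", "reduce_at_450", "reduce_at_500",
             "reduce_intermediate", "no_vegetation_control")
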