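"""Dynamic mangrove vegetation (*Avicennia marina*).

The life cycle runs on a seasonal clock (four updates per morphological
year): colonization at the first season of the ecological year, diameter
growth every season, and mortality (growth-suppression bookkeeping plus
self-thinning) at the last.  One cohort occupies a cell at a time — a cell
only accepts seedlings while unvegetated, and becomes recolonizable the
ecological year after it is cleared.

Growth couples back to the flow through two roughness object classes per
cell: tree stems (height from the allometric relation, diameter from the
growth law) and pneumatophores (fixed 10 cm height, count scaling with tree
size).  The fitness curve f(hydroperiod) and the competition curve
C(biomass) are documented, swappable lineage defaults, not field-calibrated
forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import VegetationConfig


@dataclass
class VegetationState:
    """Per-cell mangrove cohort plus residual-root bookkeeping."""

    stems: np.ndarray        # stems per cell (0 = unvegetated)
    d_cm: np.ndarray         # stem diameter (cm)
    age: np.ndarray          # cohort age (yr)
    supp: np.ndarray         # consecutive years with f*C below viability
    pneu_m: np.ndarray       # residual pneumatophore count per m2 (post-removal)
    pneu_timer: np.ndarray   # years the residual roots persist
    colonize_block: np.ndarray  # cleared this year; reopens next ecological year

    @classmethod
    def empty(cls, ny, nx):
        return cls(stems=np.zeros((ny, nx)), d_cm=np.zeros((ny, nx)),
                   age=np.zeros((ny, nx)), supp=np.zeros((ny, nx), dtype=np.int32),
                   pneu_m=np.zeros((ny, nx)), pneu_timer=np.zeros((ny, nx)),
                   colonize_block=np.zeros((ny, nx), dtype=bool))

    def copy(self) -> "VegetationState":
        return VegetationState(*(a.copy() for a in
                                 (self.stems, self.d_cm, self.age, self.supp,
                                  self.pneu_m, self.pneu_timer,
                                  self.colonize_block)))

    @property
    def mask(self) -> np.ndarray:
        return self.stems > 0

    def clear_cells(self, sel):
        self.stems[sel] = 0.0
        self.d_cm[sel] = 0.0
        self.age[sel] = 0.0
        self.supp[sel] = 0


def tree_height(d_cm, cfg: VegetationConfig | None = None):
    """Quadratic allometry H = 137 + b2 D - b3 D^2 (cm; D in cm)."""
    p = cfg or VegetationConfig()
    d = np.asarray(d_cm, dtype=float)
    h = 137.0 + p.b2 * d - p.b3 * d**2
    return h if h.ndim else float(h)


def fitness(hydroperiod, cfg: VegetationConfig | None = None):
    """Inundation fitness f in [0, 1].

    Zero outside the (0, 0.5] inundation band (too dry above mean high
    water, too wet below mean sea level); rises linearly to its optimum over
    ``fitness_ramp`` at the dry end.
    """
    p = cfg or VegetationConfig()
    hp = np.asarray(hydroperiod, dtype=float)
    f = np.clip(hp / p.fitness_ramp, 0.0, 1.0)
    f = np.where((hp <= p.hp_min) | (hp > p.hp_max), 0.0, f)
    return f if f.ndim else float(f)


def stem_biomass(d_cm, cfg: VegetationConfig | None = None):
    """Above-ground biomass per stem (kg), power-law in diameter (cm)."""
    p = cfg or VegetationConfig()
    d = np.asarray(d_cm, dtype=float)
    return p.biomass_a * d**p.biomass_b


def competition(biomass_per_m2, cfg: VegetationConfig | None = None):
    """Resource-competition factor C in [0, 1]: 1 for an empty cell and
    decaying toward 0 as standing biomass grows."""
    p = cfg or VegetationConfig()
    b = np.asarray(biomass_per_m2, dtype=float)
    c = p.biomass_half / (p.biomass_half + b)
    return c if c.ndim else float(c)


def compute_stress(veg: VegetationState, hydroperiod, cell_area,
                   cfg: VegetationConfig | None = None):
    """Fitness and competition fields for the current season."""
    p = cfg or VegetationConfig()
    f = fitness(hydroperiod, p)
    biomass = veg.stems * stem_biomass(veg.d_cm, p) / cell_area
    c = competition(biomass, p)
    return f, c


def attempt_colonization(veg: VegetationState, hydroperiod, tau_stat,
                         eligible_mask, cell_area,
                         cfg: VegetationConfig | None = None) -> np.ndarray:
    """Seed every unvegetated eligible cell at the initial density.

    Eligibility: relative hydroperiod inside (0, 0.5], bed shear stress
    statistic below 0.2 N/m2, and viable growth (f * C > 0.5 with C = 1 for
    an empty cell).  Returns the mask of newly colonized cells.
    """
    p = cfg or VegetationConfig()
    hp = np.asarray(hydroperiod, dtype=float)
    tau = np.asarray(tau_stat, dtype=float)
    f = fitness(hp, p)
    new = (eligible_mask & (~veg.mask) & (~veg.colonize_block)
           & (hp > p.hp_min) & (hp <= p.hp_max)
           & (tau < p.tau_settle)
           & (f * 1.0 > p.viability))
    density = p.seedling_density_ha / 1e4  # stems per m2
    veg.stems[new] = density * cell_area
    veg.d_cm[new] = p.seedling_diameter
    veg.age[new] = 0.0
    veg.supp[new] = 0
    return new


def grow_cohorts(veg: VegetationState, f, c, dt_yr=0.25,
                 cfg: VegetationConfig | None = None) -> None:
    """Advance stem diameters one season with the logistic-like growth law.

    dD/dt = G D (1 - D H / (Dmax Hmax)) / (274 + 3 b2 D - 4 b3 D^2) * f * C
    (cm/yr); height follows the allometry, so growth stalls exactly when
    D H reaches Dmax Hmax.  Diameters never shrink and are capped at Dmax.
    """
    p = cfg or VegetationConfig()
    m = veg.mask
    if not m.any():
        return
    d = veg.d_cm[m]
    h = 137.0 + p.b2 * d - p.b3 * d**2
    bracket = 1.0 - d * h / (p.d_max * p.h_max)
    denom = 274.0 + 3.0 * p.b2 * d - 4.0 * p.b3 * d**2
    rate = np.maximum(p.growth_g * d * bracket / denom, 0.0)
    fc = (np.asarray(f, dtype=float) * np.asarray(c, dtype=float))[m]
    d_new = np.minimum(d + rate * fc * dt_yr, p.d_max)
    veg.d_cm[m] = d_new
    veg.age[m] += dt_yr


def thinning_target(f, d_cm, cell_area, cfg: VegetationConfig | None = None):
    """Largest stem count at which suppressed growth terminates (f*C >= 0.5).

    Returns 0 when no count can satisfy viability (f too low).
    """
    p = cfg or VegetationConfig()
    if f * 1.0 < p.viability:  # even an empty cell would be suppressed
        return 0.0
    c_req = p.viability / f
    b_allowed = p.biomass_half * (1.0 - c_req) / c_req  # kg/m2
    per_stem = stem_biomass(d_cm, p)
    if per_stem <= 0:
        return np.inf
    return np.floor(b_allowed * cell_area / per_stem)


def apply_mortality(veg: VegetationState, f, c, cell_area,
                    cfg: VegetationConfig | None = None) -> None:
    """End-of-year suppression bookkeeping and self-thinning.

    Cohorts with f*C below the viability product extend their suppression
    streak (a single good year resets it).  A streak reaching the configured
    number of consecutive years triggers self-thinning: stems are removed
    until the suppression lifts, or the cell empties.
    """
    p = cfg or VegetationConfig()
    m = veg.mask
    fc = np.asarray(f, dtype=float) * np.asarray(c, dtype=float)
    suppressed = m & (fc < p.viability)
    veg.supp[m & ~suppressed] = 0
    veg.supp[suppressed] += 1
    trigger = suppressed & (veg.supp >= p.suppression_years)
    if not trigger.any():
        return
    jj, ii = np.nonzero(trigger)
    fa = np.asarray(f, dtype=float)
    for j, i in zip(jj, ii):
        target = thinning_target(fa[j, i], veg.d_cm[j, i], cell_area, p)
        veg.stems[j, i] = min(veg.stems[j, i], target)
        veg.supp[j, i] = 0
    gone = trigger & (veg.stems <= 0)
    veg.clear_cells(gone)


def elevation_taper(veg: VegetationState, z, z_mhw,
                    cfg: VegetationConfig | None = None) -> None:
    """Reduce stem density linearly where the bed has accreted above mean
    high water (the upper elevation limit of the species)."""
    p = cfg or VegetationConfig()
    over = veg.mask & (np.asarray(z) > z_mhw)
    if not over.any():
        return
    factor = np.clip(1.0 - (np.asarray(z) - z_mhw) / p.taper_scale, 0.0, 1.0)
    veg.stems[over] *= factor[over]
    veg.clear_cells(veg.stems <= 1e-9)


def pneumatophore_density(veg: VegetationState, cell_area,
                          cfg: VegetationConfig | None = None):
    """Pneumatophore count per m2: live trees contribute in proportion to
    stem basal dimension; residual (post-removal) roots add while their
    persistence timer runs."""
    p = cfg or VegetationConfig()
    d_m = veg.d_cm / 100.0
    live = veg.stems * p.pneu_per_stem_coeff * d_m**2 / cell_area
    residual = np.where(veg.pneu_timer > 0, veg.pneu_m, 0.0)
    return live + residual


def remove_mangroves(veg: VegetationState, fraction, cell_area,
                     cfg: VegetationConfig | None = None,
                     root_persistence_years=0.0, rng=None) -> int:
    """Clear a fraction of the vegetated area (a management intervention).

    The default selection clears contiguous vegetated area seaward-first;
    the alternative mode picks cells uniformly at random with an explicit
    generator.  With a positive root persistence the cleared cells keep
    their pneumatophore roughness for that many years; stems vanish at once.
    Returns the number of cells cleared.
    """
    p = cfg or VegetationConfig()
    if not (0.0 < fraction <= 1.0):
        raise ValueError("removal fraction must lie in (0, 1]")
    jj, ii = np.nonzero(veg.mask)
    ncells = len(jj)
    if ncells == 0:
        return 0
    k = int(round(fraction * ncells))
    if p.removal_mode == "random":
        rng = rng or np.random.default_rng()
        sel = rng.choice(ncells, size=k, replace=False)
    else:  # seaward-first: smallest x (i) first, then y for determinism
        order = np.lexsort((jj, ii))
        sel = order[:k]
    js, is_ = jj[sel], ii[sel]
    if root_persistence_years > 0:
        pn = pneumatophore_density(veg, cell_area, p)
        veg.pneu_m[js, is_] = pn[js, is_]
        veg.pneu_timer[js, is_] = root_persistence_years
    else:
        veg.pneu_m[js, is_] = 0.0
        veg.pneu_timer[js, is_] = 0.0
    sel_mask = np.zeros(veg.stems.shape, dtype=bool)
    sel_mask[js, is_] = True
    veg.clear_cells(sel_mask)
    veg.colonize_block[sel_mask] = True  # recolonizable next ecological year
    return k


def tick_root_persistence(veg: VegetationState, dt_yr=1.0) -> None:
    """Annual housekeeping: advance the residual-root decomposition clock
    and reopen cells cleared earlier this ecological year."""
    veg.colonize_block[:] = False
    active = veg.pneu_timer > 0
    veg.pneu_timer[active] -= dt_yr
    expired = active & (veg.pneu_timer <= 0)
    veg.pneu_m[expired] = 0.0
    veg.pneu_timer[expired] = 0.0


def to_roughness_summary(veg: VegetationState, cell_area,
                         cfg: VegetationConfig | None = None):
    """Map cohorts to the two roughness object classes consumed by the flow.

    Returns ``(hv1, n1, hv2, n2)``: pneumatophores (class 1, fixed height)
    and stems (class 2, allometric height), each with vegetation density
    n = m D (m/m2).
    """
    p = cfg or VegetationConfig()
    ny, nx = veg.stems.shape
    m_pneu = pneumatophore_density(veg, cell_area, p)
    n1 = m_pneu * p.pneu_diameter
    hv1 = np.where(m_pneu > 0, p.pneu_height, 0.0)
    m_stem = veg.stems / cell_area
    d_m = veg.d_cm / 100.0
    n2 = m_stem * d_m
    h_m = np.maximum(tree_height(veg.d_cm, p), 0.0) / 100.0
    hv2 = np.where(veg.mask, h_m, 0.0)
    return hv1, n1, hv2, np.where(veg.mask, n2, 0.0)
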