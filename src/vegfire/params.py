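"""Model parameters and run configuration.

Every tunable in the model lives in one of the frozen-ish dataclasses below so
that a run is fully determined by (parameter set, climate inputs, seed).  The
defaults encode the calibration of the model to a ponderosa-pine / mixed-grass
ecotone: a drought-tolerant, shade-intolerant evergreen needleleaf tree type
competing with C3/C4 grasses under surface fire.

Units are stated per field.  Carbon pools are g C m^-2 throughout; monthly
fluxes g C m^-2 month^-1; lengths m unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

__all__ = [
    "ProductionParams",
    "AllocationParams",
    "DecompositionParams",
    "SoilParams",
    "AllometryParams",
    "BiogeographyParams",
    "FireParams",
    "ModelParams",
    "SyntheticConfig",
    "DroughtEpisode",
    "ScenarioConfig",
    "TRAJECTORY_STYLES",
    "FIRE_MODES",
]

TRAJECTORY_STYLES = ("wetter-warm", "hot-flat-precip", "hottest-driest")
FIRE_MODES = ("natural", "suppression", "prescribed", "none")


@dataclass
class ProductionParams:
    """Production scalars and maximum rates for trees and grasses."""

    #: Maximum tree NPP in the peak month, g C m^-2 month^-1.  This is the
    #: calibrated value produced by :func:`vegfire.simulator.calibrate_max_tree_npp`
    #: against the old-forest aboveground carbon target (7500-9000 g C m^-2).
    max_tree_npp: float = 172.0
    #: Maximum grass shoot+root NPP in the peak month, g C m^-2 month^-1.
    max_grass_npp: float = 55.0

    # Temperature response: Gaussian around an optimum, hard zero below frost.
    tree_t_opt: float = 18.0  # deg C
    tree_t_width: float = 12.0
    grass_t_opt: float = 22.0
    grass_t_width: float = 13.0
    frost_cutoff: float = 0.0  # deg C, no production below

    # Water response: scalar = clip(ratio / sat_ratio, 0, 1) ** exponent where
    # ratio = (precip + plant-available soil water) / PET.  The tree exponent
    # < 1 makes the tree curve the less steep (more drought tolerant) one.
    water_sat_ratio: float = 1.0
    tree_water_exp: float = 0.7
    grass_water_exp: float = 1.3
    water_floor: float = 0.0

    # CO2 response (logarithmic): production x(1 + beta_p*log2(C/Cref)),
    # transpiration x(1 - beta_t*log2(C/Cref)) floored at transp_floor.
    co2_ref: float = 350.0  # ppm
    co2_prod_beta: float = 0.15
    co2_transp_beta: float = 0.25
    co2_transp_floor: float = 0.25

    # Tree light interception: a Beer-law saturating function of own LAI
    # raised to light_power.  The exponent > 1 makes sparse seedling
    # canopies capture disproportionately little light (establishment
    # bottleneck under grass competition), which slows post-fire tree
    # recovery where fires are frequent; the floor is zero by default.
    light_k: float = 0.8
    light_power: float = 1.25
    light_floor: float = 0.0

    # Grass shading by tree LAI and standing dead grass.
    shade_k_lai: float = 0.45        # per unit tree LAI
    shade_k_dead: float = 0.0010     # per g C m^-2 standing dead

    #: Grass competition against tree regeneration: tree production is
    #: multiplied by exp(-k * grass root C * open-canopy fraction), so
    #: established canopies are unaffected but seedlings facing an intact
    #: grass sod are strongly suppressed (roots survive fire).
    grass_competition_k: float = 0.012  # per g C m^-2 root


@dataclass
class AllocationParams:
    """NPP allocation fractions and live-pool turnover rates (per month)."""

    # Tree allocation fractions; must sum to 1.
    tree_alloc: dict = field(default_factory=lambda: {
        "leaf": 0.25, "fine_branch": 0.15, "large_wood": 0.35,
        "fine_root": 0.15, "coarse_root": 0.10,
    })
    # Grass allocation fractions; must sum to 1.  "shoot" is aboveground.
    grass_alloc: dict = field(default_factory=lambda: {"shoot": 0.60, "root": 0.40})

    # Live turnover, fraction per month.
    tree_turnover: dict = field(default_factory=lambda: {
        "leaf": 0.025, "fine_branch": 0.004, "large_wood": 0.0017,
        "fine_root": 0.03, "coarse_root": 0.004,
    })
    grass_turnover: dict = field(default_factory=lambda: {"shoot": 0.08, "root": 0.04})
    #: Standing dead grass falls to 1-h surface litter at this rate, per month.
    standing_dead_fall: float = 0.10
    #: Fraction of leaf turnover routed to 1-h litter (rest to 10-h).
    leaf_to_1h: float = 0.7


@dataclass
class DecompositionParams:
    """First-order decay of dead and soil pools with T/moisture modifiers."""

    # Base rates at 20 deg C and moist soil, fraction per month.
    base_rates: dict = field(default_factory=lambda: {
        "litter_1h": 0.040, "litter_10h": 0.015, "litter_100h": 0.006,
        "litter_1000h": 0.004,
        "soil_active": 0.02, "soil_slow": 0.004, "soil_passive": 0.001,
    })
    #: Fraction of decayed C respired to the atmosphere; the rest moves one
    #: step down the chain (litter -> active -> slow -> passive).
    respired_fraction: float = 0.55
    #: Per-pool overrides: only a small fraction of decayed slow C is
    #: stabilized into the passive pool; passive decay is fully respired.
    respired_overrides: dict = field(default_factory=lambda: {"soil_slow": 0.90})
    q10: float = 2.0
    t_ref: float = 20.0  # deg C
    #: Moisture factor = clip(moisture ratio / this, 0, 1), where the
    #: moisture ratio is monthly available water over PET (same driver as
    #: the production water scalar).
    moisture_half: float = 0.8


@dataclass
class SoilParams:
    """Two-bucket soil water model derived from depth and texture."""

    depth_cm: float = 100.0
    layer1_depth_cm: float = 30.0
    #: Plant-available water capacity per cm of soil (cm water / cm soil);
    #: a pedotransfer default for silt loam.
    awc_per_cm: float = 0.13
    #: Fraction of PET expressed as transpiration+evaporation demand.
    demand_factor: float = 0.8


@dataclass
class AllometryParams:
    """Average-tree geometry from carbon pools (power-law forms)."""

    height_a: float = 0.25   # m per (g C m^-2)^height_b
    height_b: float = 0.45
    #: Crown ratio declines from young to old stands; CBH = height*(1-cr).
    crown_ratio_young: float = 0.9
    crown_ratio_old: float = 0.4
    crown_ratio_height_scale: float = 14.0  # m; height at which cr -> old value
    bark_c: float = 0.15     # cm bark per m height
    #: LAI = lai_max * (1 - exp(-lai_k * leaf C)); asymptote is half the
    #: generic model default of 5 (shade-intolerant, open-canopy pine).
    lai_max: float = 2.5
    lai_k: float = 0.0075    # per g C m^-2 leaf


@dataclass
class BiogeographyParams:
    """Lifeform-mix thresholds and vegetation-class carbon boundaries."""

    # Pure-type corners in (min temperature of coldest month degC,
    # growing-season precipitation cm) space.
    evergreen_corner: tuple = (-15.0, 20.0)
    deciduous_corner: tuple = (0.0, 40.0)
    #: C3/C4 grass split: C4 fraction ramps with growing-season mean T.
    c4_t_lo: float = 12.0
    c4_t_hi: float = 22.0

    # Live aboveground tree C class boundaries, g C m^-2.
    forest_min: float = 3000.0
    woodland_min: float = 1150.0
    shrubland_min: float = 80.0

    #: Exponential smoothing e-folding time for biogeography climate, years.
    smoothing_efold_years: float = 10.0

    #: Aridity-index (annual precipitation / annual PET) ramp for the
    #: equilibrium phase's initial vegetation type: pure grassland below
    #: the low bound, young woodland above the high bound.
    init_aridity_lo: float = 0.37
    init_aridity_hi: float = 0.43


@dataclass
class FireParams:
    """Fire danger, behavior, effects, and management-policy parameters."""

    # Ignition gates (Canadian FWI system codes).
    ffmc_threshold: float = 90.4
    bui_threshold: float = 80.0

    # FWI spring startup values; codes reset each calendar year on the first
    # month with mean temperature above the snow-free cutoff.
    ffmc_start: float = 85.0
    dmc_start: float = 6.0
    dc_start: float = 15.0
    snow_free_tmean: float = 0.0  # deg C

    # Realized mean wind speeds by vegetation class, m s^-1.
    wind_grass: float = 6.0
    wind_forest: float = 3.0

    # Fuel bed.
    c_to_dry_matter: float = 2.0          # g DM per g C
    mx_dead_grass: float = 0.30           # moisture of extinction, fraction
    mx_dead_forest: float = 0.25
    mx_live: float = 3.0
    live_fuel_moisture: float = 1.0       # fraction (100%)
    heat_yield_kj_kg: float = 18600.0
    fuel_depth_grass_m: float = 0.35
    fuel_depth_forest_m: float = 0.04
    #: Surface-area-to-volume ratios by class, m^-1.
    sav: dict = field(default_factory=lambda: {
        "1h_grass": 9000.0, "1h_forest": 6000.0, "10h": 360.0,
        "100h": 98.0, "live": 7200.0,
    })
    particle_density_kg_m3: float = 513.0
    mineral_content: float = 0.0555
    effective_mineral: float = 0.010
    residence_time_s: float = 60.0        # for energy release per area

    # Crown fire and mortality.
    foliar_moisture_pct: float = 100.0
    scorch_coef: float = 0.1483           # m per (kW m^-1)^(2/3)
    scorch_exp: float = 2.0 / 3.0
    mortality_logistic_scale: float = 0.8  # m, on (scorch - CBH)
    bark_survival_scale_cm: float = 3.0

    # Dead fuel consumption fractions by class in a burn.
    consumption: dict = field(default_factory=lambda: {
        "litter_1h": 0.90, "litter_10h": 0.70, "litter_100h": 0.40,
        "litter_1000h": 0.15,
    })
    grass_shoot_consumption: float = 0.90
    #: Fraction of fire-killed leaf/fine material emitted immediately.
    killed_fine_emission: float = 0.50

    # Burn fraction ramp: fraction = min(years_since_fire / ramp_years, 1).
    burn_fraction_ramp_years: float = 10.0

    # Suppression policy: unscaled severity thresholds and the scaling factor.
    ros_threshold_m_s: float = 0.51
    fli_threshold_kw_m: float = 3100.0
    erc_threshold_kw_m2: float = 680.0
    suppression_scale: float = 0.45
    #: A fire escapes suppression when "all" (default) or "any" of the three
    #: severity metrics exceed the scaled thresholds.  With the fuel beds and
    #: winds simulated here, surface fires are slow but intense, so the
    #: "any" rule would let every fire escape through the intensity gate;
    #: "all" yields the intended policy: routine fires are contained and
    #: only fires severe in every dimension escape.
    escape_rule: Literal["any", "all"] = "all"

    # Prescribed-fire policy.
    prescribed_start_year: int = 2001
    prescribed_interval_years: int = 11
    prescribed_month: int = 9
    prescribed_day: int = 15
    prescribed_tree_mortality: float = 0.20

    # Equilibrium-phase fixed fire return intervals, years.
    fri_grassland: int = 10
    fri_wooded: int = 30


@dataclass
class ModelParams:
    """Bundle of all process-parameter groups."""

    production: ProductionParams = field(default_factory=ProductionParams)
    allocation: AllocationParams = field(default_factory=AllocationParams)
    decomposition: DecompositionParams = field(default_factory=DecompositionParams)
    soil: SoilParams = field(default_factory=SoilParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    biogeography: BiogeographyParams = field(default_factory=BiogeographyParams)
    fire: FireParams = field(default_factory=FireParams)

    def copy(self) -> "ModelParams":
        return replace(
            self,
            production=replace(self.production),
            allocation=replace(self.allocation),
            decomposition=replace(self.decomposition),
            soil=replace(self.soil),
            allometry=replace(self.allometry),
            biogeography=replace(self.biogeography),
            fire=replace(self.fire),
        )


@dataclass
class DroughtEpisode:
    """A scheduled multi-year drought (1930s / 1950s analogues)."""

    start_year: int
    length_years: int
    precip_multiplier: float
    temp_offset: float  # deg C


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic climate/soil generator.

    The defaults emulate the study setting: ~48 cm yr^-1 mean annual
    precipitation with half falling May-July, a NW (cool/wet) to SE (warm/dry)
    gradient spanning the ecotone boundary values (7.6 degC / 48.5 cm), and
    severe droughts in the 1930s- and 1950s-analogue decades.
    """

    nx: int = 12
    ny: int = 12
    year_start: int = 1895
    year_end: int = 2008

    # Gradient endpoints (NW corner, SE corner).
    tmean_nw: float = 6.0    # deg C mean annual temperature
    tmean_se: float = 9.2
    ppt_nw: float = 58.0     # cm yr^-1 mean annual precipitation
    ppt_se: float = 38.0

    may_jul_fraction: float = 0.5
    seasonal_t_amplitude: float = 15.0  # deg C, Jan-Jul half-range
    diurnal_range_winter: float = 11.0  # tmax - tmin, deg C
    diurnal_range_summer: float = 16.0

    # Seasonal relative-humidity targets used to generate vapor pressure.
    rh_winter: float = 0.72
    rh_summer: float = 0.52

    # Interannual variability.
    precip_lognorm_sigma: float = 0.18
    precip_month_sigma: float = 0.25
    temp_ar1_sd: float = 0.7
    temp_ar1_rho: float = 0.5
    #: Vapor pressure responds to precipitation anomalies: annual multiplier
    #: = precip multiplier ** this exponent (dry years are also low-humidity).
    vpr_precip_exp: float = 0.35

    droughts: Sequence[DroughtEpisode] = field(default_factory=lambda: (
        DroughtEpisode(1933, 6, 0.55, 1.2),
        DroughtEpisode(1953, 5, 0.60, 1.2),
    ))

    # Soils (uniform by default).
    soil_depth_cm: float = 100.0
    soil_awc_per_cm: float = 0.13
    soil_bulk_density: float = 1.3  # g cm^-3, metadata

    # Future anomaly generation.
    future_year_start: int = 2001
    future_year_end: int = 2100
    anomaly_noise_sd: float = 1.0   # month-scale temperature anomaly sd, degC
    #: Lognormal sd of single-month precipitation anomaly ratios (GCM
    #: monthly anomalies are individually erratic).
    anomaly_month_precip_sigma: float = 0.45

    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not (0.0 < self.may_jul_fraction < 1.0):
            raise ValueError("may_jul_fraction must lie in (0, 1)")
        if self.precip_lognorm_sigma < 0:
            raise ValueError("precip_lognorm_sigma must be >= 0")


@dataclass
class ScenarioConfig:
    """One simulation scenario: phases, fire management, CO2, climate source."""

    fire_mode: Literal["natural", "suppression", "prescribed", "none"] = "natural"
    trajectory_style: str | None = None     # for the future phase
    co2_effects: bool = True
    evergreen_constraint: bool = True
    grazing: bool = True

    equilibrium_max_years: int = 3000
    #: Passive-pool convergence tolerance per century, g C m^-2.
    equilibrium_tol: float = 1.0
    spinup_cycles: int = 10                 # x historical length = 1140 yr
    suppression_start_year: int = 1941
    #: |mean NBP| over the final spinup cycle for quasi-equilibrium,
    #: g C m^-2 yr^-1.
    nbp_tolerance: float = 1.0

    co2_ppm_1895: float = 294.0
    co2_ppm_2000: float = 370.0
    co2_ppm_2100: float = 856.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.fire_mode not in FIRE_MODES:
            raise ValueError(f"unknown fire mode {self.fire_mode!r}")
        if self.trajectory_style is not None and self.trajectory_style not in TRAJECTORY_STYLES:
            raise ValueError(f"unknown trajectory style {self.trajectory_style!r}")
        if self.equilibrium_max_years <= 0 or self.spinup_cycles <= 0:
            raise ValueError("phase lengths must be positive")
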