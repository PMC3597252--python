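"""Synthetic monitoring-style data with known ground truth.

Emulates a northern-Baltic coastal monitoring programme: three basins of
very different size and riverine influence, a 13-year record with 13-26
research-vessel samplings per basin-year, daily river gauge flows with a
spring-flood peak and a multi-year high-discharge pulse, monthly riverine
TOC/TN/TP concentrations coupled to flow, and station measurements
(photosynthesis-irradiance incubations, light profiles, thymidine uptake,
cell volumes, phytoplankton biomass) generated from a known
photosynthetic seasonality and a known exponential trophic-balance
response ratio = a * exp(b * lagged specific TOC load).

Because every stage downstream of the generator is the same code a real
campaign would use, parameter-recovery tests can compare fitted values
against the generating truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bacterial_production import ConversionConstants, carbon_per_cell
from .primary_production import (
    DEFAULT_REFLECTION_TRANSMITTANCE,
    PRODUCTION_DEPTH_CAP,
    LightField,
    PICurve,
    daily_fixation_incubator,
    diel_surface_irradiance,
    integrate_depth,
    seasonal_shape,
)

__all__ = [
    "BasinConfig",
    "GroundTruth",
    "RiverData",
    "CampaignData",
    "default_basins",
    "simulate_river",
    "simulate_station_year",
    "simulate_campaign",
    "hourly_surface_irradiance",
    "seasonal_p_max",
]

#: Baseline monthly concentrations at reference flow, mg L^-1; humic-rich
#: boreal river water (high TOC, low P).
CONC_BASE = {"toc": 5.0, "tn": 0.30, "tp": 0.020}
#: Power-law concentration-discharge exponents; TOC and TN are mobilized
#: with flow, TP is roughly chemostatic.
CONC_GAMMA = {"toc": 0.6, "tn": 0.5, "tp": 0.0}
#: Monthly lognormal concentration noise (CV).
CONC_CV = {"toc": 0.05, "tn": 0.05, "tp": 0.30}
#: Extra per-year lognormal variability of TP concentration, decoupling
#: the P load from flow (weaker load-flow R^2 than for C and N).
TP_YEAR_CV = 0.20

#: Reference specific TOC load scale (g C m^-2 yr^-1) for the optical
#: coupling of attenuation to the current year's load.
ATTENUATION_LOAD_REF = 10.0
ATTENUATION_LOAD_SENSITIVITY = 0.4

#: Mean bacterial cell volume written to station records, um^3.
MEAN_CELL_VOLUME = 0.08

PI_IRRADIANCE_LEVELS = (10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1500.0)

STATION_COLUMNS = [
    "date",
    "station",
    "basin",
    "depth_m",
    "irradiance_umol_m2_s",
    "c14_uptake_mgC_m3_h",
    "tdr_uptake_mol_m3_h",
    "cell_volume_um3",
    "biomass_mgC_m3",
]


@dataclass(frozen=True)
class BasinConfig:
    """Morphometry and riverine reference levels of one receiving basin."""

    name: str
    area_km2: float
    volume_km3: float
    mean_depth_m: float
    export_fraction: float = 0.0
    mean_flow_km3_yr: float = 0.0  # reference scenario level
    mean_toc_load_kg_yr: float = 0.0  # reference scenario level

    def __post_init__(self) -> None:
        if self.area_km2 <= 0 or self.volume_km3 <= 0 or self.mean_depth_m <= 0:
            raise ValueError("basin morphometry must be positive")
        if not 0 <= self.export_fraction < 1:
            raise ValueError("export_fraction must be in [0, 1)")
        # Reported mean depths are independent survey values and disagree
        # slightly with volume/area; tolerate a factor-of-2 band only.
        implied = self.volume_km3 / self.area_km2 * 1000.0
        if not 0.5 <= self.mean_depth_m / implied <= 2.0:
            raise ValueError(
                f"mean_depth {self.mean_depth_m} m inconsistent with "
                f"volume/area = {implied:.1f} m"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters the recovery tests estimate.

    true_a, true_b : exponential trophic-balance response coefficients
        (ratio = true_a * exp(true_b * specific TOC load)); true_b in
        (g C)^-1 m^2 yr.
    true_lag : years between riverine load and the full Pb:Pp response.
    true_pmax_winter/summer : seasonal envelope of the photosynthetic
        maximum, mg C m^-3 h^-1.
    true_alpha : P-I initial slope, mg C m^-3 h^-1 per (umol m^-2 s^-1).
    true_attenuation_base : clear-water attenuation coefficient, m^-1.
    pulse_years / pulse_multiplier : high-discharge episode.
    noise_cv : multiplicative lognormal CV applied to rate measurements.
    """

    true_a: float = 0.5
    true_b: float = 0.09
    true_lag: int = 2
    true_pmax_winter: float = 0.4
    true_pmax_summer: float = 5.0
    true_alpha: float = 0.05
    true_attenuation_base: float = 0.25
    pulse_years: tuple = tuple(range(1998, 2002))
    pulse_multiplier: float = 1.5
    flow_year_cv: float = 0.15
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_lag < 0:
            raise ValueError("true_lag must be >= 0")
        if self.pulse_multiplier < 1:
            raise ValueError("pulse_multiplier must be >= 1")
        for name in ("true_a", "true_b", "true_pmax_winter", "true_pmax_summer",
                     "true_alpha", "true_attenuation_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class RiverData:
    """Simulated river record for one basin."""

    basin: str
    daily_flow: pd.Series  # m^3 s^-1, daily DatetimeIndex
    monthly_concentration: pd.DataFrame  # index (year, month); toc/tn/tp mg L^-1


def default_basins() -> list[BasinConfig]:
    """The three reference basins: large bay, small estuary, large sea basin."""
    return [
        BasinConfig(
            name="Bothnian Bay", area_km2=36_800.0, volume_km3=1490.0,
            mean_depth_m=43.0, export_fraction=0.0,
            mean_flow_km3_yr=52.0, mean_toc_load_kg_yr=329e6,
        ),
        BasinConfig(
            name="Ore estuary", area_km2=50.0, volume_km3=1.0,
            mean_depth_m=16.0, export_fraction=0.9,
            mean_flow_km3_yr=0.85, mean_toc_load_kg_yr=12e6,
        ),
        BasinConfig(
            name="Bothnian Sea", area_km2=66_000.0, volume_km3=4340.0,
            mean_depth_m=68.0, export_fraction=0.0,
            mean_flow_km3_yr=68.0, mean_toc_load_kg_yr=483e6,
        ),
    ]


def derive_seed(master: int, *parts) -> int:
    """Deterministic sub-seed from a master seed and string/number labels."""
    label = ":".join([str(master), *map(str, parts)])
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def _flow_template(doy: np.ndarray) -> np.ndarray:
    """Seasonal daily-flow shape: baseflow + spring-melt peak + autumn rains."""
    spring = 2.6 * np.exp(-0.5 * ((doy - 135.0) / 28.0) ** 2)
    autumn = 0.35 * np.exp(-0.5 * ((doy - 280.0) / 45.0) ** 2)
    return 0.55 + spring + autumn


_TEMPLATE_MEAN = float(np.mean(_flow_template(np.arange(1, 366, dtype=float))))


def simulate_river(
    years: Sequence[int], basin: BasinConfig, truth: GroundTruth
) -> RiverData:
    """Daily flow plus monthly TOC/TN/TP concentrations for the basin.

    Daily flow = seasonal template x interannual lognormal factor x pulse
    multiplier in pulse years x short-scale noise, scaled to the basin's
    reference mean annual flow. Concentrations follow power-law
    concentration-discharge coupling (strong for TOC/TN, chemostatic plus
    extra year-level noise for TP). Deterministic given the truth seed.
    """
    years = sorted(int(y) for y in years)
    if len(years) < 2:
        raise ValueError("need >= 2 years of river record")
    rng = np.random.default_rng(derive_seed(truth.seed, basin.name, "river"))
    mean_flow_m3s = basin.mean_flow_km3_yr * 1e9 / (365.0 * 86_400.0)

    flows = []
    index = []
    monthly_rows = []
    sigma = truth.flow_year_cv
    for year in years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = days.dayofyear.to_numpy(dtype=float)
        year_factor = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma)
        if year in truth.pulse_years:
            year_factor *= truth.pulse_multiplier
        daily_noise = rng.lognormal(mean=-0.005, sigma=0.1, size=len(days))
        flow = (
            mean_flow_m3s
            * _flow_template(doy) / _TEMPLATE_MEAN
            * year_factor
            * daily_noise
        )
        flows.append(flow)
        index.append(days)

        tp_year_factor = rng.lognormal(
            mean=-(TP_YEAR_CV**2) / 2.0, sigma=TP_YEAR_CV
        )
        fs = pd.Series(flow, index=days)
        for month in range(1, 13):
            month_flow = float(fs[fs.index.month == month].mean())
            rel = month_flow / mean_flow_m3s
            row = {"year": year, "month": month}
            for const in ("toc", "tn", "tp"):
                cv = CONC_CV[const]
                conc = (
                    CONC_BASE[const]
                    * rel ** CONC_GAMMA[const]
                    * rng.lognormal(mean=-(cv**2) / 2.0, sigma=cv)
                )
                if const == "tp":
                    conc *= tp_year_factor
                row[const] = conc
            monthly_rows.append(row)

    daily = pd.Series(
        np.concatenate(flows), index=index[0].append(index[1:]), name="flow_m3_s"
    )
    monthly = pd.DataFrame(monthly_rows).set_index(["year", "month"])
    return RiverData(basin=basin.name, daily_flow=daily, monthly_concentration=monthly)


def _noon_irradiance(doy: float) -> float:
    return 120.0 + 1380.0 * seasonal_shape(doy)


def hourly_surface_irradiance(doy: float) -> np.ndarray:
    """24 hourly mean surface irradiances (umol m^-2 s^-1) for a day of year."""
    return diel_surface_irradiance(doy, _noon_irradiance(doy))


def seasonal_p_max(doy: float, truth: GroundTruth) -> float:
    """Photosynthetic maximum for a day of year, mg C m^-3 h^-1."""
    return truth.true_pmax_winter + (
        truth.true_pmax_summer - truth.true_pmax_winter
    ) * seasonal_shape(doy)


def attenuation_for_load(truth: GroundTruth, specific_load: float | None) -> float:
    """Attenuation coefficient, increasing with the current year's TOC load."""
    if specific_load is None:
        return truth.true_attenuation_base
    return truth.true_attenuation_base * (
        1.0 + ATTENUATION_LOAD_SENSITIVITY * specific_load / ATTENUATION_LOAD_REF
    )


def expected_daily_pp(
    doy: float, truth: GroundTruth, attenuation_k: float
) -> float:
    """Noise-free daily areal fixation (mg C m^-2 d^-1) for one day of year."""
    curve = PICurve(p_max=seasonal_p_max(doy, truth), alpha=truth.true_alpha)
    lf = LightField(
        surface_irradiance=hourly_surface_irradiance(doy), attenuation_k=attenuation_k
    )
    grid = np.array([0.0, 1.0, 2.0, 3.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0])
    profile = daily_fixation_incubator(curve, lf, grid)
    return integrate_depth(profile, PRODUCTION_DEPTH_CAP)


def _sampling_days(rng: np.random.Generator, n_dates: int | None) -> np.ndarray:
    if n_dates is None:
        n_dates = int(rng.integers(13, 27))
    if not 13 <= n_dates <= 26:
        raise ValueError("sampling effort is 13-26 dates per year")
    base = np.linspace(30.0, 340.0, n_dates)
    jitter = rng.uniform(-5.0, 5.0, size=n_dates)
    return np.unique(np.round(base + jitter).astype(int))


def simulate_station_year(
    year: int,
    basin: BasinConfig,
    truth: GroundTruth,
    lagged_specific_load: float | None = None,
    current_specific_load: float | None = None,
    n_dates: int | None = None,
    constants: ConversionConstants = ConversionConstants(),
) -> pd.DataFrame:
    """One basin-year of station records in the standard monitoring schema.

    Per sampling date the frame carries four record kinds, distinguished by
    which cells are filled: P-I incubation bottles (irradiance + 14C
    uptake, no depth), an irradiance depth profile, thymidine uptake with
    measured cell volumes over the water column, and a biomass record.

    Thymidine uptake is scaled so that the *noise-free* annual Pb:Pp equals
    true_a * exp(true_b * lagged specific load); when no lagged load is
    available the baseline ratio true_a applies. Light attenuation responds
    to the current year's load. Reproducible from the truth seed.
    """
    rng = np.random.default_rng(derive_seed(truth.seed, basin.name, year, "station"))
    days = _sampling_days(rng, n_dates)
    cv = truth.noise_cv

    def noisy(value, cv=cv, size=None):
        if cv <= 0:
            return value if size is None else np.full(size, value, dtype=float)
        factor = rng.lognormal(mean=-(cv**2) / 2.0, sigma=cv, size=size)
        return value * factor

    k = attenuation_for_load(truth, current_specific_load)
    load = 0.0 if lagged_specific_load is None else float(lagged_specific_load)
    target_ratio = truth.true_a * np.exp(truth.true_b * load)

    # Noise-free daily Pp per sampling date; the Pb target is proportional,
    # so annual trapezoids of both sides preserve the ratio exactly.
    pp_daily = np.array([expected_daily_pp(d, truth, k) for d in days])
    pb_daily = target_ratio * pp_daily

    depth_cap = min(basin.mean_depth_m, 30.0)
    tdr_depths = sorted({1.0, 5.0, 10.0, round(basin.mean_depth_m / 2.0), depth_cap})
    light_depths = [d for d in (1.0, 2.0, 5.0, 10.0, 15.0, 20.0) if d <= depth_cap]
    fg_c = carbon_per_cell(MEAN_CELL_VOLUME, constants)

    rows: list[dict] = []
    for day, pp_d, pb_d in zip(days, pp_daily, pb_daily):
        date = (pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(day) - 1)).date()
        p_max = seasonal_p_max(day, truth)
        curve = PICurve(p_max=p_max, alpha=truth.true_alpha)

        for irr in PI_IRRADIANCE_LEVELS:
            uptake = p_max * np.tanh(truth.true_alpha * irr / p_max)
            rows.append({
                "date": date, "depth_m": np.nan,
                "irradiance_umol_m2_s": irr,
                "c14_uptake_mgC_m3_h": noisy(uptake),
            })

        noon = _noon_irradiance(day) * DEFAULT_REFLECTION_TRANSMITTANCE
        for z in light_depths:
            rows.append({
                "date": date, "depth_m": z,
                "irradiance_umol_m2_s": noisy(noon * np.exp(-k * z), cv=0.03),
            })

        # Uniform volumetric Pb over the mean water column reproduces the
        # areal target under trapezoidal integration to the basin depth.
        pb_vol = pb_d / basin.mean_depth_m  # mg C m^-3 d^-1
        tdr = pb_vol / (24.0 * constants.cells_per_mol_tdr * fg_c * 1e-12)
        for z in tdr_depths:
            rows.append({
                "date": date, "depth_m": float(z),
                "tdr_uptake_mol_m3_h": noisy(tdr),
                "cell_volume_um3": noisy(MEAN_CELL_VOLUME, cv=cv / 2.0),
            })

        # Standing biomass consistent with a plausible community growth
        # rate; volumetric over the production layer.
        biomass_vol = max(pp_d, 1e-9) / PRODUCTION_DEPTH_CAP / 0.5
        rows.append({
            "date": date, "depth_m": 1.0,
            "biomass_mgC_m3": noisy(biomass_vol),
        })

    frame = pd.DataFrame(rows)
    frame["station"] = f"{basin.name[:2].upper()}1"
    frame["basin"] = basin.name
    return frame.reindex(columns=STATION_COLUMNS)


@dataclass
class CampaignData:
    """A full multi-basin, multi-year synthetic monitoring campaign."""

    truth: GroundTruth
    basins: list
    years: list
    rivers: dict  # basin name -> RiverData (includes lead-in years)
    specific_loads: dict  # basin name -> {year: g C m^-2 yr^-1}
    stations: dict  # (basin name, year) -> station DataFrame


def simulate_campaign(
    years: Sequence[int],
    basins: Sequence[BasinConfig] | None = None,
    truth: GroundTruth = GroundTruth(),
    n_dates: int | None = None,
) -> CampaignData:
    """Simulate rivers and station records for several basins and years.

    The river record starts ``true_lag`` years before the first station
    year so every station year has a lagged specific TOC load. Station
    thymidine levels follow the exponential response to that lagged load;
    attenuation follows the current year's load.
    """
    from .riverine_load import AnnualLoad, annual_flow, annual_load, specific_toc_load

    if basins is None:
        basins = default_basins()
    years = sorted(int(y) for y in years)
    river_years = list(range(years[0] - truth.true_lag, years[-1] + 1))
    rivers: dict = {}
    loads: dict = {}
    stations: dict = {}
    for basin in basins:
        river = simulate_river(river_years, basin, truth)
        rivers[basin.name] = river
        per_year: dict[int, float] = {}
        for year in river_years:
            flow = annual_flow(river.daily_flow, year)
            toc_kg, _ = annual_load(
                river.daily_flow,
                river.monthly_concentration.loc[year]["toc"],
                year,
            )
            al = AnnualLoad(basin=basin.name, year=year, flow=flow, toc=toc_kg)
            per_year[year] = specific_toc_load(al, basin).toc_specific
        loads[basin.name] = per_year
        for year in years:
            stations[(basin.name, year)] = simulate_station_year(
                year,
                basin,
                truth,
                lagged_specific_load=per_year.get(year - truth.true_lag),
                current_specific_load=per_year.get(year),
                n_dates=n_dates,
            )
    return CampaignData(
        truth=truth, basins=list(basins), years=years,
        rivers=rivers, specific_loads=loads, stations=stations,
    )
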