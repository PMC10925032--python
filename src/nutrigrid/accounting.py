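"""Annual provincial nutrient-discharge accounting.

Five sectors contribute to anthropogenic discharge (AD) of total nitrogen
(TN) and total phosphorus (TP): urban residential (UD), rural residential
(RD), industrial (ID), crop farming (FD) and livestock farming (LD), with

    AD = UD + RD + ID + FD + LD

Each sector is an activity level (population, GDP, sown area, headcount)
times per-unit generation/discharge coefficients, attenuated by the
treatment, reuse and pastoral-retention pathways that keep nutrients out
of the water environment.

Canonical units: discharge mass in tonnes per year; water use in litres
per person per day over a fixed 365-day year; wastewater concentrations
in mg per litre; per-capita and per-head coefficients in kg per year.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "POLLUTANTS",
    "SECTORS",
    "SPECIES",
    "PASTORAL_SPECIES",
    "ParameterError",
    "UrbanParams",
    "RuralParams",
    "IndustrySeries",
    "CropParams",
    "SpeciesParams",
    "LivestockParams",
    "ProvinceSectorTotal",
    "DischargeResult",
    "urban_discharge",
    "rural_discharge",
    "industrial_discharge",
    "crop_discharge",
    "livestock_discharge",
    "total_discharge",
]

POLLUTANTS = ("TN", "TP")
SECTORS = ("urban", "rural", "industrial", "crop", "livestock")

#: The six livestock species tracked, in the conventional order.
SPECIES = ("pig", "beef_cattle", "dairy_cow", "laying_hen", "broiler", "sheep")
#: Ruminants raised partly on pasture; excreta retained in grassland soils
#: are removed from the water-bound balance. The pastoral ratio is forced
#: to zero for the monogastric species.
PASTORAL_SPECIES = frozenset({"beef_cattle", "dairy_cow", "sheep"})

DAYS_PER_YEAR = 365.0
#: L × mg/L → tonnes.
MG_L_TO_TONNES = 1e-9
KG_TO_TONNES = 1e-3
#: Rounded statistical tables: share sums are checked to this tolerance.
SHARE_TOL = 1e-6


class ParameterError(ValueError):
    """A sector parameter violates its physical range; names the field."""


def _per_pollutant(value: float | Mapping[str, float], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {str(k): float(v) for k, v in value.items()}
    return {p: float(value) for p in POLLUTANTS}


def _check_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ParameterError(f"{name} must be finite and >= 0, got {value}")


def _check_fraction(name: str, value: float) -> None:
    _check_nonneg(name, value)
    if value > 1 + SHARE_TOL:
        raise ParameterError(f"{name} must be <= 1, got {value}")


class DischargeResult(NamedTuple):
    """A sector's annual mass (t yr⁻¹) with its pathway breakdown."""

    total: float
    components: dict[str, float]


@dataclass(frozen=True)
class UrbanParams:
    """Urban residential wastewater pathway for one province-year.

    Wastewater volume is ``u_pop × um_water × 365`` litres; a fraction
    ``ur_direct`` reaches water untreated at concentration ``uc_direct``,
    a fraction ``ur_treat`` passes wastewater treatment plants, of which
    ``ur_reuse`` is reclaimed and the rest discharged at the plants'
    effluent concentration ``uc_treat``.
    """

    u_pop: float
    um_water: float  # L person⁻¹ day⁻¹
    ur_direct: float
    ur_treat: float
    ur_reuse: float
    uc_direct: Mapping[str, float] | float  # mg L⁻¹, per pollutant
    uc_treat: Mapping[str, float] | float  # mg L⁻¹, per pollutant

    def __post_init__(self) -> None:
        _check_nonneg("u_pop", self.u_pop)
        _check_nonneg("um_water", self.um_water)
        _check_fraction("ur_direct", self.ur_direct)
        _check_fraction("ur_treat", self.ur_treat)
        _check_fraction("ur_reuse", self.ur_reuse)
        if self.ur_direct + self.ur_treat > 1 + SHARE_TOL:
            raise ParameterError(
                "ur_direct + ur_treat must be <= 1, got "
                f"{self.ur_direct + self.ur_treat}"
            )
        object.__setattr__(self, "uc_direct", _per_pollutant(self.uc_direct, "uc_direct"))
        object.__setattr__(self, "uc_treat", _per_pollutant(self.uc_treat, "uc_treat"))
        for name in ("uc_direct", "uc_treat"):
            for pol, v in getattr(self, name).items():
                _check_nonneg(f"{name}[{pol}]", v)


def urban_discharge(p: UrbanParams, pollutant: str) -> DischargeResult:
    """Annual urban residential discharge UD = UD_direct + UD_treat (t yr⁻¹)."""
    volume = p.u_pop * p.um_water * DAYS_PER_YEAR  # litres
    direct = volume * p.ur_direct * p.uc_direct[pollutant] * MG_L_TO_TONNES
    treated = (
        volume * p.ur_treat * (1.0 - p.ur_reuse) * p.uc_treat[pollutant] * MG_L_TO_TONNES
    )
    return DischargeResult(direct + treated, {"direct": direct, "treated": treated})


@dataclass(frozen=True)
class RuralParams:
    """Rural residential pathway for one province-year.

    Per-capita generation blends the dry- and flush-toilet coefficients by
    their household shares; a fraction goes to water directly and a
    fraction through rural treatment facilities with removal efficiency
    ``rm_removal``.
    """

    r_pop: float
    rr_dry: float
    rr_flu: float
    rm_dry: Mapping[str, float] | float  # kg person⁻¹ yr⁻¹
    rm_flu: Mapping[str, float] | float  # kg person⁻¹ yr⁻¹
    rm_direct: float
    rm_treat: float
    rm_removal: float

    def __post_init__(self) -> None:
        _check_nonneg("r_pop", self.r_pop)
        _check_fraction("rr_dry", self.rr_dry)
        _check_fraction("rr_flu", self.rr_flu)
        if abs(self.rr_dry + self.rr_flu - 1.0) > SHARE_TOL:
            raise ParameterError(
                f"rr_dry + rr_flu must equal 1, got {self.rr_dry + self.rr_flu}"
            )
        _check_fraction("rm_direct", self.rm_direct)
        _check_fraction("rm_treat", self.rm_treat)
        if self.rm_direct + self.rm_treat > 1 + SHARE_TOL:
            raise ParameterError(
                "rm_direct + rm_treat must be <= 1, got "
                f"{self.rm_direct + self.rm_treat}"
            )
        _check_fraction("rm_removal", self.rm_removal)
        object.__setattr__(self, "rm_dry", _per_pollutant(self.rm_dry, "rm_dry"))
        object.__setattr__(self, "rm_flu", _per_pollutant(self.rm_flu, "rm_flu"))
        for name in ("rm_dry", "rm_flu"):
            for pol, v in getattr(self, name).items():
                _check_nonneg(f"{name}[{pol}]", v)

    def generation(self, pollutant: str) -> float:
        """Blended per-capita generation coefficient (kg person⁻¹ yr⁻¹)."""
        return self.rr_dry * self.rm_dry[pollutant] + self.rr_flu * self.rm_flu[pollutant]


def rural_discharge(p: RuralParams, pollutant: str) -> DischargeResult:
    """Annual rural residential discharge RD = RD_direct + RD_treat (t yr⁻¹)."""
    gen = p.generation(pollutant)  # kg person⁻¹ yr⁻¹
    direct = p.r_pop * gen * p.rm_direct * KG_TO_TONNES
    treated = p.r_pop * gen * p.rm_treat * (1.0 - p.rm_removal) * KG_TO_TONNES
    return DischargeResult(direct + treated, {"direct": direct, "treated": treated})


@dataclass(frozen=True)
class IndustrySeries:
    """Per-province industrial discharge and GDP time series.

    Discharge statistics have gaps; GDP is complete. Missing years are
    filled from the province's own discharge–GDP relationship (log–log
    fit; see :func:`industrial_discharge`).
    """

    years: Sequence[int]
    gdp: Mapping[int, float]
    discharge: Mapping[str, Mapping[int, float]]  # pollutant -> year -> t yr⁻¹

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        gdp = {int(y): float(v) for y, v in self.gdp.items()}
        object.__setattr__(self, "gdp", gdp)
        for y in years:
            if y not in gdp:
                raise ParameterError(f"gdp missing for year {y}")
            if gdp[y] <= 0:
                raise ParameterError(f"gdp must be > 0, got {gdp[y]} for year {y}")
        disch = {
            pol: {int(y): float(v) for y, v in series.items()}
            for pol, series in self.discharge.items()
        }
        object.__setattr__(self, "discharge", disch)
        for pol, series in disch.items():
            for y, v in series.items():
                _check_nonneg(f"discharge[{pol}][{y}]", v)

    def observed(self, pollutant: str) -> dict[int, float]:
        return dict(self.discharge.get(pollutant, {}))


class IndustrialEstimate(NamedTuple):
    mass: float
    flag: str  # "observed" | "imputed"


def _loglog_fit(years: list[int], gdp: Mapping[int, float], values: list[float]):
    """OLS of log(discharge) on log(GDP); returns predict(gdp)->mass."""
    x = np.log([gdp[y] for y in years])
    y = np.log(values)
    slope, intercept = np.polyfit(x, y, 1)
    return lambda g: float(np.exp(intercept + slope * np.log(g)))


def industrial_discharge(
    s: IndustrySeries, year: int, pollutant: str = "TN"
) -> IndustrialEstimate:
    """Industrial discharge for ``year``: observed pass-through or gap-fill.

    Observed years return the statistical value unchanged. Missing years
    are predicted from the province's discharge–GDP elasticity: a log–log
    ordinary-least-squares fit on the positive observations (exact line
    through two points); with a single observation the fill is constant.
    Predictions are clipped at zero and flagged ``"imputed"``.
    """
    year = int(year)
    obs = s.observed(pollutant)
    if not obs:
        raise ParameterError(f"no observed industrial discharge for {pollutant}")
    if year in obs:
        return IndustrialEstimate(obs[year], "observed")
    if year not in s.gdp:
        raise ParameterError(f"gdp missing for requested year {year}")
    positive = {y: v for y, v in obs.items() if v > 0}
    if len(positive) >= 2:
        years = sorted(positive)
        predict = _loglog_fit(years, s.gdp, [positive[y] for y in years])
        value = predict(s.gdp[year])
    else:
        # Degenerate fit: constant extrapolation of the mean observation.
        value = float(np.mean(list(obs.values())))
    return IndustrialEstimate(max(value, 0.0), "imputed")


@dataclass(frozen=True)
class CropParams:
    """Crop farming loss for one province-year.

    The 2017 census baseline loss coefficient ``fm_2017`` (kg ha⁻¹ yr⁻¹)
    is rescaled by the year's fertilizer application relative to 2017 and
    applied to the sown area.
    """

    f_area: float  # ha
    fm_2017: Mapping[str, float] | float  # kg ha⁻¹ yr⁻¹
    f_fertilizer_y: float  # t yr⁻¹
    f_fertilizer_2017: float  # t yr⁻¹

    def __post_init__(self) -> None:
        _check_nonneg("f_area", self.f_area)
        _check_nonneg("f_fertilizer_y", self.f_fertilizer_y)
        _check_nonneg("f_fertilizer_2017", self.f_fertilizer_2017)
        if self.f_fertilizer_2017 == 0:
            raise ParameterError("f_fertilizer_2017 must be > 0")
        object.__setattr__(self, "fm_2017", _per_pollutant(self.fm_2017, "fm_2017"))
        for pol, v in self.fm_2017.items():
            _check_nonneg(f"fm_2017[{pol}]", v)


def crop_discharge(p: CropParams, pollutant: str, year: int | None = None) -> float:
    """Annual crop-farming discharge FD = F_area × FM_y (t yr⁻¹)."""
    fm_y = p.fm_2017[pollutant] * p.f_fertilizer_y / p.f_fertilizer_2017
    return p.f_area * fm_y * KG_TO_TONNES


@dataclass(frozen=True)
class SpeciesParams:
    """One species' headcount, farming-mode split and discharge coefficients."""

    l_num: float  # head
    lr_pst: float  # pastoral ratio; meaningful for ruminants only
    lr_centralized: float
    lr_free: float
    lm_centralized: Mapping[str, float] | float  # kg head⁻¹ yr⁻¹
    lm_free: Mapping[str, float] | float  # kg head⁻¹ yr⁻¹

    def __post_init__(self) -> None:
        _check_nonneg("l_num", self.l_num)
        _check_fraction("lr_pst", self.lr_pst)
        _check_fraction("lr_centralized", self.lr_centralized)
        _check_fraction("lr_free", self.lr_free)
        if self.lr_centralized + self.lr_free > 1 + SHARE_TOL:
            raise ParameterError(
                "lr_centralized + lr_free must be <= 1, got "
                f"{self.lr_centralized + self.lr_free}"
            )
        object.__setattr__(
            self, "lm_centralized", _per_pollutant(self.lm_centralized, "lm_centralized")
        )
        object.__setattr__(self, "lm_free", _per_pollutant(self.lm_free, "lm_free"))


@dataclass(frozen=True)
class LivestockParams:
    """Per-species livestock parameters for one province-year.

    The pastoral ratio removes the grassland-retained share of ruminant
    excreta; it is forced to zero for pigs, laying hens and broilers.
    """

    species: Mapping[str, SpeciesParams]

    def __post_init__(self) -> None:
        clean: dict[str, SpeciesParams] = {}
        for name, sp in self.species.items():
            if name not in SPECIES:
                raise ParameterError(
                    f"unknown species {name!r}; expected one of {sorted(SPECIES)}"
                )
            if name not in PASTORAL_SPECIES and sp.lr_pst != 0.0:
                sp = SpeciesParams(
                    sp.l_num, 0.0, sp.lr_centralized, sp.lr_free,
                    sp.lm_centralized, sp.lm_free,
                )
            clean[name] = sp
        object.__setattr__(self, "species", clean)


def livestock_discharge(p: LivestockParams, pollutant: str) -> DischargeResult:
    """Annual livestock discharge LD = LD_centralized + LD_free (t yr⁻¹).

    Components carry a per-species breakdown under ``by_species`` keys.
    """
    centralized = 0.0
    free = 0.0
    by_species: dict[str, float] = {}
    for name, sp in p.species.items():
        eff_num = sp.l_num * (1.0 - sp.lr_pst)
        c = eff_num * sp.lr_centralized * sp.lm_centralized[pollutant] * KG_TO_TONNES
        f = eff_num * sp.lr_free * sp.lm_free[pollutant] * KG_TO_TONNES
        centralized += c
        free += f
        by_species[name] = c + f
    components = {"centralized": centralized, "free_range": free}
    components.update({f"by_species:{k}": v for k, v in by_species.items()})
    return DischargeResult(centralized + free, components)


@dataclass(frozen=True)
class ProvinceSectorTotal:
    """One (province, year, pollutant, sector) annual mass in t yr⁻¹."""

    province_id: int | str
    year: int
    pollutant: str
    sector: str
    mass: float

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ParameterError(f"unknown sector {self.sector!r}")
        if self.pollutant not in POLLUTANTS:
            raise ParameterError(f"unknown pollutant {self.pollutant!r}")
        if not math.isfinite(self.mass) or self.mass < 0:
            raise ParameterError(f"mass must be finite and >= 0, got {self.mass}")

    @property
    def key(self) -> tuple:
        return (self.province_id, self.year, self.pollutant)


class TotalDischarge(NamedTuple):
    mass: float
    shares: dict[str, float]


def total_discharge(components: Iterable[ProvinceSectorTotal]) -> TotalDischarge:
    """Sum the five sector totals into AD for one (province, year, pollutant).

    Returns the exact sum and each sector's share of it (all zero shares
    when the total is zero).
    """
    comps = list(components)
    if len(comps) != len(SECTORS) or {c.sector for c in comps} != set(SECTORS):
        raise ParameterError(
            f"need exactly one total per sector {SECTORS}, got "
            f"{sorted(c.sector for c in comps)}"
        )
    keys = {c.key for c in comps}
    if len(keys) != 1:
        raise ParameterError(f"mixed (province, year, pollutant) keys: {sorted(keys)}")
    total = math.fsum(c.mass for c in comps)
    shares = {
        c.sector: (c.mass / total if total > 0 else 0.0) for c in comps
    }
    return TotalDischarge(total, shares)
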