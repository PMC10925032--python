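"""Annual-to-monthly allocation profiles and their application.

Each sector splits its annual mass over the twelve months with a
non-negative profile summing to one:

* residential (urban and rural): a temperature-modulated water-use curve,
  C_i = (1/12) · [(T_i − T_avg)/(T_max − T_min) · R + 1], with amplitude R
  the relative difference in water use between the warmest and coldest
  months (default 0.2);
* crop farming: monthly rainfall times the regional crop-calendar term
  Σ_n A_n,i · F_n,i (sown-area share times fertilization share), then
  normalized;
* livestock: proportional to monthly rainfall (flushing effect);
* industrial: uniform, 1/12 each month.

The rainfall-driven profiles are normalized to sum to one — the only
reading under which splitting an annual value into months conserves its
mass — and every profile falls back to uniform when its driver is flat
(constant temperature, zero annual rainfall).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grids import Affine, Raster
from .spatial import GriddedInventory

__all__ = [
    "DEFAULT_AMPLITUDE",
    "ClimateStack",
    "CropCalendar",
    "MonthlyProfile",
    "MonthlyInventory",
    "residential_profile",
    "crop_profile",
    "livestock_profile",
    "industrial_profile",
    "apply_profiles",
]

log = logging.getLogger(__name__)

MONTHS = 12
#: Default residential water-use amplitude R (dimensionless), the adopted
#: national assessment value.
DEFAULT_AMPLITUDE = 0.2
_SUM_TOL = 1e-9


@dataclass
class ClimateStack:
    """Twelve monthly temperature (°C) and precipitation (mm) layers."""

    temperature: np.ndarray  # (12, ny, nx)
    precipitation: np.ndarray  # (12, ny, nx)
    transform: Affine
    crs_label: str = "local-albers-equal-area"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=np.float64)
        self.precipitation = np.asarray(self.precipitation, dtype=np.float64)
        for name, arr in (("temperature", self.temperature),
                          ("precipitation", self.precipitation)):
            if arr.ndim != 3 or arr.shape[0] != MONTHS:
                raise ValueError(f"{name} must have shape (12, ny, nx), got {arr.shape}")
        if self.temperature.shape != self.precipitation.shape:
            raise ValueError("temperature and precipitation shapes differ")
        valid = self.valid
        if np.any(self.precipitation[:, valid] < 0):
            raise ValueError("precipitation must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperature.shape[1:]

    @property
    def valid(self) -> np.ndarray:
        return np.all(self.temperature != self.nodata, axis=0) & np.all(
            self.precipitation != self.nodata, axis=0
        )

    # Annual per-cell summaries of the temperature cycle. The average uses
    # sequential month accumulation (see _month_sum) for per-cell
    # reproducibility.
    @property
    def t_avg(self) -> np.ndarray:
        return _month_sum(self.temperature) / MONTHS

    @property
    def t_max(self) -> np.ndarray:
        return self.temperature.max(axis=0)

    @property
    def t_min(self) -> np.ndarray:
        return self.temperature.min(axis=0)

    @property
    def p_avg(self) -> np.ndarray:
        return _month_sum(self.precipitation) / MONTHS


@dataclass(frozen=True)
class CropCalendar:
    """Monthly sown-area (A) and fertilization (F) shares per region and crop.

    ``regions`` maps a region key to ``{crop: (A[12], F[12])}``. A is the
    share of the region's sown area the crop occupies in each month; F is
    the share of the crop's annual fertilizer applied in each month and
    sums to one per crop.
    """

    regions: Mapping[str, Mapping[str, tuple]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for region, crops in self.regions.items():
            clean[region] = {}
            for crop, (a, f) in crops.items():
                a = np.asarray(a, dtype=np.float64)
                f = np.asarray(f, dtype=np.float64)
                if a.shape != (MONTHS,) or f.shape != (MONTHS,):
                    raise ValueError(
                        f"calendar for {region}/{crop} must hold 12 monthly values"
                    )
                if np.any(a < 0) or np.any(f < 0):
                    raise ValueError(f"calendar shares for {region}/{crop} must be >= 0")
                if abs(f.sum() - 1.0) > 1e-6:
                    raise ValueError(
                        f"fertilization shares for {region}/{crop} must sum to 1, "
                        f"got {f.sum():.6f}"
                    )
                clean[region][crop] = (a, f)
        object.__setattr__(self, "regions", clean)

    def monthly_weight(self, region: str) -> np.ndarray:
        """Σ_n A_n,i · F_n,i for each month i of a region."""
        if region not in self.regions:
            raise KeyError(f"no crop calendar for region {region!r}")
        w = np.zeros(MONTHS)
        for a, f in self.regions[region].values():
            w += a * f
        if w.sum() == 0:
            raise ValueError(f"crop calendar for region {region!r} is all zero")
        return w


@dataclass(frozen=True)
class MonthlyProfile:
    """Twelve non-negative allocation coefficients summing to one."""

    sector: str
    coefficients: np.ndarray
    scope: str = "province"

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if coef.shape != (MONTHS,):
            raise ValueError(f"profile must hold 12 coefficients, got {coef.shape}")
        if np.any(coef < 0):
            raise ValueError("profile coefficients must be >= 0")
        if abs(coef.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"profile must sum to 1, got {coef.sum():.12f}")
        object.__setattr__(self, "coefficients", coef)


def _uniform() -> np.ndarray:
    return np.full(MONTHS, 1.0 / MONTHS)


def _month_sum(stack: np.ndarray) -> np.ndarray:
    """Sum over the month axis by strict sequential accumulation.

    Fixes the floating-point evaluation order (month 1 + month 2 + …), so
    the vectorized stacks are bit-for-bit reproducible by a per-cell
    scalar loop.
    """
    out = np.array(stack[0], dtype=np.float64, copy=True)
    for k in range(1, stack.shape[0]):
        out = out + stack[k]
    return out


def residential_profile(
    temperatures: Sequence[float], amplitude: float = DEFAULT_AMPLITUDE
) -> MonthlyProfile:
    """Temperature-modulated residential profile.

    Warm months receive more than 1/12 and cold months less, by up to
    ±R/12 at the annual extremes; the deviations cancel, so the twelve
    coefficients sum to one analytically. A flat temperature record gives
    the uniform profile. With R > 1 extreme months could go negative;
    such coefficients are clipped at zero and the profile renormalized
    (logged).
    """
    t = np.asarray(temperatures, dtype=np.float64)
    if t.shape != (MONTHS,):
        raise ValueError(f"need 12 monthly temperatures, got shape {t.shape}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    span = t.max() - t.min()
    if span == 0:
        coef = _uniform()
    else:
        coef = ((t - t.mean()) / span * amplitude + 1.0) / MONTHS
        if np.any(coef < 0):
            log.warning(
                "residential profile clipped: amplitude %.3g produced negative "
                "coefficients", amplitude,
            )
            coef = np.clip(coef, 0.0, None)
            coef = coef / coef.sum()
    return MonthlyProfile("residential", coef)


def crop_profile(
    precipitation: Sequence[float], calendar: CropCalendar, region: str
) -> MonthlyProfile:
    """Rainfall- and calendar-driven crop-farming profile.

    The raw coefficient is monthly rainfall times the calendar term
    Σ_n A_n,i F_n,i, normalized to sum to one. With zero annual rainfall
    the calendar term alone (normalized) is used.
    """
    p = np.asarray(precipitation, dtype=np.float64)
    if p.shape != (MONTHS,):
        raise ValueError(f"need 12 monthly precipitation values, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("precipitation must be >= 0")
    cal = calendar.monthly_weight(region)
    raw = p * cal
    if raw.sum() == 0:
        raw = cal
    return MonthlyProfile("crop", raw / raw.sum())


def livestock_profile(precipitation: Sequence[float]) -> MonthlyProfile:
    """Rainfall-proportional livestock profile (uniform when rain-free)."""
    p = np.asarray(precipitation, dtype=np.float64)
    if p.shape != (MONTHS,):
        raise ValueError(f"need 12 monthly precipitation values, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("precipitation must be >= 0")
    total = p.sum()
    coef = _uniform() if total == 0 else p / total
    return MonthlyProfile("livestock", coef)


def industrial_profile() -> MonthlyProfile:
    """Uniform industrial profile: annual mass evenly split, 1/12 a month."""
    return MonthlyProfile("industrial", _uniform())


@dataclass
class MonthlyInventory:
    """Per-(sector, pollutant) monthly raster stacks in t cell⁻¹ month⁻¹."""

    data: dict  # (sector, pollutant) -> (12, ny, nx) ndarray
    transform: Affine
    crs_label: str
    nodata: float
    year: int
    amplitude: float = DEFAULT_AMPLITUDE
    units: str = "t cell-1 month-1"
    provenance: dict = field(default_factory=dict)

    def annual(self, sector: str, pollutant: str) -> np.ndarray:
        """Recomputed annual layer: sum over the 12 months."""
        return self.data[(sector, pollutant)].sum(axis=0)


def _coefficient_stacks(
    sectors: set[str],
    climate: ClimateStack,
    calendar: CropCalendar | None,
    region_ids: Raster | None,
    amplitude: float,
) -> dict[str, np.ndarray]:
    """Per-cell (12, ny, nx) monthly coefficient stacks for each sector."""
    ny, nx = climate.shape
    valid = climate.valid
    coeffs: dict[str, np.ndarray] = {}

    if sectors & {"urban", "rural"}:
        t = climate.temperature
        span = climate.t_max - climate.t_min
        with np.errstate(invalid="ignore", divide="ignore"):
            c = ((t - climate.t_avg) / span * amplitude + 1.0) / MONTHS
        c = np.where(span == 0, 1.0 / MONTHS, c)
        if np.any(c[:, valid] < 0):
            log.warning("residential coefficients clipped at 0 and renormalized")
            c = np.clip(c, 0.0, None)
            c = c / c.sum(axis=0)
        for s in sectors & {"urban", "rural"}:
            coeffs[s] = c

    if "crop" in sectors:
        if calendar is None:
            raise ValueError("crop sector requires a crop calendar")
        cal_grid = np.zeros((MONTHS, ny, nx))
        if region_ids is None:
            regions = list(calendar.regions)
            if len(regions) != 1:
                raise ValueError(
                    "multi-region calendar requires a region-ID raster"
                )
            cal_grid += calendar.monthly_weight(regions[0])[:, None, None]
        else:
            for region in calendar.regions:
                cells = region_ids.values == _region_code(region)
                cal_grid[:, cells] = calendar.monthly_weight(region)[:, None]
            unassigned = valid & ~np.isin(
                region_ids.values, [_region_code(r) for r in calendar.regions]
            )
            if unassigned.any():
                raise ValueError(
                    f"{int(unassigned.sum())} cells belong to no calendar region"
                )
        raw = climate.precipitation * cal_grid
        tot = _month_sum(raw)
        cal_tot = _month_sum(cal_grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(tot > 0, raw / tot, cal_grid / cal_tot)
        coeffs["crop"] = c

    if "livestock" in sectors:
        p = climate.precipitation
        tot = _month_sum(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(tot > 0, p / tot, 1.0 / MONTHS)
        coeffs["livestock"] = c

    if "industrial" in sectors:
        coeffs["industrial"] = np.full((MONTHS, ny, nx), 1.0 / MONTHS)
    return coeffs


def _region_code(region) -> int:
    """Calendar region keys may be ints or 'name:<code>' strings."""
    if isinstance(region, int):
        return region
    s = str(region)
    if ":" in s:
        return int(s.rsplit(":", 1)[1])
    return int(s)


def apply_profiles(
    annual: GriddedInventory,
    climate: ClimateStack,
    calendar: CropCalendar | None = None,
    region_ids: Raster | None = None,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> MonthlyInventory:
    """Split each annual raster into twelve monthly rasters per cell.

    Residential, crop and livestock coefficients are computed per grid
    cell from the climate stack; the industrial split is uniform. Per
    cell, the twelve monthly values sum back to the annual value.
    """
    if not annual.data:
        raise ValueError("annual inventory is empty")
    ref = next(iter(annual.data.values()))
    if climate.shape != ref.shape:
        raise ValueError(
            f"climate stack shape {climate.shape} != inventory shape {ref.shape}"
        )
    if climate.transform != ref.transform:
        raise ValueError("climate stack grid transform differs from the inventory's")
    sectors = annual.sectors()
    coeffs = _coefficient_stacks(sectors, climate, calendar, region_ids, amplitude)
    data: dict = {}
    for (sector, pollutant), raster in annual.data.items():
        data[(sector, pollutant)] = coeffs[sector] * raster.filled(0.0)
    prov = dict(annual.provenance)
    prov["amplitude_R"] = amplitude
    prov["profile_normalization"] = "monthly coefficients normalized to sum 1"
    return MonthlyInventory(
        data=data,
        transform=ref.transform,
        crs_label=ref.crs_label,
        nodata=ref.nodata,
        year=annual.year,
        amplitude=amplitude,
        provenance=prov,
    )
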