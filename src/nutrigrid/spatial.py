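"""Conservation-preserving spatial downscaling of provincial totals.

A provincial sector total is spread over the grid cells of that province
in proportion to non-negative surrogate weights: calibrated population for
the residential and industrial sectors, terrain-derived nutrient-loss
propensity (slope grade × soil-clay grade) for the agricultural sectors,
restricted to the sector's eligible land-use classes. Weights are
normalized to sum to one within each province, so allocation conserves
mass exactly; aggregating the grid back to provinces is the inverse
operation used for cross-scale validation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .accounting import POLLUTANTS, SECTORS, ProvinceSectorTotal
from .grids import Raster, require_aligned

__all__ = [
    "LANDUSE_CLASSES",
    "SECTOR_LANDUSE",
    "SLOPE_BINS",
    "SLOPE_COEFFICIENTS",
    "CLAY_BINS",
    "CLAY_COEFFICIENTS",
    "PopulationGrid",
    "SurrogateWeights",
    "GriddedInventory",
    "calibrate_population",
    "landuse_mask",
    "slope_from_dem",
    "slope_coefficient",
    "clay_coefficient",
    "build_weights",
    "allocate",
    "aggregate_to_provinces",
]

log = logging.getLogger(__name__)

#: Integer codes of the land-use classes the model distinguishes.
LANDUSE_CLASSES = {
    "urban_land": 1,
    "rural_residential_land": 2,
    "other_construction_land": 3,
    "cultivated_land": 4,
    "other": 5,
}

#: Land-use classes eligible to receive each sector's discharge. Urban land
#: carries urban residential and industrial discharge, rural residential
#: land the rural sector, other construction land industrial discharge,
#: and cultivated land (paddy and dryland) the crop and livestock sectors.
SECTOR_LANDUSE: dict[str, frozenset[int]] = {
    "urban": frozenset({1}),
    "rural": frozenset({2}),
    "industrial": frozenset({1, 3}),
    "crop": frozenset({4}),
    "livestock": frozenset({4}),
}

#: Nutrient-loss coefficient grades by percent slope. Bins are
#: lower-inclusive / upper-exclusive; a boundary value lands in the
#: higher-loss class.
SLOPE_BINS = (8.0, 15.0, 25.0)
SLOPE_COEFFICIENTS = (0.10, 0.20, 0.35, 0.50)

#: Nutrient-loss coefficient grades by soil clay content (percent):
#: coarse soils lose most, very fine soils least.
CLAY_BINS = (18.0, 35.0, 60.0)
CLAY_COEFFICIENTS = (0.75, 0.50, 0.25, 0.10)


@dataclass
class PopulationGrid:
    """Reference and statistically calibrated gridded population."""

    reference: Raster
    calibrated: Raster
    province_factors: dict  # province id -> POPC correction factor


@dataclass
class SurrogateWeights:
    """Per-cell allocation shares for one sector.

    Within each province the weights over valid cells sum to one. The
    ``normalization`` record states, per province, which rule produced the
    weights: ``"proxy"`` (the sector's surrogate), ``"uniform_eligible"``
    (uniform over eligible land-use cells) or ``"uniform_province"``
    (uniform over all province cells) — the latter two are fallbacks for
    provinces where the surrogate carries no mass.
    """

    sector: str
    weights: Raster
    normalization: dict = field(default_factory=dict)


@dataclass
class GriddedInventory:
    """Per-(sector, pollutant) annual rasters in t cell⁻¹ yr⁻¹."""

    data: dict  # (sector, pollutant) -> Raster
    year: int
    units: str = "t cell-1 yr-1"
    provenance: dict = field(default_factory=dict)

    def sectors(self) -> set[str]:
        return {s for s, _ in self.data}

    def total(self, pollutant: str) -> Raster:
        """Sum of all sector layers for one pollutant (AD per cell)."""
        layers = [r for (s, p), r in self.data.items() if p == pollutant]
        if not layers:
            raise KeyError(f"no layers for pollutant {pollutant!r}")
        out = np.zeros(layers[0].shape)
        for r in layers:
            out += r.filled(0.0)
        return layers[0].with_values(out)


def _province_ids(province_raster: Raster) -> list:
    ids = np.unique(province_raster.values[province_raster.valid])
    return [i.item() if hasattr(i, "item") else i for i in ids]


def calibrate_population(
    reference: Raster, province_ids: Raster, sta_pop: Mapping
) -> PopulationGrid:
    """Scale the reference population grid to match statistical totals.

    Each province's cells are multiplied by one correction factor
    POPC = STAPOP / RPOP, where RPOP is the reference-map population of
    the province, so per-province sums of the calibrated grid equal the
    statistics exactly.
    """
    require_aligned(reference, province_ids)
    if (reference.values[reference.valid] < 0).any():
        raise ValueError("reference population must be >= 0")
    ref = reference.filled(0.0)
    calibrated = np.zeros_like(ref)
    factors: dict = {}
    for prov, target in sta_pop.items():
        cells = (province_ids.values == prov) & province_ids.valid
        if not cells.any():
            raise ValueError(f"province {prov!r} has no cells on the grid")
        rpop = float(ref[cells].sum())
        if rpop == 0.0:
            if target > 0:
                raise ValueError(
                    f"province {prov!r}: reference population is zero but "
                    f"statistical population is {target}; cannot scale a zero field"
                )
            factors[prov] = 1.0
            continue
        popc = float(target) / rpop
        factors[prov] = popc
        calibrated[cells] = popc * ref[cells]
    out = reference.with_values(calibrated)
    out.values[~reference.valid] = reference.nodata
    return PopulationGrid(reference=reference, calibrated=out, province_factors=factors)


def landuse_mask(lu: Raster, sector: str) -> Raster:
    """Binary eligibility mask for a sector from the land-use grid."""
    if sector not in SECTOR_LANDUSE:
        raise KeyError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    valid = lu.valid
    codes = np.unique(lu.values[valid])
    known = set(LANDUSE_CLASSES.values())
    unknown = [int(c) for c in codes if int(c) not in known]
    if unknown:
        raise ValueError(f"unknown land-use category codes {unknown}")
    eligible = SECTOR_LANDUSE[sector]
    mask = np.where(np.isin(lu.values, list(eligible)) & valid, 1.0, 0.0)
    mask[~valid] = float(np.float64(lu.nodata))
    return Raster(mask, lu.transform, lu.crs_label, nodata=float(np.float64(lu.nodata)))


def slope_from_dem(dem: Raster) -> Raster:
    """Percent slope from a DEM by Horn's 3×3 finite-difference operator.

    Edge cells use edge-clamped neighborhoods. Cell size is taken from the
    grid transform, so the DEM heights and the transform must share the
    same length unit.
    """
    if min(dem.shape) < 2:
        raise ValueError(f"DEM grid {dem.shape} too small for a slope operator")
    z = dem.filled(0.0)
    # Fill nodata with the nearest valid structure is overkill for the toy
    # grids; edge-clamp after zero-filling nodata, then re-mask.
    zp = np.pad(z, 1, mode="edge")
    dx = dem.transform.cell_width
    dy = dem.transform.cell_height
    z1, z2, z3 = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    z4, z6 = zp[1:-1, :-2], zp[1:-1, 2:]
    z7, z8, z9 = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    gx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8.0 * dx)
    gy = ((z7 + 2 * z8 + z9) - (z1 + 2 * z2 + z3)) / (8.0 * dy)
    slope = 100.0 * np.sqrt(gx**2 + gy**2)
    slope[~dem.valid] = dem.nodata
    return dem.with_values(slope)


def _grade_lookup(values, bins, coefficients, name, lower, upper):
    arr = np.asarray(values, dtype=np.float64)
    if np.any(arr < lower) or (upper is not None and np.any(arr > upper)):
        bound = f"[{lower}, {upper}]" if upper is not None else f">= {lower}"
        raise ValueError(f"{name} out of range {bound}")
    idx = np.digitize(arr, bins, right=False)  # lower-inclusive bins
    out = np.asarray(coefficients)[idx]
    return out if out.ndim else float(out)


def slope_coefficient(slope_percent):
    """Nutrient-loss coefficient grade for percent slope (scalar or array).

    Horizontal [0, 8) → 0.10, moderate [8, 15) → 0.20, medium
    [15, 25) → 0.35, steep ≥ 25 → 0.50.
    """
    return _grade_lookup(
        slope_percent, SLOPE_BINS, SLOPE_COEFFICIENTS, "slope", 0.0, None
    )


def clay_coefficient(clay_percent):
    """Nutrient-loss coefficient grade for soil clay content in percent.

    Coarse [0, 18) → 0.75, medium [18, 35) → 0.50, fine [35, 60) → 0.25,
    very fine ≥ 60 → 0.10.
    """
    return _grade_lookup(
        clay_percent, CLAY_BINS, CLAY_COEFFICIENTS, "clay content", 0.0, 100.0
    )


def build_weights(
    sector: str,
    mask: Raster,
    population: PopulationGrid | None = None,
    slope_coef: Raster | None = None,
    clay_coef: Raster | None = None,
    *,
    province_ids: Raster,
) -> SurrogateWeights:
    """Normalized per-cell allocation weights for one sector.

    Residential and industrial sectors use calibrated population on
    eligible land; crop and livestock use the product of the slope and
    clay loss-coefficient grades on cultivated land. Per province the
    weights sum to one; a province whose surrogate carries no mass falls
    back to a uniform split over eligible cells, then over all its cells.
    """
    layers = [mask, province_ids]
    if sector in ("urban", "rural", "industrial"):
        if population is None:
            raise ValueError(f"sector {sector!r} requires a population surrogate")
        proxy = population.calibrated.filled(0.0)
        layers.append(population.calibrated)
    elif sector in ("crop", "livestock"):
        if slope_coef is None or clay_coef is None:
            raise ValueError(f"sector {sector!r} requires slope and clay surrogates")
        proxy = slope_coef.filled(0.0) * clay_coef.filled(0.0)
        layers.extend([slope_coef, clay_coef])
    else:
        raise KeyError(f"unknown sector {sector!r}")
    require_aligned(*layers)

    m = mask.filled(0.0)
    raw = m * proxy
    weights = np.zeros_like(raw)
    normalization: dict = {}
    for prov in _province_ids(province_ids):
        cells = (province_ids.values == prov) & province_ids.valid
        total = raw[cells].sum()
        if total > 0:
            weights[cells] = raw[cells] / total
            normalization[prov] = "proxy"
            continue
        eligible = cells & (m > 0)
        if eligible.any():
            weights[eligible] = 1.0 / eligible.sum()
            normalization[prov] = "uniform_eligible"
            log.warning(
                "sector %s, province %s: surrogate carries no mass; "
                "uniform split over %d eligible cells",
                sector, prov, int(eligible.sum()),
            )
        else:
            weights[cells] = 1.0 / cells.sum()
            normalization[prov] = "uniform_province"
            log.warning(
                "sector %s, province %s: no eligible land-use cells; "
                "uniform split over all %d province cells",
                sector, prov, int(cells.sum()),
            )
    out = Raster(weights, mask.transform, mask.crs_label, nodata=mask.nodata)
    out.values[~province_ids.valid] = mask.nodata
    return SurrogateWeights(sector=sector, weights=out, normalization=normalization)


def allocate(
    totals: Iterable[ProvinceSectorTotal],
    weights: SurrogateWeights | Mapping[str, SurrogateWeights],
    province_ids: Raster,
    *,
    year: int | None = None,
    provenance: dict | None = None,
) -> GriddedInventory:
    """Downscale provincial sector totals onto the grid.

    Each cell receives its province's total times the cell's weight, so
    per-province raster sums reproduce the inputs exactly (up to floating
    point). Accepts a single sector's weights or a mapping over sectors.
    """
    if isinstance(weights, SurrogateWeights):
        weights = {weights.sector: weights}
    totals = list(totals)
    grid_provinces = set(_province_ids(province_ids))
    missing = sorted({t.province_id for t in totals} - grid_provinces)
    if missing:
        raise ValueError(f"provinces absent from the grid: {missing}")
    years = {t.year for t in totals}
    if year is None:
        if len(years) != 1:
            raise ValueError(f"totals span several years {sorted(years)}; pass year=")
        year = years.pop()

    data: dict = {}
    norm_record: dict = {}
    for sector, w in weights.items():
        require_aligned(w.weights, province_ids)
        norm_record[sector] = dict(w.normalization)
        wv = w.weights.filled(0.0)
        for pollutant in POLLUTANTS:
            sel = [t for t in totals if t.sector == sector and t.pollutant == pollutant]
            if not sel:
                continue
            grid = np.zeros(province_ids.shape)
            for t in sel:
                cells = (province_ids.values == t.province_id) & province_ids.valid
                grid[cells] = t.mass * wv[cells]
            r = Raster(
                grid, province_ids.transform, province_ids.crs_label,
                nodata=float(np.float64(province_ids.nodata)),
            )
            r.values[~province_ids.valid] = r.nodata
            data[(sector, pollutant)] = r
    prov = dict(provenance or {})
    prov["weight_normalization"] = norm_record
    return GriddedInventory(data=data, year=int(year), provenance=prov)


def aggregate_to_provinces(
    inv: GriddedInventory, province_ids: Raster
) -> list[ProvinceSectorTotal]:
    """Zonal sums of the inventory back to provincial totals.

    On this package's own pipeline this is the exact inverse of
    :func:`allocate`; it is the statistic behind the 1:1 cross-scale
    validation.
    """
    out: list[ProvinceSectorTotal] = []
    provs = _province_ids(province_ids)
    for (sector, pollutant), raster in inv.data.items():
        require_aligned(raster, province_ids)
        vals = raster.filled(0.0)
        for prov in provs:
            cells = (province_ids.values == prov) & province_ids.valid
            mass = float(vals[cells].sum())
            out.append(
                ProvinceSectorTotal(
                    province_id=prov.item() if hasattr(prov, "item") else prov,
                    year=inv.year,
                    pollutant=pollutant,
                    sector=sector,
                    mass=max(mass, 0.0),
                )
            )
    return out
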