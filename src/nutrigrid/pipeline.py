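"""End-to-end orchestration: accounting → spatial → temporal → validation.

The pipeline is a pure function of its inputs and configuration: the
same tables, rasters and seed always yield identical outputs. Every
downscaling step is checked for mass conservation, and the gridded
product is aggregated back to provinces and compared with the accounting
totals on the 1:1 line — the cross-scale validation statistic.
"""
from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .accounting import (
    POLLUTANTS,
    SECTORS,
    ProvinceSectorTotal,
    crop_discharge,
    industrial_discharge,
    livestock_discharge,
    rural_discharge,
    urban_discharge,
)
from .grids import Affine, Raster
from .io import RunConfig, read_raster, write_monthly_nc, write_raster
from .spatial import (
    GriddedInventory,
    aggregate_to_provinces,
    allocate,
    build_weights,
    calibrate_population,
    clay_coefficient,
    landuse_mask,
    slope_coefficient,
    slope_from_dem,
)
from .tables import DEFAULT_SCHEMAS, params_from_tables
from .temporal import ClimateStack, CropCalendar, MonthlyInventory, apply_profiles

__all__ = [
    "CONSERVATION_RTOL",
    "PipelineInputs",
    "PipelineResult",
    "ValidationReport",
    "compute_totals",
    "cross_scale_r2",
    "load_inputs",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: Relative tolerance for every mass-conservation check.
CONSERVATION_RTOL = 1e-9


@dataclass
class PipelineInputs:
    """All spatial and tabular inputs of one run, on one shared grid."""

    province_ids: Raster
    landuse: Raster
    reference_pop: Raster
    dem: Raster
    clay: Raster
    region_ids: Raster | None
    climate: ClimateStack
    calendar: CropCalendar
    tables: dict


def load_inputs(input_dir, schemas=DEFAULT_SCHEMAS) -> tuple[PipelineInputs, list]:
    """Read an input directory (as written by a synthetic scenario).

    Returns the inputs and the list of schema violations found in the
    parameter tables.
    """
    from .io import read_tables

    input_dir = Path(input_dir)
    province_ids = read_raster(input_dir / "province_ids.tif")
    geometry = (province_ids.shape, province_ids.transform)
    landuse = read_raster(input_dir / "landuse.tif", expected_geometry=geometry)
    reference_pop = read_raster(
        input_dir / "reference_population.tif", expected_geometry=geometry
    )
    dem = read_raster(input_dir / "dem.tif", expected_geometry=geometry)
    clay = read_raster(input_dir / "clay.tif", expected_geometry=geometry)
    region_path = input_dir / "region_ids.tif"
    region_ids = (
        read_raster(region_path, expected_geometry=geometry)
        if region_path.exists()
        else None
    )
    with xr.open_dataset(input_dir / "climate.nc", engine="scipy") as ds:
        ds.load()
    climate = ClimateStack(
        temperature=np.asarray(ds["temperature"].values, dtype=np.float64),
        precipitation=np.asarray(ds["precipitation"].values, dtype=np.float64),
        transform=Affine(*ast.literal_eval(str(ds.attrs["transform"]))),
        crs_label=str(ds.attrs.get("crs_label", "")),
        nodata=float(ds.attrs.get("nodata", -9999.0)),
    )
    cal_df = pd.read_csv(input_dir / "calendar.csv")
    regions: dict = {}
    for (region, crop), grp in cal_df.groupby(["region", "crop"]):
        grp = grp.sort_values("month")
        regions.setdefault(int(region), {})[crop] = (
            grp["sown_share"].to_numpy(), grp["fert_share"].to_numpy()
        )
    calendar = CropCalendar(regions=regions)
    tables, violations = read_tables(input_dir, schemas)
    return (
        PipelineInputs(
            province_ids=province_ids,
            landuse=landuse,
            reference_pop=reference_pop,
            dem=dem,
            clay=clay,
            region_ids=region_ids,
            climate=climate,
            calendar=calendar,
            tables=tables,
        ),
        violations,
    )


def compute_totals(
    tables: Mapping, years: Sequence[int], pollutants=POLLUTANTS, sectors=SECTORS
) -> list[ProvinceSectorTotal]:
    """Run the accounting module over the parameter tables."""
    params = params_from_tables(tables, years)
    out: list[ProvinceSectorTotal] = []
    for (prov, year), p in params.items():
        for pol in pollutants:
            if "urban" in sectors:
                out.append(ProvinceSectorTotal(
                    prov, year, pol, "urban", urban_discharge(p["urban"], pol).total))
            if "rural" in sectors:
                out.append(ProvinceSectorTotal(
                    prov, year, pol, "rural", rural_discharge(p["rural"], pol).total))
            if "industrial" in sectors:
                out.append(ProvinceSectorTotal(
                    prov, year, pol, "industrial",
                    industrial_discharge(p["industrial"], year, pol).mass))
            if "crop" in sectors:
                out.append(ProvinceSectorTotal(
                    prov, year, pol, "crop", crop_discharge(p["crop"], pol, year)))
            if "livestock" in sectors:
                out.append(ProvinceSectorTotal(
                    prov, year, pol, "livestock",
                    livestock_discharge(p["livestock"], pol).total))
    return out


def cross_scale_r2(observed: Mapping, predicted: Mapping) -> float:
    """Coefficient of determination against the 1:1 line.

    R² = 1 − Σ(pred − obs)² / Σ(obs − mean(obs))², over matched keys.
    This scores agreement with the diagonal, not a refitted slope. With
    zero variance in the observations the statistic is undefined and NaN
    is returned.
    """
    keys = sorted(observed)
    if set(keys) != set(predicted):
        raise ValueError(
            f"mismatched keys: {sorted(set(keys) ^ set(predicted))}"
        )
    if len(keys) < 2:
        raise ValueError("need at least two paired values")
    obs = np.array([observed[k] for k in keys], dtype=np.float64)
    pred = np.array([predicted[k] for k in keys], dtype=np.float64)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(((pred - obs) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class ValidationReport:
    """Conservation and 1:1 cross-scale comparison for one run."""

    rows: pd.DataFrame  # sector, pollutant, max_rel_err_spatial, ... r2
    max_spatial_rel_err: float
    max_temporal_rel_err: float
    fallback_warnings: list = field(default_factory=list)
    tolerance: float = CONSERVATION_RTOL

    @property
    def passed(self) -> bool:
        return (
            self.max_spatial_rel_err <= self.tolerance
            and self.max_temporal_rel_err <= self.tolerance
        )

    def to_text(self) -> str:
        lines = [
            "validation report",
            f"  spatial conservation: max relative error "
            f"{self.max_spatial_rel_err:.3e} (tolerance {self.tolerance:.0e})",
            f"  temporal conservation: max relative error "
            f"{self.max_temporal_rel_err:.3e}",
            f"  status: {'PASS' if self.passed else 'FAIL'}",
        ]
        for row in self.rows.itertuples():
            lines.append(
                f"  {row.sector:<11s} {row.pollutant}: "
                f"R2(1:1) = {row.r2:.6f}, "
                f"max spatial rel err = {row.max_rel_err:.3e}"
            )
        for w in self.fallback_warnings:
            lines.append(f"  note: {w}")
        return "\n".join(lines)


def _validate(
    totals: list[ProvinceSectorTotal],
    annual: GriddedInventory,
    monthly: MonthlyInventory,
    province_ids: Raster,
) -> ValidationReport:
    aggregated = aggregate_to_provinces(annual, province_ids)
    agg = {(t.province_id, t.sector, t.pollutant): t.mass for t in aggregated}
    rows = []
    max_spatial = 0.0
    for (sector, pollutant) in sorted(annual.data):
        obs = {
            t.province_id: t.mass
            for t in totals
            if t.sector == sector and t.pollutant == pollutant
        }
        pred = {p: agg.get((p, sector, pollutant), 0.0) for p in obs}
        errs = [
            abs(pred[p] - obs[p]) / max(obs[p], 1e-30) for p in obs
        ]
        max_err = max(errs) if errs else 0.0
        max_spatial = max(max_spatial, max_err)
        r2 = cross_scale_r2(obs, pred) if len(obs) >= 2 else float("nan")
        rows.append(
            {"sector": sector, "pollutant": pollutant,
             "max_rel_err": max_err, "r2": r2}
        )
    max_temporal = 0.0
    for key, stack in monthly.data.items():
        annual_vals = annual.data[key].filled(0.0)
        recomposed = stack.sum(axis=0)
        denom = np.maximum(np.abs(annual_vals), 1e-30)
        max_temporal = max(
            max_temporal, float(np.max(np.abs(recomposed - annual_vals) / denom))
        )
    warnings = []
    for sector, record in annual.provenance.get("weight_normalization", {}).items():
        for prov, method in record.items():
            if method != "proxy":
                warnings.append(
                    f"sector {sector}, province {prov}: fallback weights ({method})"
                )
    return ValidationReport(
        rows=pd.DataFrame(rows),
        max_spatial_rel_err=max_spatial,
        max_temporal_rel_err=max_temporal,
        fallback_warnings=warnings,
    )


@dataclass
class PipelineResult:
    totals: list
    annual: GriddedInventory
    monthly: MonthlyInventory
    report: ValidationReport


def run_stages(
    inputs: PipelineInputs,
    years: Sequence[int],
    pollutants=POLLUTANTS,
    sectors=SECTORS,
    amplitude: float = 0.2,
    provenance: dict | None = None,
) -> PipelineResult:
    """Run accounting, spatial and temporal stages on in-memory inputs.

    Only single-year runs produce gridded output (the grids are per-year
    layers); the accounting stage accepts any number of years.
    """
    totals = compute_totals(inputs.tables, years, pollutants, sectors)
    if len(years) != 1:
        raise ValueError("gridded stages run one year at a time")
    year = years[0]
    year_totals = [t for t in totals if t.year == year]

    sta_pop = _sta_pop_from_tables(inputs.tables, year)
    population = calibrate_population(
        inputs.reference_pop, inputs.province_ids, sta_pop
    )
    slope = slope_from_dem(inputs.dem)
    slope_coef = slope.with_values(slope_coefficient(slope.filled(0.0)))
    clay_coef = inputs.clay.with_values(clay_coefficient(inputs.clay.filled(0.0)))
    weights = {}
    for sector in sectors:
        mask = landuse_mask(inputs.landuse, sector)
        weights[sector] = build_weights(
            sector,
            mask,
            population=population,
            slope_coef=slope_coef,
            clay_coef=clay_coef,
            province_ids=inputs.province_ids,
        )
    annual = allocate(
        year_totals, weights, inputs.province_ids, year=year, provenance=provenance
    )
    monthly = apply_profiles(
        annual,
        inputs.climate,
        calendar=inputs.calendar,
        region_ids=inputs.region_ids,
        amplitude=amplitude,
    )
    report = _validate(year_totals, annual, monthly, inputs.province_ids)
    return PipelineResult(totals=totals, annual=annual, monthly=monthly, report=report)


def _sta_pop_from_tables(tables, year) -> dict:
    u = tables["urban"]
    r = tables["rural"]
    out: dict = {}
    for prov in sorted(set(u["province_id"])):
        up = u[(u.province_id == prov) & (u.year == year) & (u.parameter == "u_pop")]
        rp = r[(r.province_id == prov) & (r.year == year) & (r.parameter == "r_pop")]
        out[prov] = float(up["value"].iloc[0]) + float(rp["value"].iloc[0])
    return out


def _totals_frame(totals) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"province_id": t.province_id, "year": t.year,
             "pollutant": t.pollutant, "sector": t.sector, "mass_t": t.mass}
            for t in totals
        ]
    )


def write_outputs(result: PipelineResult, config: RunConfig) -> Path:
    """Write all declared outputs: totals CSVs, annual TIFFs, monthly
    NetCDF and the validation report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    df = _totals_frame(result.totals)
    df.to_csv(out / "province_sector_totals.csv", index=False)
    # Workbook-style export: one CSV per sector.
    sheets = out / "totals_by_sector"
    sheets.mkdir(exist_ok=True)
    for sector, grp in df.groupby("sector"):
        grp.to_csv(sheets / f"{sector}.csv", index=False)

    for (sector, pollutant), raster in sorted(result.annual.data.items()):
        write_raster(
            raster,
            out / f"annual_{sector}_{pollutant}_{result.annual.year}.tif",
            provenance=prov,
        )
    for pollutant in config.pollutants:
        try:
            total = result.annual.total(pollutant)
        except KeyError:
            continue
        write_raster(
            total, out / f"annual_total_{pollutant}_{result.annual.year}.tif",
            provenance=prov,
        )
    result.monthly.provenance.update(prov)
    write_monthly_nc(result.monthly, out / f"monthly_{result.monthly.year}.nc")
    result.report.rows.to_csv(out / "validation_report.csv", index=False)
    (out / "validation_report.txt").write_text(result.report.to_text() + "\n")
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full run from an input directory: load, compute, validate, write."""
    inputs, violations = load_inputs(config.input_dir)
    if violations:
        msgs = "\n".join(str(v) for v in violations)
        raise ValueError(f"input tables violate their schemas:\n{msgs}")
    result = run_stages(
        inputs,
        years=config.years,
        pollutants=config.pollutants,
        sectors=config.sectors,
        amplitude=config.amplitude_r,
        provenance=config.provenance(),
    )
    write_outputs(result, config)
    return result
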