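"""Self-contained synthetic scenarios for exercising the full pipeline.

A scenario is a toy landscape with the statistical structure the model
assumes: a few provinces tiling one grid, a categorical land-use map with
every class each sector needs, a clustered log-normal population field, a
smooth terrain and soil-clay field, a sinusoidal annual temperature cycle
and summer-peaked precipitation, and per-province sector parameter tables
drawn from realistic ranges. Every draw comes from one seeded generator,
so a scenario is reproducible bit-for-bit from its seed.

The fixtures target structure, not realism: magnitudes are plausible for
a mid-sized province but make no attempt to mimic any real region.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .accounting import (
    PASTORAL_SPECIES,
    POLLUTANTS,
    SPECIES,
    ProvinceSectorTotal,
    crop_discharge,
    industrial_discharge,
    livestock_discharge,
    rural_discharge,
    urban_discharge,
)
from .grids import Affine, Raster, FLOAT_NODATA, INT_NODATA
from .io import write_raster
from .tables import params_from_tables
from .temporal import ClimateStack, CropCalendar

__all__ = ["ScenarioSpec", "Scenario", "generate_scenario", "perturb_scenario"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Knobs of the synthetic world; defaults are the standard toy scale."""

    n_provinces: int = 3
    shape: tuple = (60, 60)
    cell_size: float = 1000.0  # metres
    years: tuple = (2020,)
    pollutants: tuple = POLLUTANTS
    # Land-use class shares: urban, rural residential, other construction,
    # cultivated, other.
    landuse_fractions: tuple = (0.05, 0.10, 0.05, 0.50, 0.30)
    dem_amplitude: float = 800.0  # metres of synthetic relief
    crs_label: str = "local-albers-equal-area"

    def __post_init__(self) -> None:
        if self.n_provinces < 1:
            raise ValueError("need at least one province")
        if min(self.shape) < 4:
            raise ValueError(f"grid {self.shape} too small")
        if abs(sum(self.landuse_fractions) - 1.0) > 1e-9:
            raise ValueError("landuse_fractions must sum to 1")
        if self.landuse_fractions[0] <= 0:
            raise ValueError("urban land fraction must be positive")


@dataclass
class Scenario:
    """A generated input set plus the ground-truth provincial totals."""

    spec: ScenarioSpec
    seed: int
    province_ids: Raster
    landuse: Raster
    reference_pop: Raster
    dem: Raster
    clay: Raster
    region_ids: Raster
    climate: ClimateStack
    calendar: CropCalendar
    tables: dict = field(default_factory=dict)  # sector -> tidy DataFrame
    ground_truth: list = field(default_factory=list)  # ProvinceSectorTotal

    @property
    def provinces(self) -> list[int]:
        ids = self.province_ids.values[self.province_ids.valid]
        return sorted(int(i) for i in np.unique(ids))

    def sta_pop(self, year: int) -> dict[int, float]:
        """Statistical (urban + rural) population per province."""
        out = {}
        for prov in self.provinces:
            u = self.tables["urban"]
            r = self.tables["rural"]
            u = u[(u.province_id == prov) & (u.year == year) & (u.parameter == "u_pop")]
            r = r[(r.province_id == prov) & (r.year == year) & (r.parameter == "r_pop")]
            out[prov] = float(u.value.iloc[0]) + float(r.value.iloc[0])
        return out

    def as_pipeline_inputs(self):
        """Package the in-memory layers as :class:`~nutrigrid.pipeline.PipelineInputs`."""
        from .pipeline import PipelineInputs

        return PipelineInputs(
            province_ids=self.province_ids,
            landuse=self.landuse,
            reference_pop=self.reference_pop,
            dem=self.dem,
            clay=self.clay,
            region_ids=self.region_ids,
            climate=self.climate,
            calendar=self.calendar,
            tables=self.tables,
        )

    def write(self, directory) -> Path:
        """Write the complete on-disk input set (rasters, climate, CSVs)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, raster in (
            ("province_ids", self.province_ids),
            ("landuse", self.landuse),
            ("reference_population", self.reference_pop),
            ("dem", self.dem),
            ("clay", self.clay),
            ("region_ids", self.region_ids),
        ):
            write_raster(raster, directory / f"{name}.tif")
        ds = xr.Dataset(
            {
                "temperature": (("month", "y", "x"),
                                self.climate.temperature.astype(np.float32),
                                {"units": "degC"}),
                "precipitation": (("month", "y", "x"),
                                  self.climate.precipitation.astype(np.float32),
                                  {"units": "mm"}),
            },
            coords={"month": np.arange(1, 13, dtype=np.int32)},
            attrs={
                "transform": str(list(self.climate.transform)),
                "crs_label": self.climate.crs_label,
                "nodata": float(self.climate.nodata),
            },
        )
        ds.to_netcdf(directory / "climate.nc", engine="scipy")
        for sector, df in self.tables.items():
            df.to_csv(directory / f"{sector}.csv", index=False)
        cal_rows = []
        for region, crops in self.calendar.regions.items():
            code = int(str(region).rsplit(":", 1)[1]) if ":" in str(region) else region
            for crop, (a, f) in crops.items():
                for m in range(12):
                    cal_rows.append(
                        {"region": code, "crop": crop, "month": m + 1,
                         "sown_share": a[m], "fert_share": f[m]}
                    )
        pd.DataFrame(cal_rows).to_csv(directory / "calendar.csv", index=False)
        gt = pd.DataFrame(
            [
                {"province_id": t.province_id, "year": t.year,
                 "pollutant": t.pollutant, "sector": t.sector, "mass_t": t.mass}
                for t in self.ground_truth
            ]
        )
        gt.to_csv(directory / "ground_truth.csv", index=False)
        return directory


def _voronoi_provinces(rng, shape, n_provinces) -> np.ndarray:
    ny, nx = shape
    seeds = rng.uniform(0, 1, size=(n_provinces, 2)) * [ny, nx]
    rows, cols = np.mgrid[0:ny, 0:nx]
    d = (rows[None] - seeds[:, 0, None, None]) ** 2 + (
        cols[None] - seeds[:, 1, None, None]
    ) ** 2
    return np.argmin(d, axis=0).astype(np.int64) + 1  # province ids 1..n


def _landuse(rng, shape, fractions, province_grid) -> np.ndarray:
    codes = rng.choice(
        np.arange(1, 6), size=shape, p=np.asarray(fractions)
    ).astype(np.int64)
    # Guarantee every province holds the classes its sectors need.
    for prov in np.unique(province_grid):
        cells = np.argwhere(province_grid == prov)
        need = [1, 2, 3, 4]
        picks = cells[rng.choice(len(cells), size=len(need) * 2, replace=False)]
        for k, code in enumerate(need):
            for j in range(2):
                r, c = picks[2 * k + j]
                codes[r, c] = code
    return codes


def _smooth_field(rng, shape, sigma=5.0) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")


def _population(rng, shape, landuse, province_grid) -> np.ndarray:
    base = np.exp(1.5 * _smooth_field(rng, shape, sigma=4.0))
    pop = 20.0 * base
    pop[landuse == 1] *= 200.0  # urban cores
    pop[landuse == 2] *= 30.0  # rural settlements
    return pop


def _climate(rng, spec: ScenarioSpec, transform) -> ClimateStack:
    ny, nx = spec.shape
    months = np.arange(12)
    # Annual temperature cycle peaking in July (index 6) over a smooth
    # spatial mean field; mild month-to-month noise.
    t_mean = 12.0 + 6.0 * _smooth_field(rng, spec.shape, sigma=8.0)
    t_amp = 12.0 + 2.0 * _smooth_field(rng, spec.shape, sigma=8.0)
    cycle = np.cos(2 * np.pi * (months[:, None, None] - 6) / 12.0)
    temperature = t_mean[None] + t_amp[None] * cycle + 0.5 * rng.standard_normal(
        (12, ny, nx)
    )
    # Summer-peaked precipitation, strictly non-negative.
    p_base = 60.0 * np.exp(0.8 * _smooth_field(rng, spec.shape, sigma=8.0))
    p_season = 1.0 + 0.85 * cycle
    precipitation = np.clip(
        p_base[None] * p_season * np.exp(0.2 * rng.standard_normal((12, ny, nx))),
        0.0,
        None,
    )
    return ClimateStack(
        temperature=temperature,
        precipitation=precipitation,
        transform=transform,
        crs_label=spec.crs_label,
    )


def _default_calendar() -> CropCalendar:
    """Two-region example: a grain region (spring/summer fertilization)
    and a double-cropping region with a second autumn application."""
    a_north = np.array([0, 0, .2, .6, 1, 1, 1, 1, .6, .2, 0, 0], dtype=float)
    f_north = np.array([0, 0, .1, .35, .3, .15, .1, 0, 0, 0, 0, 0], dtype=float)
    a_south1 = np.array([0, .3, .8, 1, 1, 1, .5, 0, 0, 0, 0, 0], dtype=float)
    f_south1 = np.array([0, .2, .4, .25, .15, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    a_south2 = np.array([0, 0, 0, 0, 0, .3, .8, 1, 1, 1, .4, 0], dtype=float)
    f_south2 = np.array([0, 0, 0, 0, 0, .25, .4, .2, .15, 0, 0, 0], dtype=float)
    return CropCalendar(
        regions={
            "north:1": {"spring_grain": (a_north, f_north)},
            "south:2": {"early_crop": (a_south1, f_south1),
                        "late_crop": (a_south2, f_south2)},
        }
    )


def _regions(shape) -> np.ndarray:
    """North half region 1, south half region 2."""
    ny, nx = shape
    out = np.ones(shape, dtype=np.int64)
    out[ny // 2:, :] = 2
    return out


def _urban_rows(rng, prov, year, pollutants):
    ur_treat = rng.uniform(0.55, 0.95)
    rows = [
        ("u_pop", None, rng.uniform(2e5, 2e6)),
        ("um_water", None, rng.uniform(80, 180)),
        ("ur_treat", None, ur_treat),
        ("ur_direct", None, rng.uniform(0.0, 1.0 - ur_treat)),
        ("ur_reuse", None, rng.uniform(0.0, 0.3)),
    ]
    conc = {"TN": (20, 45, 8, 16), "TP": (2, 5, 0.3, 1.0)}
    for pol in pollutants:
        lo_d, hi_d, lo_t, hi_t = conc[pol]
        rows.append(("uc_direct", pol, rng.uniform(lo_d, hi_d)))
        rows.append(("uc_treat", pol, rng.uniform(lo_t, hi_t)))
    return rows


def _rural_rows(rng, prov, year, pollutants):
    rr_dry = rng.uniform(0.2, 0.7)
    rm_direct = rng.uniform(0.3, 0.6)
    rows = [
        ("r_pop", None, rng.uniform(1e5, 1e6)),
        ("rr_dry", None, rr_dry),
        ("rr_flu", None, 1.0 - rr_dry),
        ("rm_direct", None, rm_direct),
        ("rm_treat", None, rng.uniform(0.0, 1.0 - rm_direct)),
        ("rm_removal", None, rng.uniform(0.3, 0.7)),
    ]
    gen = {"TN": (0.2, 0.5, 2.0, 4.0), "TP": (0.02, 0.06, 0.2, 0.5)}
    for pol in pollutants:
        lo_d, hi_d, lo_f, hi_f = gen[pol]
        rows.append(("rm_dry", pol, rng.uniform(lo_d, hi_d)))
        rows.append(("rm_flu", pol, rng.uniform(lo_f, hi_f)))
    return rows


def _industrial_rows(rng, prov, years, pollutants):
    span = range(min(years) - 4, max(years) + 1)
    gdp0 = rng.uniform(1e3, 1e4)
    rows = []
    gdp = {}
    for k, y in enumerate(span):
        gdp[y] = gdp0 * (1.0 + rng.uniform(0.04, 0.10)) ** k
        rows.append(("gdp", None, y, gdp[y]))
    base = {"TN": rng.uniform(5e3, 5e4), "TP": rng.uniform(2e2, 2e3)}
    for pol in pollutants:
        elasticity = rng.uniform(0.4, 0.9)
        for y in span:
            # Leave interior gaps so gap-filling is exercised; always
            # observe the first and last years of the span.
            if y not in (min(span), max(span)) and rng.uniform() < 0.4:
                continue
            value = base[pol] * (gdp[y] / gdp0) ** elasticity
            rows.append(("discharge", pol, y, value))
    return rows


def _crop_rows(rng, prov, year, pollutants):
    rows = [
        ("f_area", None, rng.uniform(1e5, 1e6)),
        ("f_fertilizer_2017", None, 1e5),
        ("f_fertilizer_y", None, 1e5 * rng.uniform(0.8, 1.3)),
    ]
    fm = {"TN": (1.0, 3.0), "TP": (0.1, 0.4)}
    for pol in pollutants:
        rows.append(("fm_2017", pol, rng.uniform(*fm[pol])))
    return rows


_HEADCOUNT = {
    "pig": (5e5, 5e6), "beef_cattle": (5e4, 5e5), "dairy_cow": (2e4, 2e5),
    "laying_hen": (2e6, 2e7), "broiler": (5e6, 5e7), "sheep": (2e5, 2e6),
}
_LM_TN = {
    "pig": (0.6, 1.2), "beef_cattle": (4.0, 8.0), "dairy_cow": (6.0, 12.0),
    "laying_hen": (0.01, 0.03), "broiler": (0.005, 0.015), "sheep": (0.8, 1.6),
}


def _livestock_rows(rng, prov, year, pollutants):
    rows = []
    for sp in SPECIES:
        lr_pst = rng.uniform(0.1, 0.5) if sp in PASTORAL_SPECIES else 0.0
        lr_c = rng.uniform(0.3, 0.7)
        rows.append((sp, "l_num", None, rng.uniform(*_HEADCOUNT[sp])))
        rows.append((sp, "lr_pst", None, lr_pst))
        rows.append((sp, "lr_centralized", None, lr_c))
        rows.append((sp, "lr_free", None, rng.uniform(0.0, 1.0 - lr_c)))
        for pol in pollutants:
            lo, hi = _LM_TN[sp]
            scale = 1.0 if pol == "TN" else 0.15
            rows.append((sp, "lm_centralized", pol, rng.uniform(lo, hi) * scale * 0.3))
            rows.append((sp, "lm_free", pol, rng.uniform(lo, hi) * scale * 0.6))
    return rows


def _make_tables(rng, provinces, spec: ScenarioSpec) -> dict[str, pd.DataFrame]:
    urban, rural, crop, industrial, livestock = [], [], [], [], []
    for prov in provinces:
        for year in spec.years:
            for param, pol, value in _urban_rows(rng, prov, year, spec.pollutants):
                urban.append((prov, year, param, value, pol))
            for param, pol, value in _rural_rows(rng, prov, year, spec.pollutants):
                rural.append((prov, year, param, value, pol))
            for param, pol, value in _crop_rows(rng, prov, year, spec.pollutants):
                crop.append((prov, year, param, value, pol))
            for sp, param, pol, value in _livestock_rows(
                rng, prov, year, spec.pollutants
            ):
                livestock.append((prov, year, param, value, pol, sp))
        for param, pol, year, value in _industrial_rows(
            rng, prov, spec.years, spec.pollutants
        ):
            industrial.append((prov, year, param, value, pol))
    cols = ["province_id", "year", "parameter", "value", "pollutant"]
    return {
        "urban": pd.DataFrame(urban, columns=cols),
        "rural": pd.DataFrame(rural, columns=cols),
        "industrial": pd.DataFrame(industrial, columns=cols),
        "crop": pd.DataFrame(crop, columns=cols),
        "livestock": pd.DataFrame(livestock, columns=cols + ["species"]),
    }


def compute_ground_truth(
    tables: Mapping[str, pd.DataFrame], years, pollutants
) -> list[ProvinceSectorTotal]:
    """Provincial sector totals implied by the tables (accounting oracle)."""
    params = params_from_tables(tables, years)
    out = []
    for (prov, year), p in params.items():
        for pol in pollutants:
            out.append(ProvinceSectorTotal(
                prov, year, pol, "urban", urban_discharge(p["urban"], pol).total))
            out.append(ProvinceSectorTotal(
                prov, year, pol, "rural", rural_discharge(p["rural"], pol).total))
            out.append(ProvinceSectorTotal(
                prov, year, pol, "industrial",
                industrial_discharge(p["industrial"], year, pol).mass))
            out.append(ProvinceSectorTotal(
                prov, year, pol, "crop", crop_discharge(p["crop"], pol, year)))
            out.append(ProvinceSectorTotal(
                prov, year, pol, "livestock",
                livestock_discharge(p["livestock"], pol).total))
    return out


def generate_scenario(seed: int, spec: ScenarioSpec | None = None) -> Scenario:
    """Generate a complete, self-consistent synthetic input set.

    All randomness flows from one ``numpy.random.default_rng(seed)``; the
    same seed reproduces the scenario bit-for-bit.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(seed)
    transform = Affine.from_origin(0.0, spec.shape[0] * spec.cell_size,
                                   spec.cell_size, spec.cell_size)

    province_grid = _voronoi_provinces(rng, spec.shape, spec.n_provinces)
    landuse_grid = _landuse(rng, spec.shape, spec.landuse_fractions, province_grid)
    pop_grid = _population(rng, spec.shape, landuse_grid, province_grid)
    dem_grid = 500.0 + spec.dem_amplitude * _smooth_field(rng, spec.shape, sigma=3.0)
    clay_field = _smooth_field(rng, spec.shape, sigma=6.0)
    lo, hi = clay_field.min(), clay_field.max()
    clay_grid = 5.0 + 90.0 * (clay_field - lo) / max(hi - lo, 1e-12)
    climate = _climate(rng, spec, transform)
    region_grid = _regions(spec.shape)

    def as_raster(values, nodata=FLOAT_NODATA):
        return Raster(values, transform, spec.crs_label, nodata=nodata)

    provinces = sorted(int(i) for i in np.unique(province_grid))
    tables = _make_tables(rng, provinces, spec)
    ground_truth = compute_ground_truth(tables, spec.years, spec.pollutants)

    return Scenario(
        spec=spec,
        seed=seed,
        province_ids=as_raster(province_grid, nodata=INT_NODATA),
        landuse=as_raster(landuse_grid, nodata=INT_NODATA),
        reference_pop=as_raster(pop_grid),
        dem=as_raster(dem_grid),
        clay=as_raster(clay_grid),
        region_ids=as_raster(region_grid, nodata=INT_NODATA),
        climate=climate,
        calendar=_default_calendar(),
        tables=tables,
        ground_truth=ground_truth,
    )


#: Recognized perturbation knobs: table, parameter and how ``delta``
#: applies ("scale" multiplies the value, "shift" adds to it, clipped to
#: [0, 1] for fractions).
_KNOBS = {
    "u_pop": ("urban", "scale"),
    "um_water": ("urban", "scale"),
    "ur_reuse": ("urban", "shift"),
    "r_pop": ("rural", "scale"),
    "rm_removal": ("rural", "shift"),
    "f_area": ("crop", "scale"),
    "f_fertilizer_y": ("crop", "scale"),
    "l_num": ("livestock", "scale"),
}


def perturb_scenario(scenario: Scenario, parameter: str, delta: float) -> Scenario:
    """Return a copy of the scenario with one knob changed everywhere.

    ``delta`` multiplies quantity knobs (population, headcount, area,
    fertilizer) and shifts fraction knobs (reuse, removal rates), with
    fractions clipped to [0, 1]. Ground truth is recomputed.
    """
    if parameter not in _KNOBS:
        raise KeyError(
            f"unknown knob {parameter!r}; recognized: {sorted(_KNOBS)}"
        )
    table, mode = _KNOBS[parameter]
    tables = {k: df.copy() for k, df in scenario.tables.items()}
    df = tables[table]
    sel = df["parameter"] == parameter
    if mode == "scale":
        df.loc[sel, "value"] *= delta
    else:
        df.loc[sel, "value"] = np.clip(df.loc[sel, "value"] + delta, 0.0, 1.0)
    ground_truth = compute_ground_truth(
        tables, scenario.spec.years, scenario.spec.pollutants
    )
    return replace(scenario, tables=tables, ground_truth=ground_truth)
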