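"""Readers/writers for the package's external formats.

Rasters travel as single-band TIFF files (float32 values, int32
categories) with the grid geometry, nodata sentinel and run provenance
embedded as a JSON document in the TIFF ImageDescription tag. Monthly
stacks travel as NetCDF files with dimensions (month, y, x), one variable
per ``<sector>_<pollutant>``. Statistics come in as tidy CSV tables
(comma-separated, UTF-8, header row) validated against declared schemas.

Values are float64 in memory and float32 on disk; conservation checks run
in memory before the cast.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from . import __version__
from .grids import Affine, Raster
from .temporal import MonthlyInventory

__all__ = [
    "read_raster",
    "write_raster",
    "read_monthly_nc",
    "write_monthly_nc",
    "TableSchema",
    "SchemaViolation",
    "SchemaError",
    "read_tables",
    "RunConfig",
    "load_config",
    "provenance_record",
]

log = logging.getLogger(__name__)

_META_KEY = "nutrigrid"


def provenance_record(config_hash: str = "", seed: int | None = None) -> dict:
    """Run provenance embedded in every output file."""
    return {
        "software": f"nutrigrid {__version__}",
        "config_hash": config_hash,
        "seed": seed,
    }


def write_raster(raster: Raster, path, provenance: dict | None = None) -> Path:
    """Write a single-band raster as TIFF (float32, or int32 for categories)."""
    path = Path(path)
    values = raster.values
    if np.issubdtype(values.dtype, np.integer):
        disk = values.astype(np.int32)
    else:
        disk = values.astype(np.float32)
    meta = {
        _META_KEY: {
            "transform": list(raster.transform),
            "crs_label": raster.crs_label,
            "nodata": raster.nodata,
            "provenance": provenance or provenance_record(),
        }
    }
    tifffile.imwrite(path, disk, description=json.dumps(meta))
    return path


def read_raster(path, expected_geometry: tuple | None = None) -> Raster:
    """Read a single-band TIFF raster written by :func:`write_raster`.

    ``expected_geometry`` is an optional ``(shape, Affine)`` contract;
    a mismatch raises with both geometries spelled out.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single band, found {len(tif.pages)}")
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(
                f"{path}: expected a single band, found data of shape {values.shape}"
            )
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value).get(_META_KEY, {})
            except (json.JSONDecodeError, AttributeError):
                meta = {}
    if not meta:
        raise ValueError(f"{path}: missing grid-geometry metadata tag")
    transform = Affine(*meta["transform"])
    nodata = meta["nodata"]
    if np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.int64)
        nodata = int(nodata)
    else:
        values = values.astype(np.float64)
    raster = Raster(values, transform, meta.get("crs_label", ""), nodata=nodata)
    if expected_geometry is not None:
        shape, xf = expected_geometry
        if raster.shape != tuple(shape) or raster.transform != Affine(*xf):
            raise ValueError(
                f"{path}: geometry mismatch — expected shape {tuple(shape)} / "
                f"transform {Affine(*xf)}, found shape {raster.shape} / "
                f"transform {raster.transform}"
            )
    return raster


def _var_name(sector: str, pollutant: str) -> str:
    return f"{sector}_{pollutant}"


def write_monthly_nc(inv: MonthlyInventory, path) -> Path:
    """Write a monthly inventory as NetCDF with dimensions (month, y, x)."""
    path = Path(path)
    data_vars = {}
    for (sector, pollutant), stack in sorted(inv.data.items()):
        data_vars[_var_name(sector, pollutant)] = (
            ("month", "y", "x"),
            stack.astype(np.float32),
            {"units": inv.units, "sector": sector, "pollutant": pollutant},
        )
    ds = xr.Dataset(
        data_vars,
        coords={"month": np.arange(1, 13, dtype=np.int32)},
        attrs={
            "transform": json.dumps(list(inv.transform)),
            "crs_label": inv.crs_label,
            "nodata": float(inv.nodata),
            "year": inv.year,
            "amplitude_R": inv.amplitude,
            "units": inv.units,
            "provenance": json.dumps(inv.provenance, default=str),
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_monthly_nc(path) -> MonthlyInventory:
    """Read a monthly inventory NetCDF written by :func:`write_monthly_nc`."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    if "month" not in ds.dims:
        raise ValueError(f"{path}: missing 'month' dimension")
    if ds.sizes["month"] != 12:
        raise ValueError(f"{path}: month dimension must be 12, got {ds.sizes['month']}")
    if "units" not in ds.attrs:
        warnings.warn(f"{path}: missing 'units' attribute", stacklevel=2)
    data = {}
    for name, var in ds.data_vars.items():
        sector = var.attrs.get("sector")
        pollutant = var.attrs.get("pollutant")
        if sector is None or pollutant is None:
            sector, pollutant = name.rsplit("_", 1)
        data[(sector, pollutant)] = np.asarray(var.values, dtype=np.float64)
    provenance = {}
    if "provenance" in ds.attrs:
        try:
            provenance = json.loads(ds.attrs["provenance"])
        except json.JSONDecodeError:
            provenance = {"raw": ds.attrs["provenance"]}
    return MonthlyInventory(
        data=data,
        transform=Affine(*json.loads(ds.attrs["transform"])),
        crs_label=str(ds.attrs.get("crs_label", "")),
        nodata=float(ds.attrs.get("nodata", -9999.0)),
        year=int(ds.attrs.get("year", 0)),
        amplitude=float(ds.attrs.get("amplitude_R", 0.2)),
        units=str(ds.attrs.get("units", "t cell-1 month-1")),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# CSV parameter tables


@dataclass(frozen=True)
class TableSchema:
    """Declared shape of one tidy parameter CSV.

    ``ranges`` maps a parameter name to its (min, max) bounds;
    ``share_sums`` lists groups of parameters whose values must sum to a
    target within a tolerance (checked per province-year).
    """

    name: str
    required_columns: tuple = ("province_id", "year", "parameter", "value")
    ranges: Mapping[str, tuple] = field(default_factory=dict)
    share_sums: Sequence[tuple] = ()  # (params tuple, target, tol)


@dataclass(frozen=True)
class SchemaViolation:
    file: str
    row: int | None
    column: str
    message: str

    def __str__(self) -> str:
        where = f"{self.file}" + (f", row {self.row}" if self.row is not None else "")
        return f"{where}, column {self.column!r}: {self.message}"


class SchemaError(ValueError):
    """A structural defect (missing file/column) that prevents parsing."""


def read_tables(
    directory, schemas: Sequence[TableSchema]
) -> tuple[dict[str, pd.DataFrame], list[SchemaViolation]]:
    """Read and validate one CSV per schema from ``directory``.

    Structural defects (missing file or required column) raise
    :class:`SchemaError` naming file and column. Range and share-sum
    violations are collected — not fail-fast — and returned alongside the
    parsed tables.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    violations: list[SchemaViolation] = []
    for schema in schemas:
        path = directory / f"{schema.name}.csv"
        if not path.exists():
            raise SchemaError(f"{path}: table file missing")
        df = pd.read_csv(path, encoding="utf-8")
        for col in schema.required_columns:
            if col not in df.columns:
                raise SchemaError(f"{path.name}: missing required column {col!r}")
        for idx, row in df.iterrows():
            param = row["parameter"]
            bounds = schema.ranges.get(param)
            if bounds is None:
                continue
            lo, hi = bounds
            v = row["value"]
            if not np.isfinite(v) or v < lo or (hi is not None and v > hi):
                violations.append(
                    SchemaViolation(
                        path.name, int(idx), "value",
                        f"{param} = {v} outside [{lo}, {hi}]",
                    )
                )
        for params, target, tol in schema.share_sums:
            group_cols = ["province_id", "year"]
            if "pollutant" in df.columns:
                group_cols.append("pollutant")
            sub = df[df["parameter"].isin(params)]
            for key, grp in sub.groupby(group_cols, dropna=False):
                total = grp["value"].sum()
                if abs(total - target) > tol:
                    violations.append(
                        SchemaViolation(
                            path.name, int(grp.index[0]), "value",
                            f"{' + '.join(params)} = {total} != {target} "
                            f"(tolerance {tol}) for {key}",
                        )
                    )
        tables[schema.name] = df
    return tables, violations


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    input_dir: Path
    output_dir: Path
    years: tuple = (2020,)
    pollutants: tuple = ("TN", "TP")
    sectors: tuple = ("urban", "rural", "industrial", "crop", "livestock")
    amplitude_r: float = 0.2
    boundary_convention: str = "lower-inclusive"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.years = tuple(int(y) for y in self.years)
        self.pollutants = tuple(self.pollutants)
        self.sectors = tuple(self.sectors)
        if not self.input_dir.exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")
        if self.amplitude_r < 0:
            raise ValueError(f"amplitude_r must be >= 0, got {self.amplitude_r}")
        if self.boundary_convention != "lower-inclusive":
            raise ValueError(
                "only the lower-inclusive bin-boundary convention is implemented"
            )

    @property
    def config_hash(self) -> str:
        # Hash of the scientific configuration only; file-system paths do
        # not affect the result, so reruns into a new directory stay
        # byte-identical.
        payload = {
            "years": self.years, "pollutants": self.pollutants,
            "sectors": self.sectors, "amplitude_r": self.amplitude_r,
            "boundary_convention": self.boundary_convention, "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def provenance(self) -> dict:
        return provenance_record(self.config_hash, self.seed)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
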