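"""Schemas for the tidy sector CSVs and construction of typed parameters.

Each sector ships one tidy CSV with columns ``province_id, year,
parameter, value`` and, for per-pollutant coefficients, ``pollutant``.
The schemas here drive :func:`nutrigrid.io.read_tables`; the builders
turn validated tables into the accounting module's parameter objects.
"""
from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .accounting import (
    POLLUTANTS,
    SPECIES,
    CropParams,
    IndustrySeries,
    LivestockParams,
    RuralParams,
    SpeciesParams,
    UrbanParams,
)
from .io import SchemaError, TableSchema

__all__ = ["DEFAULT_SCHEMAS", "ProvinceParams", "params_from_tables"]

_FRACTION = (0.0, 1.0)
_NONNEG = (0.0, None)

DEFAULT_SCHEMAS: tuple[TableSchema, ...] = (
    TableSchema(
        name="urban",
        ranges={
            "u_pop": _NONNEG, "um_water": _NONNEG,
            "ur_direct": _FRACTION, "ur_treat": _FRACTION, "ur_reuse": _FRACTION,
            "uc_direct": _NONNEG, "uc_treat": _NONNEG,
        },
    ),
    TableSchema(
        name="rural",
        ranges={
            "r_pop": _NONNEG,
            "rr_dry": _FRACTION, "rr_flu": _FRACTION,
            "rm_dry": _NONNEG, "rm_flu": _NONNEG,
            "rm_direct": _FRACTION, "rm_treat": _FRACTION, "rm_removal": _FRACTION,
        },
        share_sums=((("rr_dry", "rr_flu"), 1.0, 1e-6),),
    ),
    TableSchema(
        name="industrial",
        ranges={"gdp": (1e-12, None), "discharge": _NONNEG},
    ),
    TableSchema(
        name="crop",
        ranges={
            "f_area": _NONNEG, "fm_2017": _NONNEG,
            "f_fertilizer_y": _NONNEG, "f_fertilizer_2017": (1e-12, None),
        },
    ),
    TableSchema(
        name="livestock",
        required_columns=("province_id", "year", "parameter", "value", "species"),
        ranges={
            "l_num": _NONNEG, "lr_pst": _FRACTION,
            "lr_centralized": _FRACTION, "lr_free": _FRACTION,
            "lm_centralized": _NONNEG, "lm_free": _NONNEG,
        },
    ),
)


class ProvinceParams(dict):
    """Per-(province, year) parameter objects keyed by sector name."""


def _scalar(df: pd.DataFrame, param: str, context: str) -> float:
    rows = df[df["parameter"] == param]
    if rows.empty:
        raise SchemaError(f"{context}: parameter {param!r} missing")
    return float(rows["value"].iloc[0])


def _per_pollutant(df: pd.DataFrame, param: str, context: str) -> dict[str, float]:
    rows = df[df["parameter"] == param]
    out = {}
    for pol in POLLUTANTS:
        sel = rows[rows["pollutant"] == pol]
        if sel.empty:
            raise SchemaError(f"{context}: parameter {param!r} missing for {pol}")
        out[pol] = float(sel["value"].iloc[0])
    return out


def _industry_series(df: pd.DataFrame, province, context: str) -> IndustrySeries:
    sub = df[df["province_id"] == province]
    gdp_rows = sub[sub["parameter"] == "gdp"]
    if gdp_rows.empty:
        raise SchemaError(f"{context}: no GDP series")
    gdp = {int(r.year): float(r.value) for r in gdp_rows.itertuples()}
    discharge: dict[str, dict[int, float]] = {}
    for r in sub[sub["parameter"] == "discharge"].itertuples():
        pol = r.pollutant
        if isinstance(pol, float) and math.isnan(pol):
            raise SchemaError(f"{context}: discharge row without pollutant")
        discharge.setdefault(str(pol), {})[int(r.year)] = float(r.value)
    if not discharge:
        raise SchemaError(f"{context}: no observed industrial discharge")
    return IndustrySeries(years=sorted(gdp), gdp=gdp, discharge=discharge)


def params_from_tables(
    tables: Mapping[str, pd.DataFrame], years, provinces=None
) -> dict[tuple, ProvinceParams]:
    """Build typed sector parameters for every (province, year) requested.

    Returns ``{(province_id, year): ProvinceParams}`` where each value
    maps sector name to its parameter object (the industrial entry is the
    province's full :class:`IndustrySeries`, shared across years).
    """
    if provinces is None:
        provinces = sorted(
            set().union(*(set(df["province_id"]) for df in tables.values()))
        )
    out: dict[tuple, ProvinceParams] = {}
    industry_cache: dict = {}
    for province in provinces:
        for year in years:
            ctx = f"province {province}, year {year}"
            p = ProvinceParams()
            u = tables["urban"]
            u = u[(u["province_id"] == province) & (u["year"] == year)]
            p["urban"] = UrbanParams(
                u_pop=_scalar(u, "u_pop", ctx),
                um_water=_scalar(u, "um_water", ctx),
                ur_direct=_scalar(u, "ur_direct", ctx),
                ur_treat=_scalar(u, "ur_treat", ctx),
                ur_reuse=_scalar(u, "ur_reuse", ctx),
                uc_direct=_per_pollutant(u, "uc_direct", ctx),
                uc_treat=_per_pollutant(u, "uc_treat", ctx),
            )
            r = tables["rural"]
            r = r[(r["province_id"] == province) & (r["year"] == year)]
            p["rural"] = RuralParams(
                r_pop=_scalar(r, "r_pop", ctx),
                rr_dry=_scalar(r, "rr_dry", ctx),
                rr_flu=_scalar(r, "rr_flu", ctx),
                rm_dry=_per_pollutant(r, "rm_dry", ctx),
                rm_flu=_per_pollutant(r, "rm_flu", ctx),
                rm_direct=_scalar(r, "rm_direct", ctx),
                rm_treat=_scalar(r, "rm_treat", ctx),
                rm_removal=_scalar(r, "rm_removal", ctx),
            )
            if province not in industry_cache:
                industry_cache[province] = _industry_series(
                    tables["industrial"], province, ctx
                )
            p["industrial"] = industry_cache[province]
            c = tables["crop"]
            c = c[(c["province_id"] == province) & (c["year"] == year)]
            p["crop"] = CropParams(
                f_area=_scalar(c, "f_area", ctx),
                fm_2017=_per_pollutant(c, "fm_2017", ctx),
                f_fertilizer_y=_scalar(c, "f_fertilizer_y", ctx),
                f_fertilizer_2017=_scalar(c, "f_fertilizer_2017", ctx),
            )
            lv = tables["livestock"]
            lv = lv[(lv["province_id"] == province) & (lv["year"] == year)]
            species = {}
            for sp in SPECIES:
                sub = lv[lv["species"] == sp]
                if sub.empty:
                    continue
                species[sp] = SpeciesParams(
                    l_num=_scalar(sub, "l_num", f"{ctx}, species {sp}"),
                    lr_pst=_scalar(sub, "lr_pst", f"{ctx}, species {sp}"),
                    lr_centralized=_scalar(
                        sub, "lr_centralized", f"{ctx}, species {sp}"
                    ),
                    lr_free=_scalar(sub, "lr_free", f"{ctx}, species {sp}"),
                    lm_centralized=_per_pollutant(
                        sub, "lm_centralized", f"{ctx}, species {sp}"
                    ),
                    lm_free=_per_pollutant(sub, "lm_free", f"{ctx}, species {sp}"),
                )
            p["livestock"] = LivestockParams(species=species)
            out[(province, year)] = p
    return out
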