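"""Reading and writing of cast tables (delimited text, one row per level).

The canonical interchange format is a UTF-8 comma-separated table with a
mandatory header::

    cast_id, fjord, zone, date, depth_m, temp_C, sal_psu, pH,
    dpm_light_mean, dpm_dark_mean, dpm_added,
    chl_A665, chl_A750, extract_vol_ml, filtered_vol_l, cuvette_cm

plus an optional ``exposure_hours`` column (default 2 h).  Bottle or
pigment cells may be left empty: such levels are kept for hydrography but
excluded from the production or chlorophyll computation, with a log entry.

Reading refuses tables that already contain pipeline *output* columns
(``pe_mgC_m3_h`` etc.) — re-running the pipeline on its own outputs would
silently double unit scalings.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .profiles import BottleSet, Cast, Level, PigmentSample

__all__ = ["read_casts", "write_casts", "CastTableError",
           "CAST_COLUMNS", "OUTPUT_ONLY_COLUMNS"]

log = logging.getLogger("fjordpp")

CAST_COLUMNS = [
    "cast_id", "fjord", "zone", "date", "depth_m", "temp_C", "sal_psu", "pH",
    "dpm_light_mean", "dpm_dark_mean", "dpm_added",
    "chl_A665", "chl_A750", "extract_vol_ml", "filtered_vol_l", "cuvette_cm",
]
NUMERIC_COLUMNS = CAST_COLUMNS[4:]
OUTPUT_ONLY_COLUMNS = {
    "pe_mgC_m3_h", "chl_mgm3", "total_co2_mM", "pi_mgC_m2_day", "water_mass",
}


class CastTableError(ValueError):
    pass


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def read_casts(path) -> list[Cast]:
    """Parse a cast table into typed, validated casts.

    Malformed rows are reported with their 1-based file line numbers; any
    such row aborts the read.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CAST_COLUMNS if c not in df.columns]
    if missing:
        raise CastTableError(f"{path}: missing mandatory column(s) {missing}")
    contaminated = OUTPUT_ONLY_COLUMNS.intersection(df.columns)
    if contaminated:
        raise CastTableError(
            f"{path}: contains pipeline output column(s) {sorted(contaminated)}; "
            "refusing to re-process pipeline output as input"
        )
    for col in NUMERIC_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise CastTableError(
                    f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
                )
            df[col] = coerced

    errors: list[str] = []
    casts: list[Cast] = []
    for cast_id, group in df.groupby("cast_id", sort=False):
        group = group.sort_values("depth_m")
        levels = []
        fjord = str(group["fjord"].iloc[0])
        zone = str(group["zone"].iloc[0])
        date = str(group["date"].iloc[0])
        for idx, row in group.iterrows():
            line = idx + 2  # header + 1-based
            try:
                bottles = None
                if not any(_is_missing(row[c]) for c in
                           ("dpm_light_mean", "dpm_dark_mean", "dpm_added")):
                    bottles = BottleSet(
                        dpm_light=(float(row["dpm_light_mean"]),),
                        dpm_dark=(float(row["dpm_dark_mean"]),),
                        dpm_added=float(row["dpm_added"]),
                        exposure_hours=float(row.get("exposure_hours", 2.0))
                        if not _is_missing(row.get("exposure_hours")) else 2.0,
                    )
                else:
                    log.info("cast %s line %d: no bottle data; level kept for T/S only",
                             cast_id, line)
                chl = None
                if not any(_is_missing(row[c]) for c in
                           ("chl_A665", "chl_A750", "extract_vol_ml",
                            "filtered_vol_l", "cuvette_cm")):
                    chl = PigmentSample(
                        A665=float(row["chl_A665"]), A750=float(row["chl_A750"]),
                        extract_vol_ml=float(row["extract_vol_ml"]),
                        filtered_vol_l=float(row["filtered_vol_l"]),
                        cuvette_cm=float(row["cuvette_cm"]),
                    )
                levels.append(Level(
                    depth_m=float(row["depth_m"]),
                    temperature_C=float(row["temp_C"]),
                    salinity_psu=float(row["sal_psu"]),
                    pH=None if _is_missing(row["pH"]) else float(row["pH"]),
                    bottles=bottles,
                    chl_inputs=chl,
                ))
            except ValueError as exc:
                errors.append(f"line {line} (cast {cast_id}): {exc}")
        if errors:
            continue
        try:
            casts.append(Cast(cast_id=str(cast_id), fjord=fjord, zone=zone,
                              date_utc=date, levels=levels))
        except ValueError as exc:
            errors.append(f"cast {cast_id}: {exc}")
    if errors:
        raise CastTableError(f"{path}: " + "; ".join(errors))
    return casts


def write_casts(casts: list[Cast], path) -> None:
    """Write casts to the canonical table (replicate bottle activities are
    written as their means, matching the schema)."""
    rows = []
    for cast in casts:
        for lv in cast.levels:
            b, c = lv.bottles, lv.chl_inputs
            rows.append({
                "cast_id": cast.cast_id, "fjord": cast.fjord, "zone": cast.zone,
                "date": cast.date_utc, "depth_m": lv.depth_m,
                "temp_C": lv.temperature_C, "sal_psu": lv.salinity_psu,
                "pH": lv.pH,
                "dpm_light_mean": sum(b.dpm_light) / len(b.dpm_light) if b else None,
                "dpm_dark_mean": sum(b.dpm_dark) / len(b.dpm_dark) if b else None,
                "dpm_added": b.dpm_added if b else None,
                "exposure_hours": b.exposure_hours if b else None,
                "chl_A665": c.A665 if c else None,
                "chl_A750": c.A750 if c else None,
                "extract_vol_ml": c.extract_vol_ml if c else None,
                "filtered_vol_l": c.filtered_vol_l if c else None,
                "cuvette_cm": c.cuvette_cm if c else None,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
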