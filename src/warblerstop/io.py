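"""Readers and writers for the study's plain-text interchange formats.

* ``birds.csv`` — one banding row per bird: id, day_of_year, year, sex,
  age, wing_chord_mm, body_mass_g, d2h_feather.
* ``plasma.csv`` — id, triglyceride, bohb (mmol/L), bleedtime (min),
  daytime (min since sunrise), day_of_year, year.
* encounter histories — MARK-style ``.inp`` (``/* id */ 110010000 1;``)
  or a tidy CSV with ``occ1..occN`` columns plus covariates.
* isoscape grids — ESRI ASCII (.asc) or long-format lon/lat/value CSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cjs import CaptureHistory
from .isotopes import IsoscapeGrid

__all__ = [
    "BIRD_COLUMNS",
    "PLASMA_COLUMNS",
    "read_birds",
    "write_birds",
    "read_plasma",
    "write_plasma",
    "read_inp",
    "write_inp",
    "read_histories_csv",
    "write_histories_csv",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_grid_csv",
    "write_grid_csv",
]

BIRD_COLUMNS = [
    "bird_id",
    "day_of_year",
    "year",
    "sex",
    "age",
    "wing_chord_mm",
    "body_mass_g",
    "d2h_feather",
]

PLASMA_COLUMNS = [
    "bird_id",
    "triglyceride",
    "bohb",
    "bleedtime",
    "daytime",
    "day_of_year",
    "year",
]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} missing columns: {missing}")


def read_birds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, BIRD_COLUMNS, "bird table")
    return df


def write_birds(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, BIRD_COLUMNS, "bird table")
    df.to_csv(path, index=False, float_format="%.6g")


def read_plasma(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PLASMA_COLUMNS, "plasma table")
    return df


def write_plasma(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, PLASMA_COLUMNS, "plasma table")
    df.to_csv(path, index=False, float_format="%.6g")


# ------------------------------------------------------------ histories

_INP_LINE = re.compile(
    r"^\s*(?:/\*\s*(?P<id>[^*]*?)\s*\*/)?\s*(?P<hist>[01]+)\s+(?P<freq>\d+)\s*;\s*$"
)


def read_inp(path: str | Path) -> list[CaptureHistory]:
    """Parse a MARK-dialect .inp encounter-history file."""
    out: list[CaptureHistory] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        m = _INP_LINE.match(line)
        if not m:
            raise ValueError(f"{path}: cannot parse line {i + 1}: {line!r}")
        hist = np.array([int(c) for c in m.group("hist")])
        bird_id = m.group("id") or f"row{i + 1}"
        for rep in range(int(m.group("freq"))):
            rid = bird_id if rep == 0 else f"{bird_id}.{rep + 1}"
            out.append(CaptureHistory(rid, hist.copy()))
    return out


def write_inp(histories: list[CaptureHistory], path: str | Path) -> None:
    lines = [
        f"/* {h.bird_id} */ {''.join(map(str, h.detections))} 1;"
        for h in histories
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_histories_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_histories_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    occ = [c for c in df.columns if re.fullmatch(r"occ\d+", c)]
    if not occ:
        raise ValueError("histories CSV needs occ1..occN columns")
    return df


def histories_from_frame(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Split a tidy histories frame into (detection matrix, covariates)."""
    occ = sorted(
        (c for c in df.columns if re.fullmatch(r"occ\d+", c)),
        key=lambda c: int(c[3:]),
    )
    det = df[occ].to_numpy(dtype=int)
    cov = df.drop(columns=occ).reset_index(drop=True)
    return det, cov


# ------------------------------------------------------------- isoscape


def read_esri_ascii(path: str | Path) -> IsoscapeGrid:
    """Read an ESRI ASCII grid (cell-center coordinates)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:
        x0, y0 = header["xllcorner"] + cell / 2, header["yllcorner"] + cell / 2
    values = np.loadtxt(text[data_start:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid shape {values.shape} != header ({nrows},{ncols})")
    values = values[::-1]  # ascii rows go north->south; store south->north
    values[values == nodata] = np.nan
    lons = x0 + cell * np.arange(ncols)
    lats = y0 + cell * np.arange(nrows)
    return IsoscapeGrid(lons=lons, lats=lats, values=values, cellsize=cell)


def write_esri_ascii(grid: IsoscapeGrid, path: str | Path, nodata: float = -9999.0) -> None:
    cell = grid.cellsize or (grid.lons[1] - grid.lons[0])
    vals = np.where(np.isfinite(grid.values), grid.values, nodata)[::-1]
    lines = [
        f"ncols {grid.lons.size}",
        f"nrows {grid.lats.size}",
        f"xllcorner {grid.lons[0] - cell / 2:.6f}",
        f"yllcorner {grid.lats[0] - cell / 2:.6f}",
        f"cellsize {cell:.6f}",
        f"NODATA_value {nodata:g}",
    ]
    lines += [" ".join(f"{v:.4f}" for v in row) for row in vals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid_csv(path: str | Path) -> IsoscapeGrid:
    """Read a long-format lon,lat,d2h_p CSV into a regular grid."""
    df = pd.read_csv(path)
    _require(df, ["lon", "lat", "d2h_p"], "grid CSV")
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())
    values = np.full((lats.size, lons.size), np.nan)
    li = {v: i for i, v in enumerate(lons)}
    la = {v: i for i, v in enumerate(lats)}
    for lon, lat, v in df[["lon", "lat", "d2h_p"]].itertuples(index=False):
        values[la[lat], li[lon]] = v
    return IsoscapeGrid(lons=lons, lats=lats, values=values)


def write_grid_csv(grid: IsoscapeGrid, path: str | Path) -> None:
    lon_m, lat_m = np.meshgrid(grid.lons, grid.lats)
    df = pd.DataFrame(
        {
            "lon": lon_m.ravel(),
            "lat": lat_m.ravel(),
            "d2h_p": grid.values.ravel(),
        }
    ).dropna()
    df.to_csv(path, index=False, float_format="%.6g")
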