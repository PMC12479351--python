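"""Raster and table I/O.

Rasters are stored as ESRI ASCII grids (.asc) — a plain-text, single-band
format with a 6-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) readable by every GIS. Values are written with 17 significant
digits so float64 surfaces round-trip bitwise. Categorical grids are written
as integer codes with a sidecar CSV legend (``<name>.legend.csv``), and
reading a categorical grid without its legend is an explicit error.

A :class:`~tripleland.benefits.BenefitMaps` stack is persisted as 12 grids
(category-major, objective-minor order) plus a parameter-snapshot CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .benefits import BenefitMaps
from .categories import (CATEGORY_NAMES, Category, N_CATEGORIES, N_OBJECTIVES,
                         OBJECTIVE_NAMES, Objective)
from .errors import AlignmentError, DataError

NODATA = -9999.0
DEFAULT_CELLSIZE = 500.0  # metres


def write_ascii_grid(path: str | Path, grid: np.ndarray, *,
                     cellsize: float = DEFAULT_CELLSIZE,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = NODATA,
                     mask: np.ndarray | None = None) -> Path:
    """Write one 2-D grid as an ESRI ASCII raster."""
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if mask is not None:
        grid = np.where(mask, grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n"
                 f"nrows {grid.shape[0]}\n"
                 f"xllcorner {xllcorner:.17g}\n"
                 f"yllcorner {yllcorner:.17g}\n"
                 f"cellsize {cellsize:.17g}\n"
                 f"NODATA_value {nodata:.17g}\n")
        for row in grid:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster; returns (array, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh, dtype=float)
    grid = np.atleast_2d(grid)
    shape = (int(header["nrows"]), int(header["ncols"]))
    if grid.shape != shape:
        raise AlignmentError(f"{path}: data shape {grid.shape} != header {shape}")
    return grid, header


def write_categorical_grid(path: str | Path, grid: np.ndarray,
                           legend: dict[int, str], **kw) -> Path:
    """Integer-coded raster plus a ``.legend.csv`` sidecar (code,name)."""
    path = Path(path)
    write_ascii_grid(path, grid.astype(float), **kw)
    leg = pd.DataFrame(sorted(legend.items()), columns=["code", "name"])
    leg.to_csv(path.with_suffix(".legend.csv"), index=False)
    return path


def read_categorical_grid(path: str | Path) -> tuple[np.ndarray, dict[int, str], dict]:
    """Read an integer-coded raster; requires the legend sidecar."""
    path = Path(path)
    legend_path = path.with_suffix(".legend.csv")
    if not legend_path.exists():
        raise DataError(f"categorical raster {path} has no legend {legend_path}")
    grid, header = read_ascii_grid(path)
    leg = pd.read_csv(legend_path)
    legend = dict(zip(leg["code"].astype(int), leg["name"]))
    return grid.astype(int), legend, header


def benefit_band_name(cat: Category, obj: Objective) -> str:
    return f"benefit_{CATEGORY_NAMES[cat]}_{OBJECTIVE_NAMES[obj]}"


def write_benefit_maps(out_dir: str | Path, maps: BenefitMaps) -> Path:
    """Persist a benefit stack: 12 grids + parameter snapshot + mask/use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cat in Category:
        for obj in Objective:
            write_ascii_grid(out / f"{benefit_band_name(cat, obj)}.asc",
                             maps.raw[cat, obj], mask=maps.convertible)
    write_categorical_grid(out / "current_use.asc", maps.current_use,
                           {int(c): CATEGORY_NAMES[c] for c in Category})
    write_ascii_grid(out / "convertible.asc", maps.convertible.astype(float))
    with open(out / "benefit_params.json", "w") as fh:
        json.dump({"cell_area_ha": maps.cell_area,
                   "provenance": maps.provenance}, fh, indent=2, default=str)
    return out


def read_benefit_maps(out_dir: str | Path) -> BenefitMaps:
    """Read back a persisted benefit stack; shapes must agree across bands."""
    out = Path(out_dir)
    conv, _ = read_ascii_grid(out / "convertible.asc")
    convertible = conv > 0.5
    current, _, _ = read_categorical_grid(out / "current_use.asc")
    raw = np.zeros((N_CATEGORIES, N_OBJECTIVES, *convertible.shape))
    for cat in Category:
        for obj in Objective:
            grid, _ = read_ascii_grid(out / f"{benefit_band_name(cat, obj)}.asc")
            if grid.shape != convertible.shape:
                raise AlignmentError(
                    f"band {benefit_band_name(cat, obj)} shape {grid.shape} "
                    f"!= {convertible.shape}")
            raw[cat, obj] = grid
    raw[:, :, ~convertible] = 0.0
    with open(out / "benefit_params.json") as fh:
        meta = json.load(fh)
    return BenefitMaps(raw=raw, convertible=convertible,
                       current_use=current.astype(np.int8),
                       cell_area=float(meta["cell_area_ha"]),
                       provenance=meta.get("provenance", {}))
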