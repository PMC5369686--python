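"""Raster, node-table and manifest I/O.

Cost rasters round-trip losslessly through two formats: ESRI ASCII grid
(plain text, the six-line header per the standard) and single-band uint16
TIFF (via tifffile; no CRS/geotransform tags are written, which is
sufficient for the unit-square landscapes used here).  Focal nodes are a
two-column CSV of 0-based (row, col) pixel indices, row-major from the
top-left.  Every CLI invocation emits a RunManifest (JSON) capturing the
resolved configuration and master seed so runs can be reproduced exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RasterFormatError
from .landscape import COST_MAX, COST_MIN, CostRaster, FocalNodes

__all__ = [
    "read_raster",
    "write_raster",
    "read_nodes",
    "write_nodes",
    "RunManifest",
]

_NODATA = -9999


def _validate_grid(values: np.ndarray, source: str) -> np.ndarray:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise RasterFormatError(
            f"{source}: raster is {values.shape[0]}x{values.shape[1]}, not square"
        )
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.rint(values)):
            raise RasterFormatError(f"{source}: raster holds non-integer values")
        values = np.rint(values).astype(np.int64)
    bad = (values < COST_MIN) | (values > COST_MAX)
    if bad.any():
        raise RasterFormatError(
            f"{source}: {int(bad.sum())} cell(s) outside [{COST_MIN}, {COST_MAX}]"
        )
    return values.astype(np.int64)


def write_raster(raster: CostRaster, path, format: str | None = None) -> None:
    """Write a cost raster as ESRI ASCII grid ('ascii') or uint16 TIFF ('geotiff').

    The format is inferred from the suffix (.asc/.txt vs .tif/.tiff) when
    not given explicitly.
    """
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii"
    if format in ("ascii", "ascii_grid"):
        dim = raster.dim
        header = (
            f"ncols {dim}\nnrows {dim}\nxllcorner 0.0\nyllcorner 0.0\n"
            f"cellsize {raster.resolution}\nNODATA_value {_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, raster.values, fmt="%d")
    elif format == "geotiff":
        import tifffile

        tifffile.imwrite(
            path,
            raster.values.astype(np.uint16),
            resolution=(1.0 / raster.resolution, 1.0 / raster.resolution),
        )
    else:
        raise ValueError(f"unknown raster format {format!r}")


def read_raster(path, format: str | None = None) -> CostRaster:
    """Read a cost raster written by :func:`write_raster` (lossless round-trip)."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii"
    if format in ("ascii", "ascii_grid"):
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                line = fh.readline().split()
                if len(line) != 2:
                    raise RasterFormatError(f"{path}: malformed ESRI ASCII header")
                header[line[0].lower()] = float(line[1])
            required = {"ncols", "nrows", "cellsize"}
            if not required <= header.keys():
                raise RasterFormatError(
                    f"{path}: header missing {sorted(required - header.keys())}"
                )
            values = np.loadtxt(fh, ndmin=2)
        if int(header["ncols"]) != int(header["nrows"]):
            raise RasterFormatError(
                f"{path}: ncols={int(header['ncols'])} != nrows={int(header['nrows'])},"
                " cost rasters must be square"
            )
        values = _validate_grid(values, str(path))
        return CostRaster(values, resolution=float(header["cellsize"]))
    if format == "geotiff":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            res = page.tags.get("XResolution")
            cell = 1.0
            if res is not None:
                num, den = res.value
                if num:
                    cell = den / num
        values = _validate_grid(np.asarray(values), str(path))
        return CostRaster(values, resolution=cell)
    raise ValueError(f"unknown raster format {format!r}")


def write_nodes(nodes: FocalNodes, path) -> None:
    pd.DataFrame(nodes.coords, columns=["row", "col"]).to_csv(path, index=False)


def read_nodes(path, raster: CostRaster | None = None) -> FocalNodes:
    """Read a (row, col) CSV; validates bounds against ``raster`` when given."""
    df = pd.read_csv(path)
    if not {"row", "col"} <= set(df.columns):
        raise RasterFormatError(f"{path}: node CSV needs 'row' and 'col' columns")
    coords = df[["row", "col"]].to_numpy()
    if len(np.unique(coords, axis=0)) != len(coords):
        raise RasterFormatError(f"{path}: duplicate focal nodes")
    if coords.min() < 0:
        raise RasterFormatError(f"{path}: negative node coordinate")
    if raster is not None and coords.max() >= raster.dim:
        raise RasterFormatError(
            f"{path}: node coordinate >= raster dimension {raster.dim}"
        )
    return FocalNodes(coords)


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI invocation."""

    command: str
    seed: int | None
    config: dict
    version: str = ""
    stage_seconds: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
            fh.write("\n")
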