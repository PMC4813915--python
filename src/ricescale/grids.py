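"""Raster containers and lightweight TIFF I/O.

All grids are row-major float arrays with origin at the top-left and
pixel-center registration.  A single nodata sentinel (-9999) marks
undefined cells and is propagated through every per-pixel map.  Rasters
are written as float32 TIFF with the pixel size, day of year, nodata
value and band order recorded in a JSON description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0

#: band order used for multi-band scene files
SCENE_BANDS = ("blue", "green", "red", "nir")


def valid_mask(grid: np.ndarray) -> np.ndarray:
    """Boolean mask of defined (non-nodata, finite) cells."""
    return np.isfinite(grid) & (grid != NODATA)


@dataclass
class LAIRaster:
    """Leaf area index grid at one spatial scale and date.

    ``pixel_size_m`` is the ground size of one cell; ``doy`` the day of
    year the raster represents (observation date).
    """

    grid: np.ndarray
    pixel_size_m: float
    doy: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        m = valid_mask(self.grid)
        if np.any(self.grid[m] < 0):
            raise ValueError("LAI must be >= 0 or nodata")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


@dataclass
class VegIndexRaster:
    """GBNDVI grid; defined values lie in [-1, 1]."""

    x_grid: np.ndarray
    pixel_size_m: float
    doy: int | None = None

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)


@dataclass
class ReflectanceScene:
    """Four-band surface reflectance (B, G, R, NIR) in [0, 1]."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    doy: int
    pixel_size_m: float

    def __post_init__(self) -> None:
        grids = [np.asarray(g, dtype=float) for g in
                 (self.blue, self.green, self.red, self.nir)]
        shapes = {g.shape for g in grids}
        if len(shapes) != 1:
            raise ValueError("scene bands must share shape")
        for g in grids:
            m = valid_mask(g)
            if np.any((g[m] < 0) | (g[m] > 1)):
                raise ValueError("reflectance outside [0, 1]")
        self.blue, self.green, self.red, self.nir = grids

    @property
    def shape(self) -> tuple[int, ...]:
        return self.blue.shape

    def bands(self) -> np.ndarray:
        """Stack bands in file order (B, G, R, NIR) -> (4, H, W)."""
        return np.stack([self.blue, self.green, self.red, self.nir])


@dataclass
class StressField:
    """Per-pixel stress factors for assimilation truth or output.

    ``fg_grid`` scales daily gross assimilation, ``fc_grid`` the
    carbohydrate-to-dry-matter conversion; both lie in [0.65, 1].  The
    combined factor is their elementwise product and is recomputed from
    the factors rather than stored independently.
    """

    fg_grid: np.ndarray
    fc_grid: np.ndarray
    area_label: str = "A"
    pixel_size_m: float = 8.0
    fcomb_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fg_grid = np.asarray(self.fg_grid, dtype=float)
        self.fc_grid = np.asarray(self.fc_grid, dtype=float)
        if self.fg_grid.shape != self.fc_grid.shape:
            raise ValueError("fg and fc grids must share shape")
        for g in (self.fg_grid, self.fc_grid):
            m = valid_mask(g)
            if np.any((g[m] < 0.65) | (g[m] > 1.0)):
                raise ValueError("stress factors must lie in [0.65, 1]")
        self.fcomb_grid = np.where(
            valid_mask(self.fg_grid) & valid_mask(self.fc_grid),
            self.fg_grid * self.fc_grid,
            NODATA,
        )


# ---------------------------------------------------------------------------
# TIFF I/O

def write_raster(path: str | Path, data: np.ndarray, pixel_size_m: float,
                 doy: int | None = None, bands: tuple[str, ...] | None = None,
                 nodata: float = NODATA) -> None:
    """Write a (H, W) or (nbands, H, W) float32 TIFF with JSON metadata."""
    arr = np.asarray(data, dtype=np.float32)
    meta = {"pixel_size_m": float(pixel_size_m), "doy": doy,
            "nodata": nodata}
    if bands is not None:
        meta["bands"] = list(bands)
    tifffile.imwrite(str(path), arr, description=json.dumps(meta),
                     photometric="minisblack")


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_raster` -> (array, metadata)."""
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return arr, meta


def write_scene(path: str | Path, scene: ReflectanceScene) -> None:
    write_raster(path, scene.bands(), scene.pixel_size_m, scene.doy,
                 bands=SCENE_BANDS)


def read_scene(path: str | Path) -> ReflectanceScene:
    arr, meta = read_raster(path)
    if arr.ndim != 3 or arr.shape[0] != 4:
        raise ValueError("scene file must hold 4 bands")
    return ReflectanceScene(*arr, doy=int(meta.get("doy") or 0),
                            pixel_size_m=float(meta.get("pixel_size_m", 8.0)))


def write_lai(path: str | Path, lai: LAIRaster) -> None:
    write_raster(path, lai.grid, lai.pixel_size_m, lai.doy)


def read_lai(path: str | Path) -> LAIRaster:
    arr, meta = read_raster(path)
    return LAIRaster(arr, pixel_size_m=float(meta.get("pixel_size_m", 8.0)),
                     doy=meta.get("doy"))
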