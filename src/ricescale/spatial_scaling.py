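"""Block-mean upscaling of retrieved LAI to the six analysis scales.

The pyramid follows the retrieve-then-aggregate ("exact LAI") scheme:
LAI is computed at the native 8 m resolution and coarse cells are the
arithmetic means of their constituent fine cells.  Every coarse scale is
produced in a single hop from the base raster; because block means are
nested this is identical to cascading 2x aggregations.
"""

from __future__ import annotations

import numpy as np

from .grids import NODATA, LAIRaster, valid_mask

#: analysis scales in metres
SCALES_M = (8, 16, 32, 64, 128, 256)


def aggregate_lai(fine: LAIRaster, factor: int) -> LAIRaster:
    """Aggregate by block mean; nodata-aware.

    Each coarse cell averages the defined cells of its factor x factor
    block and is nodata only when the whole block is undefined.
    """
    if factor not in (2, 4, 8, 16, 32):
        raise ValueError("factor must be one of 2, 4, 8, 16, 32")
    h, w = fine.grid.shape
    if h % factor or w % factor:
        raise ValueError(f"grid not divisible: {h}x{w} by factor {factor}")
    blocks = fine.grid.reshape(h // factor, factor, w // factor, factor)
    ok = valid_mask(fine.grid).reshape(h // factor, factor, w // factor, factor)
    count = ok.sum(axis=(1, 3))
    total = np.where(ok, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        coarse = np.where(count > 0, total / np.maximum(count, 1), NODATA)
    return LAIRaster(coarse, pixel_size_m=fine.pixel_size_m * factor,
                     doy=fine.doy)


def build_pyramid(base: LAIRaster,
                  scales_m: tuple[int, ...] = SCALES_M) -> dict[int, LAIRaster]:
    """Return {scale_m: raster} for every requested scale.

    The base raster supplies the finest scale; each coarser scale is a
    single-hop aggregation of the base by ``scale / base_scale``.
    """
    base_scale = int(base.pixel_size_m)
    out: dict[int, LAIRaster] = {}
    for s in scales_m:
        if s == base_scale:
            out[s] = base
            continue
        if s % base_scale:
            raise ValueError(f"scale {s} m is not a multiple of the "
                             f"{base_scale} m base")
        out[s] = aggregate_lai(base, s // base_scale)
    return out


def compatible_scales(shape: tuple[int, int], base_scale_m: int = 8,
                      scales_m: tuple[int, ...] = SCALES_M) -> tuple[int, ...]:
    """Scales from ``scales_m`` whose aggregation factor divides the grid."""
    h, w = shape
    keep = []
    for s in scales_m:
        f = s // base_scale_m
        if s % base_scale_m == 0 and f >= 1 and h % f == 0 and w % f == 0:
            keep.append(s)
    return tuple(keep)
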