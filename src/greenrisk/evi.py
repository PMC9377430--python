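"""Enhanced Vegetation Index (EVI) from reflectance bands, and zonal means.

EVI is a greenness index computed from blue, red, and near-infrared
surface reflectance:

    EVI = G * (NIR - Red) / (NIR + C1 * Red - C2 * Blue + L)

with the standard Landsat-8 coefficients G=2.5, C1=6, C2=7.5, L=1 by
default.  Relative to NDVI it corrects for canopy-background signal and
atmospheric aerosols.  The per-region vegetation covariate is the
unweighted mean of EVI over the pixels a zone map assigns to each region.

Rasters are plain 2-D masked arrays; helpers read/write whitespace text
grids (NaN = nodata) and single-band TIFFs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["compute_evi", "zonal_mean", "read_grid", "write_grid"]

#: denominator magnitudes below this are masked rather than divided
DENOM_EPS = 1e-9


def _as_masked(band) -> np.ma.MaskedArray:
    a = np.ma.masked_invalid(np.ma.asarray(band, dtype=float))
    if a.ndim != 2:
        raise ValueError("band rasters must be 2-D")
    return a


def compute_evi(blue, red, nir, G: float = 2.5, C1: float = 6.0,
                C2: float = 7.5, L: float = 1.0) -> np.ma.MaskedArray:
    """EVI raster from three same-shape reflectance bands.

    A pixel is masked nodata when any input band is masked/NaN or when the
    denominator magnitude falls below ``DENOM_EPS``.  Output is not
    clipped; values outside [-1, 1] are counted in a log message (sensor
    artifacts, out of scope here).
    """
    blue, red, nir = _as_masked(blue), _as_masked(red), _as_masked(nir)
    if not (blue.shape == red.shape == nir.shape):
        raise ValueError(
            f"band shapes differ: {blue.shape}, {red.shape}, {nir.shape}"
        )
    denom = nir + C1 * red - C2 * blue + L
    bad = np.ma.filled(np.abs(denom) < DENOM_EPS, True)
    denom = np.ma.masked_where(bad, denom)
    evi = G * (nir - red) / denom
    n_out = np.count_nonzero(np.ma.filled(np.abs(evi) > 1, False))
    if n_out:
        logger.warning("%d EVI pixel(s) outside [-1, 1]; left unclipped", n_out)
    return evi


def zonal_mean(raster, zones, n_regions: int | None = None) -> pd.Series:
    """Per-region arithmetic mean of unmasked raster pixels.

    ``zones`` is an integer grid aligned with the raster; negative entries
    are background.  Regions with no valid pixel are reported as NaN.
    Raises ``ValueError`` when no region anywhere has a valid pixel.
    """
    raster = _as_masked(raster)
    zones = np.asarray(zones)
    if zones.shape != raster.shape:
        raise ValueError(f"zone grid {zones.shape} != raster {raster.shape}")
    if n_regions is None:
        n_regions = int(zones.max()) + 1 if zones.size else 0
    valid = (~np.ma.getmaskarray(raster)) & (zones >= 0)
    if not valid.any():
        raise ValueError("no valid pixel overlaps any zone")
    z = zones[valid]
    v = np.ma.filled(raster, 0.0)[valid]
    sums = np.bincount(z, weights=v, minlength=n_regions)
    counts = np.bincount(z, minlength=n_regions)
    means = np.divide(sums, counts, out=np.full(n_regions, np.nan),
                      where=counts > 0)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        logger.warning("%d region(s) have no valid pixels: %s",
                       missing.size, missing[:10].tolist())
    return pd.Series(means, index=pd.RangeIndex(n_regions, name="region"),
                     name="evi_mean")


def read_grid(path) -> np.ma.MaskedArray:
    """Read a single-band raster: whitespace text grid (NaN = nodata) or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path).astype(float)
    else:
        arr = np.loadtxt(path, ndmin=2)
    return np.ma.masked_invalid(arr)


def write_grid(arr, path) -> None:
    """Write a single-band raster, text grid or TIFF by extension."""
    path = Path(path)
    full = np.ma.filled(np.ma.asarray(arr, dtype=float), np.nan)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, full.astype(np.float32))
    else:
        np.savetxt(path, full)
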