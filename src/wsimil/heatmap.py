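"""Spatial deconvolution of tile attention back onto slide coordinates.

Each tile's footprint in a downsampled raster is filled with its per-slide
min-max-rescaled attention score; pixels not covered by any retained tile
are NaN (missing, not zero).  A slide whose tiles all share one score maps
to 0.5 by convention.  Rescaling is monotone, so the rank order of tile
scores is preserved in the raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .mil import SlideFeature

__all__ = ["HeatmapRaster", "deconvolve", "export_overlay"]


@dataclass
class HeatmapRaster:
    values: np.ndarray          # float array in [0, 1]; NaN = missing
    downsample: int
    colormap_name: str = "inferno"


def deconvolve(sf: SlideFeature, slide_dims: tuple, tile_px: int,
               downsample: int = 32) -> HeatmapRaster:
    """Paint min-max-rescaled attention onto a downsampled slide raster.

    slide_dims: (height_px, width_px) of the source slide.
    """
    H, W = slide_dims
    a = np.asarray(sf.attention, dtype=float)
    if sf.coords is None or len(sf.coords) != len(a):
        raise ValueError("SlideFeature must carry one (x0, y0) per tile")
    span = a.max() - a.min()
    scaled = np.full_like(a, 0.5) if span == 0 else (a - a.min()) / span
    hh = int(np.ceil(H / downsample))
    ww = int(np.ceil(W / downsample))
    values = np.full((hh, ww), np.nan)
    for (x0, y0), s in zip(sf.coords, scaled):
        if x0 < 0 or y0 < 0 or x0 + tile_px > W or y0 + tile_px > H:
            raise ValueError(f"tile at ({x0}, {y0}) lies outside slide {slide_dims}")
        r0, r1 = y0 // downsample, int(np.ceil((y0 + tile_px) / downsample))
        c0, c1 = x0 // downsample, int(np.ceil((x0 + tile_px) / downsample))
        values[r0:r1, c0:c1] = s
    return HeatmapRaster(values=values, downsample=downsample)


def _downsample_rgb(pixels: np.ndarray, shape: tuple) -> np.ndarray:
    from skimage.transform import resize
    out = resize(pixels.astype(np.float64) / 255.0, shape, order=1,
                 anti_aliasing=True)
    return out


def export_overlay(heatmap: HeatmapRaster, slide_pixels: np.ndarray,
                   alpha: float, path: str | Path,
                   tiff_path: str | Path | None = None) -> np.ndarray:
    """Alpha-blend the colorized heatmap over the (downsampled) slide and
    write a PNG; optionally persist the raw float raster as TIFF.

    Missing heatmap pixels always show the slide (alpha applies only where
    a score exists).  Returns the blended uint8 image.
    """
    from matplotlib import colormaps

    base = _downsample_rgb(slide_pixels, heatmap.values.shape)
    if base.shape[:2] != heatmap.values.shape:
        raise ValueError("slide/heatmap dimension mismatch after downsample")
    cmap = colormaps[heatmap.colormap_name]
    colored = cmap(np.nan_to_num(heatmap.values, nan=0.0))[:, :, :3]
    covered = ~np.isnan(heatmap.values)
    blend = base.copy()
    blend[covered] = (1.0 - alpha) * base[covered] + alpha * colored[covered]
    out = np.clip(np.round(blend * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)
    if tiff_path is not None:
        tifffile.imwrite(Path(tiff_path), heatmap.values.astype(np.float32))
    return out
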