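"""Slide preprocessing: tissue/background segmentation, tiling, color
normalization and magnification handling.

Foreground is found by Otsu thresholding the HSV *saturation* channel of a
downsampled copy of the slide — robust against the near-white background of
H&E scans — followed by small-object/hole removal.  The tissue area is then
tessellated into non-overlapping ``tile_px`` x ``tile_px`` tiles (half-open
grid, stride = tile_px, 0-based row-major enumeration, edge tiles that would
exceed the slide bounds dropped); a tile is kept when its tissue fraction
reaches ``min_tissue_frac``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2hsv, rgb2lab, lab2rgb
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.transform import downscale_local_mean

__all__ = ["MAGNIFICATIONS", "SlideRaster", "TissueMask", "TileBag",
           "read_slide", "segment_tissue", "tessellate", "normalize_color",
           "set_magnification", "REINHARD_PRESETS"]

MAGNIFICATIONS = (5, 10, 20, 40)

#: reference LAB (mean, std) triples for normalize_color string presets
REINHARD_PRESETS = {
    # generic H&E appearance: light pink field, moderate chroma
    "he_default": (np.array([72.0, 22.0, -12.0]), np.array([14.0, 8.0, 6.0])),
}


@dataclass
class SlideRaster:
    pixels: np.ndarray                 # (H, W, 3) uint8
    magnification: int = 40
    mpp: float | None = None           # microns per pixel, optional
    slide_id: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideRaster expects an (H, W, 3) RGB array")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")

    @property
    def height_px(self):
        return self.pixels.shape[0]

    @property
    def width_px(self):
        return self.pixels.shape[1]


@dataclass
class TissueMask:
    mask: np.ndarray                   # bool, at `downsample`
    threshold: float                   # Otsu level on the saturation channel
    downsample: int
    no_tissue: bool = False


@dataclass
class TileBag:
    slide_id: str
    coords: np.ndarray                 # (N, 2) int array of (x0, y0)
    pixels: np.ndarray                 # (N, tile_px, tile_px, 3) uint8
    tile_px: int
    magnification: int
    tissue_fraction_per_tile: np.ndarray = field(default=None)

    def __len__(self):
        return len(self.coords)


def read_slide(path: str | Path, magnification: int = 40,
               mpp: float | None = None) -> SlideRaster:
    """Read a plain-raster slide (PNG/TIFF) into memory."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return SlideRaster(pixels=arr, magnification=magnification, mpp=mpp,
                       slide_id=path.stem)


def segment_tissue(slide: SlideRaster, downsample: int = 32,
                   min_object_px: int = 64) -> TissueMask:
    """Otsu threshold on the saturation channel of the downsampled slide.

    A blank (zero-variance) image yields an explicit no-tissue mask rather
    than an error.
    """
    small = downscale_local_mean(slide.pixels.astype(np.float64),
                                 (downsample, downsample, 1)) / 255.0
    sat = rgb2hsv(np.clip(small, 0, 1))[:, :, 1]
    if np.ptp(sat) < 1e-12:
        return TissueMask(mask=np.zeros(sat.shape, dtype=bool), threshold=0.0,
                          downsample=downsample, no_tissue=True)
    thr = float(threshold_otsu(sat))
    mask = sat > thr
    mask = remove_small_objects(mask, max_size=min_object_px)
    mask = remove_small_holes(mask, max_size=min_object_px)
    return TissueMask(mask=mask, threshold=thr, downsample=downsample,
                      no_tissue=not mask.any())


def tessellate(slide: SlideRaster, mask: TissueMask, tile_px: int = 256,
               min_tissue_frac: float = 0.5) -> TileBag:
    """Cut the slide into a non-overlapping grid and keep tiles whose tissue
    fraction (from the mask) reaches ``min_tissue_frac``."""
    if tile_px < 32:
        raise ValueError("tile_px must be >= 32")
    ds = mask.downsample
    expect = (int(np.ceil(slide.height_px / ds)), int(np.ceil(slide.width_px / ds)))
    if mask.mask.shape != expect:
        raise ValueError(
            f"mask shape {mask.mask.shape} inconsistent with slide "
            f"{slide.pixels.shape[:2]} at downsample {ds} (expected {expect})")
    coords, fracs, blocks = [], [], []
    m = mask.mask.astype(np.float64)
    for y0 in range(0, slide.height_px - tile_px + 1, tile_px):
        for x0 in range(0, slide.width_px - tile_px + 1, tile_px):
            r0, r1 = y0 // ds, int(np.ceil((y0 + tile_px) / ds))
            c0, c1 = x0 // ds, int(np.ceil((x0 + tile_px) / ds))
            frac = float(m[r0:r1, c0:c1].mean())
            if frac >= min_tissue_frac:
                coords.append((x0, y0))
                fracs.append(frac)
                blocks.append(slide.pixels[y0:y0 + tile_px, x0:x0 + tile_px])
    n = len(coords)
    pixels = (np.stack(blocks) if n else
              np.empty((0, tile_px, tile_px, 3), dtype=slide.pixels.dtype))
    return TileBag(slide_id=slide.slide_id,
                   coords=np.array(coords, dtype=int).reshape(n, 2),
                   pixels=pixels, tile_px=tile_px,
                   magnification=slide.magnification,
                   tissue_fraction_per_tile=np.array(fracs))


def _lab_stats(rgb: np.ndarray):
    lab = rgb2lab(rgb.astype(np.float64) / 255.0)
    flat = lab.reshape(-1, 3)
    return lab, flat.mean(axis=0), flat.std(axis=0)


def normalize_color(bag: TileBag, reference="he_default") -> TileBag:
    """Reinhard stain normalization: match each tile's per-channel LAB mean
    and std to the reference tile (or a named preset)."""
    if isinstance(reference, str):
        mu_ref, sd_ref = REINHARD_PRESETS[reference]
    else:
        ref = np.asarray(reference)
        if ref.ndim != 3:
            warnings.warn("grayscale reference: color normalization skipped")
            return bag
        _, mu_ref, sd_ref = _lab_stats(ref)
    out = np.empty_like(bag.pixels)
    for i, tile in enumerate(bag.pixels):
        if tile.ndim != 3:
            warnings.warn("grayscale tile passed through un-normalized")
            out[i] = tile
            continue
        lab, mu, sd = _lab_stats(tile)
        scale = np.where(sd > 1e-8, sd_ref / np.maximum(sd, 1e-8), 1.0)
        matched = (lab - mu) * scale + mu_ref
        rgb = lab2rgb(matched)
        out[i] = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return TileBag(slide_id=bag.slide_id, coords=bag.coords.copy(), pixels=out,
                   tile_px=bag.tile_px, magnification=bag.magnification,
                   tissue_fraction_per_tile=bag.tissue_fraction_per_tile)


def set_magnification(slide: SlideRaster, target: int) -> SlideRaster:
    """Area-average-downsample the raster so tiles cut afterwards represent
    the target magnification (x40 -> x20 halves the linear resolution)."""
    if target not in MAGNIFICATIONS:
        raise ValueError(f"target magnification must be one of {MAGNIFICATIONS}")
    if target > slide.magnification:
        raise ValueError(
            f"target magnification x{target} exceeds native x{slide.magnification}")
    if target == slide.magnification:
        return slide
    factor = slide.magnification // target
    small = downscale_local_mean(slide.pixels.astype(np.float64),
                                 (factor, factor, 1))
    return SlideRaster(pixels=np.clip(np.round(small), 0, 255).astype(np.uint8),
                       magnification=target, slide_id=slide.slide_id,
                       mpp=None if slide.mpp is None else slide.mpp * factor)
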