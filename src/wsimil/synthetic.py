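"""Seeded synthetic slide cohorts with the statistical structure the
pipeline assumes.

Each slide is a pale background carrying one smooth tissue blob (thresholded
smoothed Gaussian noise).  Tumor subregions inside the blob are carved from a
second, higher-frequency field and rendered with a distinct texture: a hue
shift toward hematoxylin purple plus dense dark nuclei-like speckle.  One
knob (``texture_strength``) interpolates the tumor texture between
indistinguishable-from-tissue (0) and fully distinct (1), controlling
tile-level visual separability.

Slide-level labels are coupled to morphology:

* signal protein j:   p_j = alpha_j * tumor_fraction + eps,  eps ~ N(0, noise_sd)
* non-signal protein: pure noise
* survival:           exponential proportional hazards on latent features
                      (tumor_fraction, tissue darkness), independent censoring
* responder:          HER2-like protein (the first signal protein) below its
                      cohort median

This generator makes no attempt at photorealistic H&E or stain physics; it
exists so that tissue segmentation, MIL attention and the weakly supervised
heads can be tested against known ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .heads import ProteinPanel
from .survival import SurvivalRecord

logger = logging.getLogger(__name__)

__all__ = ["SynthesisParams", "SyntheticSlide", "CohortManifest",
           "make_slide", "make_cohort", "HER2_PROTEIN"]

#: name of the designated HER2-like protein (the first signal protein)
HER2_PROTEIN = "protein_1"

_BG = np.array([246.0, 244.0, 245.0])        # pale background
_TISSUE = np.array([231.0, 158.0, 196.0])    # eosin-pink tissue
_TUMOR = np.array([168.0, 110.0, 188.0])     # hematoxylin-purple tumor
_NUCLEUS = np.array([70.0, 42.0, 110.0])     # dark nucleus speckle
_H0 = 0.1                                    # exponential baseline hazard

_NORMAL_SPECKLE = 0.02                       # nuclei density in normal tissue
_TUMOR_SPECKLE = 0.16                        # nuclei density in tumor


@dataclass
class SynthesisParams:
    slide_px: int = 512
    tile_px: int = 64
    tissue_fraction_range: tuple = (0.35, 0.6)
    tumor_fraction_range: tuple = (0.15, 0.5)
    tumor_prevalence: float = 0.5
    n_proteins: int = 32
    n_signal_proteins: int = 8
    noise_sd: float = 0.1
    cox_coefficients: tuple = (2.0, 1.0)
    censoring_rate: float = 0.3
    texture_strength: float = 1.0
    signal_alpha: float | None = None   # force all alpha_j to this value
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_fraction_range
        tlo, thi = self.tissue_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"tumor_fraction_range {self.tumor_fraction_range} invalid")
        if not (0 < tlo <= thi <= 1):
            raise ValueError(f"tissue_fraction_range {self.tissue_fraction_range} invalid")
        if self.n_signal_proteins > self.n_proteins:
            raise ValueError("n_signal_proteins cannot exceed n_proteins")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if not 0 <= self.tumor_prevalence <= 1:
            raise ValueError("tumor_prevalence must lie in [0, 1]")
        if self.slide_px < 2 * self.tile_px:
            raise ValueError("slide_px must be at least 2 * tile_px")

    @property
    def protein_names(self):
        return [f"protein_{j + 1}" for j in range(self.n_proteins)]


@dataclass
class SyntheticSlide:
    slide_id: str
    raster: np.ndarray          # (H, W, 3) uint8
    tissue_mask: np.ndarray     # (H, W) bool
    tumor_mask: np.ndarray      # (H, W) bool, subset of tissue_mask
    tumor_fraction: float       # tumor px / tissue px, recomputed from masks
    labels: dict = field(default_factory=dict)


@dataclass
class CohortManifest:
    table: pd.DataFrame
    root: Path
    params: SynthesisParams

    @property
    def manifest_path(self):
        return self.root / "manifest.csv"


def _signal_alphas(params: SynthesisParams) -> np.ndarray:
    """Per-protein coupling strengths, fixed by the cohort seed (identical
    across slides)."""
    if params.signal_alpha is not None:
        return np.full(params.n_signal_proteins, float(params.signal_alpha))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5157]))
    return rng.uniform(0.8, 1.6, params.n_signal_proteins)


def _her2_population_median(params: SynthesisParams) -> float:
    """Median of the HER2-like protein under the generating mixture
    (point mass at tumor_fraction=0 with weight 1-prevalence, uniform on the
    tumor range otherwise); noise is symmetric so it does not shift it."""
    alpha = _signal_alphas(params)[0]
    q = params.tumor_prevalence
    lo, hi = params.tumor_fraction_range
    if q <= 0.5 or hi == 0:
        med_tf = 0.0
    else:
        med_tf = lo + (hi - lo) * (0.5 - (1 - q)) / q
    return alpha * med_tf


def _smooth_field(rng, n, sigma):
    f = gaussian_filter(rng.standard_normal((n, n)), sigma=sigma, mode="reflect")
    return f


def make_slide(params: SynthesisParams, slide_seed: int) -> SyntheticSlide:
    """Generate one slide; a pure function of (params, slide_seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, slide_seed]))
    n = params.slide_px

    # ---- tissue blob -------------------------------------------------
    tissue_field = _smooth_field(rng, n, sigma=n / 8)
    tissue_frac = rng.uniform(*params.tissue_fraction_range)
    thr = np.quantile(tissue_field, 1.0 - tissue_frac)
    tissue = tissue_field >= thr

    # ---- tumor subregions -------------------------------------------
    lo, hi = params.tumor_fraction_range
    has_tumor = hi > 0 and rng.uniform() < params.tumor_prevalence
    target_tf = rng.uniform(lo, hi)        # drawn regardless, for stream stability
    tumor = np.zeros_like(tissue)
    if has_tumor and tissue.any() and target_tf > 0:
        tumor_field = _smooth_field(rng, n, sigma=n / 16)
        thr2 = np.quantile(tumor_field[tissue], 1.0 - target_tf)
        tumor = tissue & (tumor_field >= thr2)
    tumor_fraction = float(tumor.sum() / tissue.sum()) if tissue.any() else 0.0

    # ---- render ------------------------------------------------------
    s = float(np.clip(params.texture_strength, 0.0, 1.0))
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = _BG + rng.normal(0.0, 1.5, (n, n, 1))
    shade = _smooth_field(rng, n, sigma=n / 10)[..., None] * 8.0
    img[tissue] = _TISSUE + shade[tissue]
    tumor_color = _TISSUE + s * (_TUMOR - _TISSUE)
    img[tumor] = tumor_color + shade[tumor]
    speckle_p = np.where(tumor, _NORMAL_SPECKLE + s * (_TUMOR_SPECKLE - _NORMAL_SPECKLE),
                         np.where(tissue, _NORMAL_SPECKLE, 0.0))
    nuclei = rng.uniform(size=(n, n)) < speckle_p
    img[nuclei] = _NUCLEUS
    raster = np.clip(img, 0, 255).astype(np.uint8)

    # ---- labels ------------------------------------------------------
    alphas = _signal_alphas(params)
    values = np.empty(params.n_proteins)
    k = params.n_signal_proteins
    values[:k] = alphas * tumor_fraction + rng.normal(0.0, params.noise_sd, k)
    values[k:] = rng.normal(0.0, max(params.noise_sd, 1e-12),
                            params.n_proteins - k)
    panel = ProteinPanel(names=params.protein_names, values=values,
                         patient_id=f"P{slide_seed:04d}")

    darkness = 1.0 - raster[tissue].mean() / 255.0 if tissue.any() else 0.0
    latent = np.array([tumor_fraction, darkness])
    theta = np.asarray(params.cox_coefficients, dtype=float)
    linpred = float(theta @ latent)
    t_event = rng.exponential(1.0 / (_H0 * np.exp(linpred)))
    censored = rng.uniform() < params.censoring_rate
    time = t_event * rng.uniform() if censored else t_event
    time = max(time, 1e-9)
    survival = SurvivalRecord(patient_id=panel.patient_id, time=time,
                              event=0 if censored else 1, covariates=latent)

    her2 = values[0]
    responder = bool(her2 < _her2_population_median(params))

    return SyntheticSlide(
        slide_id=f"S{slide_seed:04d}",
        raster=raster,
        tissue_mask=tissue,
        tumor_mask=tumor,
        tumor_fraction=tumor_fraction,
        labels={"tumor_flag": bool(tumor_fraction > 0), "proteins": panel,
                "survival": survival, "responder": responder,
                "latent": latent},
    )


def _split_sizes(n: int) -> tuple[int, int, int]:
    """60/20/20 partition; with too few slides, fill train, then val, then
    test."""
    n_val = int(np.floor(0.2 * n))
    n_test = int(np.floor(0.2 * n))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def make_cohort(params: SynthesisParams, n_slides: int,
                out_dir: str | Path) -> CohortManifest:
    """Generate `n_slides` slides, write them (plus masks) to `out_dir`, and
    return the manifest with train/val/test assignment and all labels."""
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    root = Path(out_dir)
    (root / "slides").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)

    slides = [make_slide(params, i) for i in range(n_slides)]

    # responder against the *empirical* cohort median of the HER2-like protein
    her2_vals = np.array([s.labels["proteins"].values[0] for s in slides])
    her2_median = float(np.median(her2_vals))
    for s in slides:
        s.labels["responder"] = bool(s.labels["proteins"].values[0] < her2_median)

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x51D5]))
    perm = rng.permutation(n_slides)
    n_train, n_val, n_test = _split_sizes(n_slides)
    if n_val == 0 or n_test == 0:
        logger.warning("cohort of %d slides too small for a 60/20/20 split; "
                       "filling train first, then val, then test", n_slides)
    split = np.empty(n_slides, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train:n_train + n_val]] = "val"
    split[perm[n_train + n_val:]] = "test"

    rows = []
    for i, s in enumerate(slides):
        spath = root / "slides" / f"{s.slide_id}.png"
        tpath = root / "masks" / f"{s.slide_id}_tissue.png"
        upath = root / "masks" / f"{s.slide_id}_tumor.png"
        try:
            iio.imwrite(spath, s.raster)
            iio.imwrite(tpath, (s.tissue_mask * 255).astype(np.uint8))
            iio.imwrite(upath, (s.tumor_mask * 255).astype(np.uint8))
        except OSError as exc:
            raise OSError(f"failed writing slide artifacts under {root}: {exc}") from exc
        rec = s.labels["survival"]
        row = {
            "slide_id": s.slide_id,
            "patient_id": s.labels["proteins"].patient_id,
            "path": str(spath),
            "split": split[i],
            "tumor_flag": s.labels["tumor_flag"],
            "tumor_fraction": s.tumor_fraction,
        }
        for name, val in zip(params.protein_names, s.labels["proteins"].values):
            row[name] = val
        row.update({
            "surv_time": rec.time, "surv_event": rec.event,
            "responder": s.labels["responder"],
            "tissue_mask_path": str(tpath), "tumor_mask_path": str(upath),
        })
        rows.append(row)

    table = pd.DataFrame(rows)
    table.to_csv(root / "manifest.csv", index=False)
    meta = {"params": asdict(params), "her2_protein": HER2_PROTEIN,
            "her2_cohort_median": her2_median,
            "signal_alphas": _signal_alphas(params).tolist(),
            "n_slides": n_slides}
    (root / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
    return CohortManifest(table=table, root=root, params=params)


def load_manifest(root: str | Path) -> CohortManifest:
    """Re-open a cohort previously written by make_cohort."""
    root = Path(root)
    table = pd.read_csv(root / "manifest.csv")
    meta = json.loads((root / "cohort_meta.json").read_text())
    p = meta["params"]
    for key in ("tissue_fraction_range", "tumor_fraction_range", "cox_coefficients"):
        p[key] = tuple(p[key])
    return CohortManifest(table=table, root=root, params=SynthesisParams(**p))
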