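"""Slide-level quality-control masking.

Two complementary detectors run on a fixed-resolution thumbnail of the
slide (default 16 µm/px, so parameters are independent of scanner
resolution):

* **Otsu's thresholding** — splits the grayscale histogram at the cut
  maximizing between-class variance; the brighter class is background
  (H&E background is near-white).
* **Gaussian-blur filtering** — flags *smooth* regions: the absolute
  Laplacian of the grayscale image is smoothed with a Gaussian, and pixels
  whose local gradient energy falls below a cutoff are masked.  This
  catches uniform pen ink, out-of-focus areas, and blank background, none
  of which carry tissue texture.

Order matters when composing: pen ink is darker than background, so Otsu
alone reads it as foreground *and* skews its histogram.  Running blur
filtering first and excluding its mask from Otsu's histogram reproduces the
recommended blur-then-Otsu pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import gaussian, laplace, threshold_otsu
from skimage.transform import resize

from .errors import CompositionError, DegenerateHistogramError
from .slide import SlidePyramid

__all__ = [
    "QCMask",
    "QCConfig",
    "thumbnail",
    "to_gray",
    "otsu_mask",
    "blur_mask",
    "compose_masks",
    "masked_fraction",
    "save_mask",
]


@dataclass
class QCMask:
    """Boolean background mask on a thumbnail grid; True = masked out."""

    mask: np.ndarray
    mpp: float
    source: str = "custom"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mpp <= 0:
            raise ValueError("QCMask needs a 2-D grid and positive mpp")

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class QCConfig:
    """Tunables for thumbnail-resolution QC.

    ``thumbnail_mpp`` fixes the working resolution (µm/px); ``blur_sigma``
    is in thumbnail pixels; ``blur_threshold`` is a gradient-energy cutoff
    on [0, 1] grayscale.  Defaults were calibrated on the synthetic slide
    generator — vendors do not publish theirs.
    """

    thumbnail_mpp: float = 16.0
    blur_sigma: float = 3.0
    blur_threshold: float = 0.02
    otsu_bins: int = 256

    def __post_init__(self):
        for name in ("thumbnail_mpp", "blur_sigma", "blur_threshold", "otsu_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def thumbnail(pyramid: SlidePyramid, mpp: float = 16.0) -> np.ndarray:
    """Whole-slide RGB thumbnail at the requested resolution.

    Reads from the coarsest level at least as fine as ``mpp`` (falling back
    to the coarsest level available) and resizes.
    """
    idx = 0
    for i, lv in enumerate(pyramid.levels):
        if lv.mpp <= mpp:
            idx = i
    w = max(1, int(round(pyramid.width_um / mpp)))
    h = max(1, int(round(pyramid.height_um / mpp)))
    arr = pyramid.level_array(idx)
    if arr.shape[:2] == (h, w):
        return arr.copy()
    out = resize(arr, (h, w), order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0, 255).astype(np.uint8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Grayscale on a 0–255 scale from RGB or already-gray input."""
    img = np.asarray(img)
    if img.ndim == 3:
        return rgb2gray(img) * 255.0
    return img.astype(np.float64)


def otsu_mask(
    thumb: np.ndarray,
    exclude: QCMask | None = None,
    bins: int = 256,
    mpp: float = 16.0,
) -> tuple[QCMask, float]:
    """Otsu background mask plus the chosen threshold.

    The histogram is computed over non-excluded pixels only, so artifacts
    already masked upstream (e.g. pen ink flagged by blur filtering) cannot
    skew the threshold.  Pixels strictly brighter than the threshold are
    masked as background; excluded pixels are left unmasked here (the
    composition union already covers them).
    """
    gray = to_gray(thumb)
    if gray.size == 0:
        raise DegenerateHistogramError("empty thumbnail")
    if exclude is not None:
        if exclude.mask.shape != gray.shape:
            raise CompositionError(
                f"exclusion shape {exclude.mask.shape} != thumbnail {gray.shape}"
            )
        values = gray[~exclude.mask]
    else:
        values = gray.ravel()
    if values.size == 0:
        raise DegenerateHistogramError("all pixels excluded from Otsu histogram")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 255.0))
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")
    centers = (edges[:-1] + edges[1:]) / 2.0
    threshold = float(threshold_otsu(hist=(counts, centers)))
    mask = gray > threshold
    if exclude is not None:
        mask &= ~exclude.mask
        mpp = exclude.mpp
    return QCMask(mask=mask, mpp=mpp, source="otsu"), threshold


def blur_mask(thumb: np.ndarray, cfg: QCConfig = QCConfig()) -> QCMask:
    """Mask smooth (low gradient-energy) regions: pen ink, defocus, blank glass."""
    gray = to_gray(thumb) / 255.0
    energy = gaussian(np.abs(laplace(gray)), sigma=cfg.blur_sigma)
    return QCMask(mask=energy < cfg.blur_threshold, mpp=cfg.thumbnail_mpp, source="blur")


StepFn = Callable[[np.ndarray, QCMask | None], QCMask]


def _named_step(name: str, cfg: QCConfig) -> StepFn:
    if name == "otsu":
        return lambda thumb, excl: otsu_mask(
            thumb, excl, bins=cfg.otsu_bins, mpp=cfg.thumbnail_mpp
        )[0]
    if name == "blur":
        return lambda thumb, excl: blur_mask(thumb, cfg)
    raise ValueError(f"unknown QC step {name!r}; use 'blur', 'otsu', or a callable")


def compose_masks(
    steps: Sequence[str | StepFn],
    thumb: np.ndarray,
    cfg: QCConfig = QCConfig(),
) -> QCMask:
    """Apply QC steps in order, unioning their masks.

    Each later step receives the union of all earlier masks as its
    exclusion set.  Custom steps are callables
    ``(thumbnail, exclude: QCMask | None) -> QCMask`` and may ignore the
    exclusion if it is not meaningful for them.
    """
    if not steps:
        raise ValueError("compose_masks needs at least one step")
    shape = np.asarray(thumb).shape[:2]
    acc: QCMask | None = None
    sources = []
    for step in steps:
        fn = _named_step(step, cfg) if isinstance(step, str) else step
        result = fn(thumb, acc)
        if result.mask.shape != shape:
            raise CompositionError(
                f"step produced mask {result.mask.shape}, expected {shape}"
            )
        sources.append(result.source)
        union = result.mask if acc is None else (acc.mask | result.mask)
        acc = QCMask(mask=union, mpp=cfg.thumbnail_mpp, source="+".join(sources))
    if len(sources) > 1:
        acc.source = "composite:" + "+".join(sources)
    return acc


def masked_fraction(
    qc: QCMask, x_um: float, y_um: float, tile_um: float
) -> float:
    """Fraction of a physical tile footprint covered by the mask."""
    h, w = qc.mask.shape
    x0 = int(np.floor(x_um / qc.mpp))
    y0 = int(np.floor(y_um / qc.mpp))
    x1 = int(np.ceil((x_um + tile_um) / qc.mpp))
    y1 = int(np.ceil((y_um + tile_um) / qc.mpp))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x1 <= x0 or y1 <= y0:
        return 0.0
    return float(qc.mask[y0:y1, x0:x1].mean())


def save_mask(qc: QCMask, path: str, params: dict | None = None) -> None:
    """Export a mask as PNG (0 = kept, 255 = masked) plus JSON metadata."""
    from PIL import Image

    Image.fromarray(qc.mask.astype(np.uint8) * 255).save(path)
    meta = {"mpp": qc.mpp, "source": qc.source, "params": params or {}}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
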