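"""Synthetic whole-slide generator with ground-truth masks.

Real scanner slides cannot ship with a test suite, so this module renders
small H&E-like slides with known content: a near-white background, darker
textured "tissue" blobs, uniform saturated pen-mark polygons, and
deliberately defocused rectangles.  Alongside the image pyramid it emits
boolean ground-truth masks (tissue / pen / blur), registered to the level-0
pixel frame, against which masking and filtering code can be scored.

Tissue texture is generated as coarse-grained noise (default 32 µm grain)
upsampled to level 0, so it survives downsampling to QC-thumbnail
resolution the way real chromatin texture does; plain per-pixel noise would
average away and make tissue look like defocus at thumbnail scale.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.transform import resize

from .errors import SpecError
from .slide import Level, SlidePyramid

__all__ = [
    "TissueBlob",
    "PenMark",
    "BlurRegion",
    "SlideSpec",
    "GroundTruth",
    "render_slide",
    "synth_pyramid",
    "synth_slide",
]

# muted H&E pink, the default tissue tone
_TISSUE_RGB = (200, 140, 170)


@dataclass(frozen=True)
class TissueBlob:
    center_um: tuple[float, float]
    radius_um: float
    mean_rgb: tuple[int, int, int] = _TISSUE_RGB


@dataclass(frozen=True)
class PenMark:
    """Uniform saturated ink polygon; vertices in µm (x, y)."""

    vertices_um: tuple[tuple[float, float], ...]
    color: tuple[int, int, int] = (0, 110, 60)


@dataclass(frozen=True)
class BlurRegion:
    """Axis-aligned out-of-focus rectangle; sigma in µm."""

    x_um: float
    y_um: float
    width_um: float
    height_um: float
    sigma_um: float = 16.0


@dataclass(frozen=True)
class SlideSpec:
    width_um: float
    height_um: float
    level_mpps: tuple[float, ...] = (1.0, 4.0, 16.0)
    tissue_blobs: tuple[TissueBlob, ...] = ()
    pen_marks: tuple[PenMark, ...] = ()
    blur_regions: tuple[BlurRegion, ...] = ()
    background_rgb: tuple[int, int, int] = (242, 241, 239)
    texture_grain_um: float = 32.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise SpecError("slide physical dimensions must be positive")
        mpps = list(self.level_mpps)
        if not mpps or any(m <= 0 for m in mpps):
            raise SpecError("level_mpps must be nonempty and positive")
        if sorted(mpps) != mpps or len(set(mpps)) != len(mpps):
            raise SpecError("level_mpps must be strictly ascending")


@dataclass
class GroundTruth:
    """Level-0-registered boolean masks plus the generating spec."""

    tissue: np.ndarray
    pen: np.ndarray
    blur: np.ndarray
    spec: SlideSpec

    @property
    def background(self) -> np.ndarray:
        return ~(self.tissue | self.pen)


def _spec_to_jsonable(spec: SlideSpec) -> dict:
    return json.loads(json.dumps(asdict(spec)))


def render_slide(spec: SlideSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Render all pyramid levels (uint8 RGB) plus ground-truth masks."""
    spec.validate()
    mpp0 = spec.level_mpps[0]
    w0 = int(round(spec.width_um / mpp0))
    h0 = int(round(spec.height_um / mpp0))
    if w0 < 4 or h0 < 4:
        raise SpecError("slide too small at level 0")
    rng = np.random.default_rng(spec.seed)

    img = np.empty((h0, w0, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    img += rng.normal(0.0, 1.5, size=(h0, w0, 1))

    yy, xx = np.mgrid[0:h0, 0:w0]
    x_um = (xx + 0.5) * mpp0
    y_um = (yy + 0.5) * mpp0

    tissue = np.zeros((h0, w0), dtype=bool)
    grain_px = max(1, int(round(spec.texture_grain_um / mpp0)))
    for blob in spec.tissue_blobs:
        cx, cy = blob.center_um
        disc = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= blob.radius_um**2
        tissue |= disc
        coarse = rng.normal(
            0.0, 22.0, size=(h0 // grain_px + 2, w0 // grain_px + 2, 3)
        )
        texture = np.kron(coarse, np.ones((grain_px, grain_px, 1)))[:h0, :w0, :]
        fine = rng.normal(0.0, 6.0, size=(h0, w0, 3))
        img[disc] = np.asarray(blob.mean_rgb) + texture[disc] + fine[disc]

    pen = np.zeros((h0, w0), dtype=bool)
    for mark in spec.pen_marks:
        verts = np.asarray(mark.vertices_um, dtype=float)
        if verts.shape[0] < 3:
            raise SpecError("pen mark polygon needs >= 3 vertices")
        rr, cc = draw_polygon(verts[:, 1] / mpp0, verts[:, 0] / mpp0, shape=(h0, w0))
        pen[rr, cc] = True
        img[rr, cc] = np.asarray(mark.color) + rng.normal(0.0, 0.8, size=(len(rr), 3))

    blur = np.zeros((h0, w0), dtype=bool)
    for region in spec.blur_regions:
        x0 = int(round(region.x_um / mpp0))
        y0 = int(round(region.y_um / mpp0))
        x1 = int(round((region.x_um + region.width_um) / mpp0))
        y1 = int(round((region.y_um + region.height_um) / mpp0))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w0), min(y1, h0)
        if x1 <= x0 or y1 <= y0:
            continue
        blur[y0:y1, x0:x1] = True
        sigma_px = region.sigma_um / mpp0
        img[y0:y1, x0:x1] = gaussian_filter(
            img[y0:y1, x0:x1], sigma=(sigma_px, sigma_px, 0)
        )

    level0 = np.clip(img, 0, 255).astype(np.uint8)
    levels = [level0]
    for mpp in spec.level_mpps[1:]:
        w = int(round(spec.width_um / mpp))
        h = int(round(spec.height_um / mpp))
        down = resize(level0, (h, w), order=1, anti_aliasing=True, preserve_range=True)
        levels.append(np.clip(down, 0, 255).astype(np.uint8))

    return levels, GroundTruth(tissue=tissue, pen=pen, blur=blur, spec=spec)


def synth_pyramid(spec: SlideSpec, slide_id: str = "synthetic") -> tuple[SlidePyramid, GroundTruth]:
    """Render a spec directly into an in-memory :class:`SlidePyramid`."""
    levels, truth = render_slide(spec)
    pyr = SlidePyramid.from_arrays(slide_id, levels, list(spec.level_mpps))
    return pyr, truth


def synth_slide(
    spec: SlideSpec, out_path: str | os.PathLike, write_masks: bool = True
) -> tuple[str, GroundTruth]:
    """Write a pyramidal TIFF plus ground-truth sidecars.

    Emits ``<out>.json`` (spec + mask areas + level geometry) and, when
    ``write_masks`` is true, one PNG per ground-truth mask at level-0
    registration.  Identical spec and seed produce byte-identical TIFFs.
    """
    import tifffile
    from PIL import Image

    out_path = os.fspath(out_path)
    levels, truth = render_slide(spec)
    with tifffile.TiffWriter(out_path) as tw:
        for arr, mpp in zip(levels, spec.level_mpps):
            ppcm = 1e4 / mpp
            tw.write(
                arr,
                photometric="rgb",
                resolution=(ppcm, ppcm),
                resolutionunit="CENTIMETER",
                compression=None,
            )

    base, _ = os.path.splitext(out_path)
    sidecar = {
        "spec": _spec_to_jsonable(spec),
        "levels": [
            {"width": a.shape[1], "height": a.shape[0], "mpp": m}
            for a, m in zip(levels, spec.level_mpps)
        ],
        "mask_areas_px": {
            "tissue": int(truth.tissue.sum()),
            "pen": int(truth.pen.sum()),
            "blur": int(truth.blur.sum()),
        },
    }
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    if write_masks:
        for name in ("tissue", "pen", "blur"):
            mask = getattr(truth, name)
            Image.fromarray(mask.astype(np.uint8) * 255).save(f"{base}.{name}.png")
    return out_path, truth


def file_digest(path: str | os.PathLike) -> str:
    """SHA-256 of a file, for determinism checks and lineage logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
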