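"""Tile-grid construction, tile-level background filtering, and extraction.

The grid is a regular lattice of square tiles specified physically: tile
width in microns, output size in pixels, and stride (stride < tile width
gives overlap).  Candidate tiles are kept only if they pass the slide's
region-of-interest constraints and their footprint on the QC mask is
sufficiently unmasked.

Two cheap per-tile background tests run on a low-magnification read of the
tile footprint before the expensive full-resolution extraction:

* **grayspace** — fraction of pixels with HSV saturation below a cutoff
  (background and glass are achromatic);
* **whitespace** — fraction of pixels with mean-RGB brightness above a
  cutoff.

Every extraction writes a lineage log — a canonical, hashable record of all
parameters — so processed datasets can be reproduced or audited, plus a
machine-readable report (counts per slide) and an optional visual summary.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
from skimage.color import rgb2hsv
from skimage.transform import resize

from . import __version__ as _pkg_version
from .errors import ROIError
from .qc import QCMask, masked_fraction, thumbnail
from .slide import SlidePyramid, read_region_um, select_source_level
from .store import StoreIndex, TileRecord, encode_tile, write_store

__all__ = [
    "ROI",
    "TileGrid",
    "FilterConfig",
    "LineageLog",
    "build_grid",
    "grayspace_fraction",
    "whitespace_fraction",
    "should_discard",
    "extract_tiles",
    "extraction_report",
    "render_report",
    "load_rois_csv",
    "load_rois_geojson",
]


@dataclass(frozen=True)
class ROI:
    """Pathologist polygon in level-0 pixel coordinates."""

    slide_id: str
    label: str
    vertices: tuple[tuple[float, float], ...]
    role: str = "include"  # include | exclude

    def polygon(self) -> Polygon:
        if len(self.vertices) < 3:
            raise ROIError(f"ROI {self.label!r}: needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ROIError(f"ROI {self.label!r}: polygon is not simple")
        return poly


@dataclass
class TileGrid:
    slide_id: str
    tile_px: int
    tile_um: float
    stride_um: float
    coords: list[tuple[float, float]]  # (x_um, y_um) top-lefts
    provenance: str = ""

    @property
    def n_tiles(self) -> int:
        return len(self.coords)

    def to_json(self) -> str:
        return json.dumps(
            {
                "slide_id": self.slide_id,
                "tile_px": self.tile_px,
                "tile_um": self.tile_um,
                "stride_um": self.stride_um,
                "coords": self.coords,
                "provenance": self.provenance,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        d = json.loads(text)
        d["coords"] = [tuple(c) for c in d["coords"]]
        return cls(**d)


@dataclass(frozen=True)
class FilterConfig:
    """Tile-level background filter thresholds.

    Published toolkits do not print their defaults; these are conventional
    HSV/brightness choices and are fully configurable.
    """

    grayspace_sat_threshold: float = 0.05
    grayspace_fraction: float = 0.6
    whitespace_bright_threshold: float = 230.0
    whitespace_fraction: float = 0.95
    filter_mpp: float | None = None  # None: lowest-mag level giving >= 8 px/tile

    def __post_init__(self):
        if not (0 <= self.grayspace_sat_threshold <= 1):
            raise ValueError("grayspace_sat_threshold must lie in [0, 1]")
        if not (0 <= self.grayspace_fraction <= 1):
            raise ValueError("grayspace_fraction must lie in [0, 1]")
        if not (0 <= self.whitespace_bright_threshold <= 255):
            raise ValueError("whitespace_bright_threshold must lie in [0, 255]")
        if not (0 <= self.whitespace_fraction <= 1):
            raise ValueError("whitespace_fraction must lie in [0, 1]")


@dataclass
class LineageLog:
    """Hashable record of every parameter needed to reproduce an extraction."""

    params: dict

    @property
    def digest(self) -> str:
        canonical = json.dumps(self.params, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params, "digest": self.digest},
            sort_keys=True,
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LineageLog":
        return cls(params=json.loads(text)["params"])


# ---------------------------------------------------------------------------
# grid construction


def build_grid(
    pyramid: SlidePyramid,
    tile_um: float,
    tile_px: int,
    stride_um: float | None = None,
    rois: Sequence[ROI] = (),
    qc: QCMask | None = None,
    roi_method: str = "center",
    roi_fraction_min: float = 0.5,
    mask_fraction_max: float = 0.6,
    jitter_seed: int | None = None,
) -> TileGrid:
    """Regular tile grid filtered by ROIs and the QC mask.

    A tile survives iff (there are no include-ROIs, or it passes
    ``roi_method`` against their union), it does not pass the same test
    against any exclude-ROI, and its QC-masked footprint fraction is at
    most ``mask_fraction_max``.  ``jitter_seed`` adds a seeded uniform
    offset up to ±stride/4 to each tile position (data augmentation).
    """
    stride_um = tile_um if stride_um is None else stride_um
    if stride_um <= 0:
        raise ValueError("stride_um must be positive")
    select_source_level(pyramid, tile_um, tile_px)  # raises if impossible

    mpp0 = pyramid.level0_mpp
    includes = [r.polygon() for r in rois if r.role == "include"]
    excludes = [r.polygon() for r in rois if r.role == "exclude"]
    include_union = unary_union(includes) if includes else None
    exclude_union = unary_union(excludes) if excludes else None

    rng = np.random.default_rng(jitter_seed) if jitter_seed is not None else None

    def passes(union, x_um, y_um) -> bool:
        if roi_method == "center":
            cx = (x_um + tile_um / 2) / mpp0
            cy = (y_um + tile_um / 2) / mpp0
            return union.covers(Point(cx, cy))  # edge counts as inside
        if roi_method == "fraction":
            tile_box = box(
                x_um / mpp0, y_um / mpp0,
                (x_um + tile_um) / mpp0, (y_um + tile_um) / mpp0,
            )
            return union.intersection(tile_box).area / tile_box.area >= roi_fraction_min
        raise ValueError(f"unknown roi_method {roi_method!r}")

    coords: list[tuple[float, float]] = []
    eps = 1e-6
    y_um = 0.0
    while y_um + tile_um <= pyramid.height_um + eps:
        x_um = 0.0
        while x_um + tile_um <= pyramid.width_um + eps:
            tx, ty = x_um, y_um
            if rng is not None:
                tx = float(np.clip(
                    tx + rng.uniform(-stride_um / 4, stride_um / 4),
                    0, pyramid.width_um - tile_um,
                ))
                ty = float(np.clip(
                    ty + rng.uniform(-stride_um / 4, stride_um / 4),
                    0, pyramid.height_um - tile_um,
                ))
            keep = True
            if include_union is not None and not passes(include_union, tx, ty):
                keep = False
            if keep and exclude_union is not None and passes(exclude_union, tx, ty):
                keep = False
            if keep and qc is not None:
                if masked_fraction(qc, tx, ty, tile_um) > mask_fraction_max:
                    keep = False
            if keep:
                coords.append((tx, ty))
            x_um += stride_um
        y_um += stride_um

    provenance = hashlib.sha256(
        json.dumps(
            {
                "slide_id": pyramid.slide_id,
                "tile_um": tile_um,
                "tile_px": tile_px,
                "stride_um": stride_um,
                "roi_method": roi_method,
                "mask_fraction_max": mask_fraction_max,
                "jitter_seed": jitter_seed,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    return TileGrid(
        slide_id=pyramid.slide_id,
        tile_px=tile_px,
        tile_um=tile_um,
        stride_um=stride_um,
        coords=coords,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# tile-level background filtering


def grayspace_fraction(tile: np.ndarray, sat_threshold: float = 0.05) -> float:
    """Fraction of pixels with HSV saturation below the threshold."""
    hsv = rgb2hsv(np.asarray(tile, dtype=np.uint8))
    return float((hsv[..., 1] < sat_threshold).mean())


def whitespace_fraction(tile: np.ndarray, bright_threshold: float = 230.0) -> float:
    """Fraction of pixels whose mean-RGB brightness exceeds the threshold."""
    brightness = np.asarray(tile, dtype=np.float64).mean(axis=-1)
    return float((brightness > bright_threshold).mean())


def _filter_read(
    pyramid: SlidePyramid, x_um: float, y_um: float, tile_um: float,
    cfg: FilterConfig,
) -> np.ndarray:
    """Low-magnification read of a tile footprint for background filtering."""
    if cfg.filter_mpp is not None:
        mpp = cfg.filter_mpp
    else:
        # coarsest level still giving >= 8 px per tile
        mpp = pyramid.level0_mpp
        for lv in pyramid.levels:
            if tile_um / lv.mpp >= 8:
                mpp = lv.mpp
    px = max(int(round(tile_um / mpp)), 4)
    return read_region_um(pyramid, x_um, y_um, tile_um, px)


def should_discard(
    pyramid: SlidePyramid,
    coord: tuple[float, float],
    tile_um: float,
    cfg: FilterConfig = FilterConfig(),
    methods: Sequence[str] = ("grayspace",),
) -> tuple[bool, dict[str, float]]:
    """Background decision for one tile, with the measured fractions.

    Reads the footprint at low magnification and discards when any
    requested fraction exceeds its configured cutoff.  With no methods the
    tile is always kept (and nothing is read).
    """
    fractions: dict[str, float] = {}
    if not methods:
        return False, fractions
    img = _filter_read(pyramid, coord[0], coord[1], tile_um, cfg)
    discard = False
    for m in methods:
        if m == "grayspace":
            frac = grayspace_fraction(img, cfg.grayspace_sat_threshold)
            fractions[m] = frac
            discard |= frac > cfg.grayspace_fraction
        elif m == "whitespace":
            frac = whitespace_fraction(img, cfg.whitespace_bright_threshold)
            fractions[m] = frac
            discard |= frac > cfg.whitespace_fraction
        else:
            raise ValueError(f"unknown filter method {m!r}")
    return discard, fractions


# ---------------------------------------------------------------------------
# extraction


def extract_tiles(
    pyramid: SlidePyramid,
    grid: TileGrid,
    out_path: str | os.PathLike,
    filter_cfg: FilterConfig = FilterConfig(),
    methods: Sequence[str] = (),
    normalizer=None,
    codec: str = "png",
    jpeg_quality: int = 100,
    interpolation: str = "bilinear",
    seed: int = 0,
    extra_lineage: dict | None = None,
) -> tuple[int, LineageLog, dict]:
    """Extract surviving grid tiles into a tile store.

    Pipeline per tile: optional low-magnification background filtering →
    full-resolution micron-based read → optional stain normalization →
    encode → append to the store.  Returns the written count, the lineage
    log (also written next to the store), and a machine-readable report.
    """
    out_path = os.fspath(out_path)
    records: list[TileRecord] = []
    discarded: list[dict] = []
    failures = 0
    mpp0 = pyramid.level0_mpp
    for x_um, y_um in grid.coords:
        drop, fractions = should_discard(
            pyramid, (x_um, y_um), grid.tile_um, filter_cfg, methods
        )
        if drop:
            discarded.append({"x_um": x_um, "y_um": y_um, **fractions})
            continue
        try:
            img = read_region_um(
                pyramid, x_um, y_um, grid.tile_um, grid.tile_px,
                interpolation=interpolation,
            )
            if normalizer is not None:
                img = normalizer.transform(img)
            payload = encode_tile(img, codec, quality=jpeg_quality)
        except Exception:
            failures += 1
            continue
        records.append(
            TileRecord(
                slide_id=grid.slide_id,
                x=int(round(x_um / mpp0)),
                y=int(round(y_um / mpp0)),
                codec=codec,
                payload=payload,
            )
        )
    index = write_store(records, out_path, tile_px=grid.tile_px, tile_um=grid.tile_um)

    lineage = LineageLog(
        params={
            "software_version": _pkg_version,
            "slide_id": pyramid.slide_id,
            "tile_um": grid.tile_um,
            "tile_px": grid.tile_px,
            "stride_um": grid.stride_um,
            "grid_provenance": grid.provenance,
            "filter": {
                "methods": list(methods),
                "grayspace_sat_threshold": filter_cfg.grayspace_sat_threshold,
                "grayspace_fraction": filter_cfg.grayspace_fraction,
                "whitespace_bright_threshold": filter_cfg.whitespace_bright_threshold,
                "whitespace_fraction": filter_cfg.whitespace_fraction,
                "filter_mpp": filter_cfg.filter_mpp,
            },
            "normalizer": type(normalizer).__name__ if normalizer else None,
            "codec": codec,
            "jpeg_quality": jpeg_quality,
            "interpolation": interpolation,
            "seed": seed,
            **(extra_lineage or {}),
        }
    )
    with open(out_path + ".lineage.json", "w") as fh:
        fh.write(lineage.to_json())

    report = extraction_report(pyramid, grid, index, discarded, failures)
    with open(out_path + ".report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return index.n_records, lineage, report


def extraction_report(
    pyramid: SlidePyramid,
    grid: TileGrid,
    index: StoreIndex,
    discarded: list[dict],
    failures: int = 0,
) -> dict:
    """Machine-readable per-slide extraction summary."""
    return {
        "slides": [
            {
                "slide_id": pyramid.slide_id,
                "grid_tiles": grid.n_tiles,
                "n_written": index.n_records,
                "n_discarded": len(discarded),
                "n_failures": failures,
                "discarded": discarded,
            }
        ],
        "total_written": index.n_records,
    }


def render_report(
    pyramid: SlidePyramid,
    grid: TileGrid,
    report: dict,
    out_path: str | os.PathLike,
    index: StoreIndex | None = None,
    n_samples: int = 4,
    thumb_mpp: float = 16.0,
) -> str:
    """Visual summary: thumbnail with kept/discarded tile overlay + samples.

    One page per slide; written as PDF (or PNG if the path says so).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    out_path = os.fspath(out_path)
    thumb = thumbnail(pyramid, thumb_mpp)
    kept = set()
    if index is not None:
        from .store import iter_records

        mpp0 = pyramid.level0_mpp
        kept = {
            (round(rec.x * mpp0, 3), round(rec.y * mpp0, 3))
            for rec in iter_records(index.path)
        }

    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    ax = axes[0]
    ax.imshow(thumb)
    scale = 1.0 / thumb_mpp
    for x_um, y_um in grid.coords:
        is_kept = (round(x_um, 3), round(y_um, 3)) in kept if index else True
        ax.add_patch(
            patches.Rectangle(
                (x_um * scale, y_um * scale),
                grid.tile_um * scale,
                grid.tile_um * scale,
                fill=False,
                linewidth=0.8,
                edgecolor="tab:green" if is_kept else "tab:red",
            )
        )
    ax.set_title(f"{pyramid.slide_id}: {report['total_written']} tiles kept")
    ax.axis("off")

    ax = axes[1]
    ax.axis("off")
    lines = [
        f"tile {grid.tile_um:g} um / {grid.tile_px} px",
        f"stride {grid.stride_um:g} um",
        f"grid {grid.n_tiles}, written {report['total_written']}",
    ]
    ax.text(0.05, 0.9, "\n".join(lines), va="top", family="monospace")
    if index is not None and n_samples > 0:
        from .store import read_tiles

        for i, (img, *_rest) in enumerate(read_tiles(index.path)):
            if i >= n_samples:
                break
            inset = ax.inset_axes([0.05 + 0.24 * i, 0.1, 0.2, 0.35])
            inset.imshow(img)
            inset.axis("off")
    fig.savefig(out_path, bbox_inches="tight")
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# ROI I/O


def load_rois_csv(path: str | os.PathLike) -> list[ROI]:
    """ROIs from CSV columns: slide, label, role, x, y (one vertex per row)."""
    df = pd.read_csv(path)
    needed = {"slide", "label", "x", "y"}
    if not needed.issubset(df.columns):
        raise ROIError(f"ROI CSV needs columns {sorted(needed)}")
    rois = []
    group_cols = ["slide", "label"] + (["role"] if "role" in df.columns else [])
    for key, g in df.groupby(group_cols, sort=True):
        key = (key,) if not isinstance(key, tuple) else key
        slide, label = str(key[0]), str(key[1])
        role = str(key[2]) if len(key) > 2 else "include"
        rois.append(
            ROI(
                slide_id=slide,
                label=label,
                vertices=tuple(zip(g["x"].astype(float), g["y"].astype(float))),
                role=role,
            )
        )
    return rois


def load_rois_geojson(path: str | os.PathLike, slide_id: str) -> list[ROI]:
    """ROIs from a GeoJSON FeatureCollection of Polygons."""
    with open(path) as fh:
        doc = json.load(fh)
    rois = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            continue
        props = feat.get("properties", {}) or {}
        rois.append(
            ROI(
                slide_id=slide_id,
                label=str(props.get("label", f"roi_{i}")),
                vertices=tuple(tuple(v) for v in geom["coordinates"][0]),
                role=str(props.get("role", "include")),
            )
        )
    return rois
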