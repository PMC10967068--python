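"""Mosaic maps: image-tile overlays on a 2-D feature embedding.

Tile feature vectors (from any external extractor) are projected to 2-D —
UMAP by default, PCA as a deterministic lightweight fallback — and the
projection's bounding box is partitioned into a uniform g x g grid
(default 50 x 50).  Each nonempty cell shows one representative tile,
chosen uniformly at random (default) or as the member nearest the cell
centroid.  The result reads as a map of morphology space: neighbouring
cells hold visually similar tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RenderError

__all__ = [
    "EmbeddingSet",
    "MosaicGrid",
    "project_features",
    "build_mosaic",
    "render_mosaic",
]


@dataclass
class EmbeddingSet:
    """2-D embedded points with resolvable tile references."""

    coords: np.ndarray  # (n, 2)
    keys: list  # per-point tile reference, e.g. (slide_id, x, y)
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")
        if len(self.keys) != len(self.coords):
            raise ValueError("one key per point required")

    @property
    def n(self) -> int:
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y"])
        df["key"] = [repr(k) for k in self.keys]
        if self.labels is not None:
            df["label"] = self.labels
        return df


@dataclass
class MosaicGrid:
    """Uniform partition of the embedding bounding box with one pick per cell."""

    grid_n: int
    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    cells: dict[tuple[int, int], int]  # (row, col) -> point index
    embedding: EmbeddingSet

    @property
    def n_occupied(self) -> int:
        return len(self.cells)

    def manifest(self) -> dict:
        return {
            "grid_n": self.grid_n,
            "bounds": list(self.bounds),
            "cells": {
                f"{i},{j}": repr(self.embedding.keys[idx])
                for (i, j), idx in sorted(self.cells.items())
            },
        }


def project_features(
    features: np.ndarray,
    seed: int = 0,
    keys: list | None = None,
    labels: np.ndarray | None = None,
    method: str = "umap",
    **kwargs,
) -> EmbeddingSet:
    """Project an N x D feature matrix to 2-D.

    A thin adapter: ``method="umap"`` delegates to umap-learn with a fixed
    random state; ``method="pca"`` uses the top-2 principal components (a
    fast deterministic stand-in for tests and environments without UMAP).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 10:
        raise ValueError("need an N x D matrix with N >= 10")
    if not np.isfinite(features).all():
        raise ValueError("feature matrix contains non-finite values")
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
        coords = reducer.fit_transform(features)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(features)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    if keys is None:
        keys = list(range(len(features)))
    return EmbeddingSet(coords=np.asarray(coords), keys=keys, labels=labels)


def build_mosaic(
    emb: EmbeddingSet,
    grid_n: int = 50,
    selection: str = "random",
    rng: np.random.Generator | int | None = None,
) -> MosaicGrid:
    """Partition the embedding into a grid and pick one point per cell.

    Cells are half-open; points on the upper boundary belong to the last
    cell.  ``selection`` is ``random`` (seeded uniform choice among cell
    members) or ``centroid`` (member nearest the cell's center).
    """
    if emb.n == 0:
        raise ValueError("empty embedding")
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    xmin, ymin = emb.coords.min(axis=0)
    xmax, ymax = emb.coords.max(axis=0)
    # degenerate (single point / collinear) boxes still get a valid partition
    wx = (xmax - xmin) or 1.0
    wy = (ymax - ymin) or 1.0
    cols = np.clip(((emb.coords[:, 0] - xmin) / wx * grid_n).astype(int), 0, grid_n - 1)
    rows = np.clip(((emb.coords[:, 1] - ymin) / wy * grid_n).astype(int), 0, grid_n - 1)

    cells: dict[tuple[int, int], int] = {}
    members: dict[tuple[int, int], list[int]] = {}
    for idx, (i, j) in enumerate(zip(rows, cols)):
        members.setdefault((int(i), int(j)), []).append(idx)

    for cell in sorted(members):
        idxs = members[cell]
        if selection == "random":
            cells[cell] = int(idxs[rng.integers(0, len(idxs))])
        elif selection == "centroid":
            i, j = cell
            cx = xmin + (j + 0.5) * wx / grid_n
            cy = ymin + (i + 0.5) * wy / grid_n
            pts = emb.coords[idxs]
            d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
            cells[cell] = int(idxs[int(np.argmin(d2))])
        else:
            raise ValueError(f"unknown selection mode {selection!r}")
    return MosaicGrid(
        grid_n=grid_n, bounds=(xmin, ymin, xmax, ymax), cells=cells, embedding=emb
    )


def render_mosaic(
    mosaic: MosaicGrid,
    resolve_tile,
    tile_size_px: int = 32,
) -> np.ndarray:
    """Paint selected tiles onto a grid canvas (RGBA; empty cells transparent).

    ``resolve_tile`` maps a point's tile key to an RGB uint8 array; it may
    raise KeyError for unresolvable keys, which becomes a render error
    naming the key.  Row 0 of the canvas is the cell with the smallest y,
    matching image coordinates.
    """
    from PIL import Image

    g, ts = mosaic.grid_n, tile_size_px
    canvas = np.zeros((g * ts, g * ts, 4), dtype=np.uint8)
    for (i, j), idx in mosaic.cells.items():
        key = mosaic.embedding.keys[idx]
        try:
            tile = np.asarray(resolve_tile(key))
        except KeyError as exc:
            raise RenderError(f"cannot resolve tile for key {key!r}") from exc
        if tile.shape[0] != ts:
            tile = np.asarray(
                Image.fromarray(tile.astype(np.uint8)).resize((ts, ts), Image.BILINEAR)
            )
        canvas[i * ts : (i + 1) * ts, j * ts : (j + 1) * ts, :3] = tile[..., :3]
        canvas[i * ts : (i + 1) * ts, j * ts : (j + 1) * ts, 3] = 255
    return canvas
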