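"""Indexed tile-record container, decode-time augmentation, and balanced sampling.

Extracted tiles are buffered into a single append-only ``.tiles`` file — a
length-prefixed record stream with a JSON header — plus a ``.idx`` JSON
sidecar holding byte offsets and per-slide counts.  The format is
self-describing and framework-free; iterating it is much faster than
re-reading tiles from the slide.  Each record stores the encoded image
(JPEG or PNG) together with its slide identifier and level-0 (x, y)
location, so predictions can later be mapped back onto the slide.

Label joining attaches a per-slide outcome (and patient) from a CSV
annotations table.  Balanced batch sampling oversamples minority classes
and/or under-tiled slides with replacement so every batch carries equal
class (and slide) representation; one epoch is ``floor(n_tiles /
batch_size)`` batches regardless of balancing.
"""

from __future__ import annotations

import io
import json
import os
import struct
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import (
    BalancingError,
    DuplicateRecordError,
    SchemaError,
    StoreError,
)

__all__ = [
    "TileRecord",
    "StoreIndex",
    "LabeledDataset",
    "encode_tile",
    "decode_tile",
    "write_store",
    "read_tiles",
    "augment_image",
    "standardize",
    "join_labels",
    "balanced_batches",
    "epoch_length",
]

_MAGIC = b"HTTS"
_VERSION = 1


@dataclass(frozen=True)
class TileRecord:
    slide_id: str
    x: int
    y: int
    codec: str  # "jpeg" | "png"
    payload: bytes

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.slide_id, self.x, self.y)


@dataclass
class StoreIndex:
    path: str
    offsets: list[int]
    slide_counts: dict[str, int]
    tile_px: int | None = None
    tile_um: float | None = None

    @property
    def n_records(self) -> int:
        return len(self.offsets)

    def to_json(self) -> str:
        return json.dumps(
            {
                "offsets": self.offsets,
                "slide_counts": self.slide_counts,
                "tile_px": self.tile_px,
                "tile_um": self.tile_um,
            },
            sort_keys=True,
        )


def encode_tile(img: np.ndarray, codec: str = "png", quality: int = 100) -> bytes:
    """Encode an RGB uint8 tile. JPEG quality defaults to 100."""
    buf = io.BytesIO()
    pil = Image.fromarray(np.asarray(img, dtype=np.uint8))
    if codec == "png":
        pil.save(buf, format="PNG")
    elif codec == "jpeg":
        pil.save(buf, format="JPEG", quality=quality, subsampling=0)
    else:
        raise ValueError(f"unknown codec {codec!r}")
    return buf.getvalue()


def decode_tile(payload: bytes) -> np.ndarray:
    return np.asarray(Image.open(io.BytesIO(payload)).convert("RGB"))


def write_store(
    tiles: Iterable[TileRecord],
    path: str | os.PathLike,
    tile_px: int | None = None,
    tile_um: float | None = None,
) -> StoreIndex:
    """Write records to a ``.tiles`` stream plus ``.idx`` sidecar.

    Records are framed as ``uint32 meta_len | meta JSON | payload``; the
    header frame carries format metadata.  Duplicate (slide, x, y) keys
    raise before anything corrupt lands on disk.
    """
    path = os.fspath(path)
    seen: set[tuple[str, int, int]] = set()
    offsets: list[int] = []
    slide_counts: dict[str, int] = {}
    with open(path, "wb") as fh:
        header = json.dumps(
            {"version": _VERSION, "tile_px": tile_px, "tile_um": tile_um},
            sort_keys=True,
        ).encode()
        fh.write(_MAGIC + struct.pack("<I", len(header)) + header)
        for rec in tiles:
            if rec.key in seen:
                raise DuplicateRecordError(
                    f"duplicate tile record {rec.key} in {path}"
                )
            seen.add(rec.key)
            meta = json.dumps(
                {
                    "slide_id": rec.slide_id,
                    "x": rec.x,
                    "y": rec.y,
                    "codec": rec.codec,
                    "payload_len": len(rec.payload),
                },
                sort_keys=True,
            ).encode()
            offsets.append(fh.tell())
            fh.write(struct.pack("<I", len(meta)) + meta + rec.payload)
            slide_counts[rec.slide_id] = slide_counts.get(rec.slide_id, 0) + 1
    index = StoreIndex(
        path=path,
        offsets=offsets,
        slide_counts=slide_counts,
        tile_px=tile_px,
        tile_um=tile_um,
    )
    with open(path + ".idx", "w") as fh:
        fh.write(index.to_json())
    return index


def load_index(path: str | os.PathLike) -> StoreIndex:
    path = os.fspath(path)
    with open(path + ".idx") as fh:
        d = json.load(fh)
    return StoreIndex(
        path=path,
        offsets=d["offsets"],
        slide_counts=d["slide_counts"],
        tile_px=d.get("tile_px"),
        tile_um=d.get("tile_um"),
    )


def _read_record(fh) -> TileRecord:
    raw = fh.read(4)
    if len(raw) < 4:
        raise StoreError("truncated record frame")
    (meta_len,) = struct.unpack("<I", raw)
    meta = json.loads(fh.read(meta_len))
    payload = fh.read(meta["payload_len"])
    if len(payload) < meta["payload_len"]:
        raise StoreError("truncated payload")
    return TileRecord(
        slide_id=meta["slide_id"],
        x=meta["x"],
        y=meta["y"],
        codec=meta["codec"],
        payload=payload,
    )


def iter_records(
    path: str | os.PathLike,
    slides: Sequence[str] | None = None,
    shuffle_seed: int | None = None,
    strict: bool = True,
) -> Iterator[TileRecord]:
    """Yield raw records, optionally slide-filtered and seed-shuffled."""
    index = load_index(path)
    order = np.arange(index.n_records)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(order)
    keep = None if slides is None else set(slides)
    with open(index.path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise StoreError(f"not a tile store: {index.path}")
        for i in order:
            fh.seek(index.offsets[i])
            try:
                rec = _read_record(fh)
            except StoreError:
                if strict:
                    raise
                continue
            if keep is None or rec.slide_id in keep:
                yield rec


def read_tiles(
    path: str | os.PathLike,
    slides: Sequence[str] | None = None,
    shuffle_seed: int | None = None,
    strict: bool = True,
) -> Iterator[tuple[np.ndarray, str, int, int]]:
    """Yield decoded ``(image, slide_id, x, y)`` tuples."""
    for rec in iter_records(path, slides, shuffle_seed, strict):
        yield decode_tile(rec.payload), rec.slide_id, rec.x, rec.y


# ---------------------------------------------------------------------------
# decode-time augmentation and standardization

_BLUR_SIGMAS = (0.5, 1.0, 1.5, 2.0)


def augment_image(
    img: np.ndarray,
    ops: Sequence[str] = ("flip-rotate",),
    rng: np.random.Generator | None = None,
    p_jpeg: float = 0.1,
    p_blur: float = 0.1,
) -> np.ndarray:
    """Random tile augmentation: dihedral flips/rotations, JPEG, blur.

    ``flip-rotate`` draws uniformly from the 8 square symmetries; ``jpeg``
    re-encodes at quality uniform in [50, 100] with probability ``p_jpeg``;
    ``blur`` applies a Gaussian with sigma from {0.5, 1, 1.5, 2} with
    probability ``p_blur``.
    """
    img = np.asarray(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError("augmentation expects square tiles")
    if rng is None:
        rng = np.random.default_rng()
    out = img
    for op in ops:
        if op == "flip-rotate":
            k = int(rng.integers(0, 8))
            out = np.rot90(out, k % 4)
            if k >= 4:
                out = out[:, ::-1]
        elif op == "jpeg":
            if rng.random() < p_jpeg:
                quality = int(rng.integers(50, 101))
                out = decode_tile(encode_tile(out, "jpeg", quality=quality))
        elif op == "blur":
            if rng.random() < p_blur:
                sigma = _BLUR_SIGMAS[int(rng.integers(0, len(_BLUR_SIGMAS)))]
                out = gaussian_filter(
                    out.astype(float), sigma=(sigma, sigma, 0)
                ).astype(np.uint8)
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    return np.ascontiguousarray(out)


def standardize(img: np.ndarray, mode: str = "zscore") -> np.ndarray:
    """Convert an 8-bit tile to floats: per-image z-score or 0–1 range."""
    img = np.asarray(img, dtype=np.float64)
    if mode == "unit":
        return img / 255.0
    if mode == "zscore":
        std = img.std()
        if std < 1e-12:
            return np.zeros_like(img)
        return (img - img.mean()) / std
    raise ValueError(f"unknown standardization mode {mode!r}")


# ---------------------------------------------------------------------------
# labels and balancing


@dataclass
class LabeledDataset:
    """Tile metadata joined with per-slide outcome and patient labels."""

    tiles: pd.DataFrame  # columns: slide_id, x, y, record_index
    labels: dict[str, object]  # slide_id -> outcome
    patients: dict[str, str]  # slide_id -> patient_id
    missing: list[str] = field(default_factory=list)
    outcome_type: str = "categorical"

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def tile_labels(self) -> np.ndarray:
        return self.tiles["slide_id"].map(self.labels).to_numpy()


def join_labels(
    index: StoreIndex | str,
    annotations: pd.DataFrame | str | os.PathLike,
    outcome_column: str = "outcome",
    slide_column: str = "slide",
    patient_column: str = "patient",
    categorical: bool | None = None,
) -> LabeledDataset:
    """Attach outcome labels from an annotations table to store records.

    Slides present in the store but absent from the table are listed in
    ``missing`` rather than silently dropped.  Numeric outcomes are treated
    as continuous unless ``categorical=True``.
    """
    if not isinstance(index, StoreIndex):
        index = load_index(index)
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, dtype={slide_column: str})
    for col in (slide_column, outcome_column):
        if col not in annotations.columns:
            raise SchemaError(f"annotations table lacks column {col!r}")
    has_patient = patient_column in annotations.columns

    labels: dict[str, object] = {}
    patients: dict[str, str] = {}
    for _, row in annotations.iterrows():
        sid = str(row[slide_column])
        labels[sid] = row[outcome_column]
        patients[sid] = str(row[patient_column]) if has_patient else sid

    rows = []
    missing = []
    pos = 0
    for rec in iter_records(index.path):
        rows.append((rec.slide_id, rec.x, rec.y, pos))
        pos += 1
    tiles = pd.DataFrame(rows, columns=["slide_id", "x", "y", "record_index"])
    for sid in index.slide_counts:
        if sid not in labels:
            missing.append(sid)
    tiles = tiles[~tiles["slide_id"].isin(missing)].reset_index(drop=True)

    values = pd.Series([labels[s] for s in tiles["slide_id"].unique()])
    numeric = pd.api.types.is_numeric_dtype(values)
    if categorical is None:
        outcome_type = "continuous" if numeric else "categorical"
    else:
        outcome_type = "categorical" if categorical else "continuous"
    return LabeledDataset(
        tiles=tiles,
        labels=labels,
        patients=patients,
        missing=missing,
        outcome_type=outcome_type,
    )


def epoch_length(n_tiles: int, batch_size: int) -> int:
    """Batches per epoch: total tiles divided by batch size, floored."""
    return n_tiles // batch_size


def _split_evenly(batch_size: int, n_strata: int, rng: np.random.Generator) -> np.ndarray:
    """Per-stratum counts summing to batch_size, equal within 1."""
    base = batch_size // n_strata
    counts = np.full(n_strata, base, dtype=int)
    extra = batch_size - base * n_strata
    if extra:
        counts[rng.choice(n_strata, size=extra, replace=False)] += 1
    return counts


def balanced_batches(
    ds: LabeledDataset,
    batch_size: int,
    balance: str = "none",
    rng: np.random.Generator | int | None = None,
    n_batches: int | None = None,
) -> Iterator[np.ndarray]:
    """Yield index batches with optional class/slide balancing.

    ``balance`` is one of ``none`` (uniform over tiles), ``slide`` (equal
    slide representation per batch), ``category`` (equal class
    representation), or ``both`` (classes equalized, then slides within
    class).  Balancing samples with replacement, so minority strata are
    oversampled.  The epoch length is ``floor(n_tiles / batch_size)``
    batches unless ``n_batches`` overrides it.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n = ds.n_tiles
    if n == 0:
        raise BalancingError("dataset has no tiles")
    total = epoch_length(n, batch_size) if n_batches is None else n_batches

    tile_slides = ds.tiles["slide_id"].to_numpy()
    if balance in ("category", "both"):
        tile_classes = ds.tile_labels()
        classes = sorted(set(tile_classes.tolist()), key=str)
        by_class = {c: np.flatnonzero(tile_classes == c) for c in classes}
        for c, idx in by_class.items():
            if idx.size == 0:
                raise BalancingError(f"class {c!r} has no tiles")
    if balance in ("slide", "both"):
        slides = sorted(ds.tiles["slide_id"].unique().tolist())
        by_slide = {s: np.flatnonzero(tile_slides == s) for s in slides}

    for _ in range(total):
        if balance == "none":
            yield rng.integers(0, n, size=batch_size)
        elif balance == "slide":
            counts = _split_evenly(batch_size, len(slides), rng)
            parts = [
                rng.choice(by_slide[s], size=c, replace=True)
                for s, c in zip(slides, counts)
                if c
            ]
            yield rng.permutation(np.concatenate(parts))
        elif balance == "category":
            counts = _split_evenly(batch_size, len(classes), rng)
            parts = [
                rng.choice(by_class[c], size=k, replace=True)
                for c, k in zip(classes, counts)
                if k
            ]
            yield rng.permutation(np.concatenate(parts))
        elif balance == "both":
            counts = _split_evenly(batch_size, len(classes), rng)
            parts = []
            for c, k in zip(classes, counts):
                if not k:
                    continue
                class_slides = sorted(set(tile_slides[by_class[c]].tolist()))
                per_slide = _split_evenly(k, len(class_slides), rng)
                for s, m in zip(class_slides, per_slide):
                    if m:
                        members = by_class[c][tile_slides[by_class[c]] == s]
                        parts.append(rng.choice(members, size=m, replace=True))
            yield rng.permutation(np.concatenate(parts))
        else:
            raise ValueError(f"unknown balance mode {balance!r}")
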