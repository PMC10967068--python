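"""Prediction aggregation, Monte-Carlo-dropout uncertainty, and heatmaps.

Weakly-supervised tile classifiers predict each tile independently;
slide-level predictions average the tile predictions for the slide, and
patient-level predictions average *all* tile predictions across a
patient's slides (pooled, not a mean of slide means, so slides contribute
in proportion to their tile counts).

Uncertainty comes from Monte Carlo dropout: a tile is passed through the
network K times with dropout active; the mean of the K probability vectors
is the prediction and the standard deviation of the predicted-class
probability is the uncertainty.  Confidence thresholding then discards
uncertain predictions: an uncertainty cutoff is searched on validation
data — first at the tile level, then, after aggregating surviving tiles,
at the slide level — using nested cross-validation so the thresholds never
see the data they are applied to.  Retained (high-confidence) predictions
are more likely to be correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, ConsistencyError
from .tiling import TileGrid

__all__ = [
    "ThresholdPair",
    "mc_dropout_stats",
    "aggregate",
    "threshold_search",
    "apply_thresholds",
    "assemble_heatmap",
    "render_heatmap",
]


@dataclass(frozen=True)
class ThresholdPair:
    theta_tile: float
    theta_slide: float
    retention: float = 1.0

    def __post_init__(self):
        if self.theta_tile < 0 or self.theta_slide < 0:
            raise ValueError("uncertainty thresholds must be >= 0")
        if not (0 <= self.retention <= 1):
            raise ValueError("retention must lie in [0, 1]")


def mc_dropout_stats(passes: np.ndarray) -> tuple[np.ndarray, float]:
    """Prediction mean and uncertainty from K stochastic forward passes.

    ``passes`` is K x C (rows are probability vectors).  The mean is the
    column mean; the uncertainty is the population standard deviation of
    the predicted-class probability across passes (for binary problems,
    the std of the class-1 probability).
    """
    passes = np.asarray(passes, dtype=float)
    if passes.ndim != 2 or passes.shape[0] < 2:
        raise ValueError("need a K x C matrix with K >= 2 passes")
    mean = passes.mean(axis=0)
    if passes.shape[1] == 2:
        cls = 1
    else:
        cls = int(np.argmax(mean))
    uncertainty = float(passes[:, cls].std())
    return mean, uncertainty


def _prob_columns(preds: pd.DataFrame) -> list[str]:
    cols = [c for c in preds.columns if c.startswith("p_")]
    if not cols:
        raise ValueError("prediction table needs p_0..p_C probability columns")
    return cols


def aggregate(
    preds: pd.DataFrame,
    level: str = "slide",
    patients: dict[str, str] | None = None,
    fn=None,
) -> pd.DataFrame:
    """Average tile predictions to slide or patient level.

    ``preds`` has columns ``slide_id`` and ``p_*``; ``patients`` maps
    slide_id to patient_id (required at patient level).  ``fn`` may replace
    the mean: it receives an (n_tiles x C) array and returns a C-vector.
    Patient-level pooling is over tiles, never over slide means.
    """
    cols = _prob_columns(preds)
    if level == "slide":
        group = preds["slide_id"]
    elif level == "patient":
        if patients is None:
            raise AggregationError("patient-level aggregation needs a patient map")
        unmapped = set(preds["slide_id"]) - set(patients)
        if unmapped:
            raise AggregationError(f"slides without a patient mapping: {sorted(unmapped)}")
        group = preds["slide_id"].map(patients)
    else:
        raise ValueError(f"unknown aggregation level {level!r}")

    if fn is None:
        out = preds.groupby(group, sort=True)[cols].mean()
    else:
        out = preds.groupby(group, sort=True)[cols].apply(
            lambda g: pd.Series(np.asarray(fn(g.to_numpy())), index=cols)
        )
    out.index.name = level + "_id"
    if "uncertainty" in preds.columns:
        out["uncertainty"] = preds.groupby(group, sort=True)["uncertainty"].mean()
    return out.reset_index()


def _scan_threshold(
    unc: np.ndarray, correct: np.ndarray, retention_min: float
) -> float:
    """Best uncertainty cutoff: max accuracy among retained, retention floor.

    Candidates are the unique uncertainty values (retain-all included).
    Ties prefer the larger threshold (higher retention).
    """
    candidates = np.unique(unc)
    best_theta = float(candidates[-1])
    best_acc = -1.0
    n = len(unc)
    for theta in candidates[::-1]:  # descending: ties keep larger theta
        keep = unc <= theta
        if keep.sum() / n < retention_min:
            continue
        acc = correct[keep].mean()
        if acc > best_acc:
            best_acc = acc
            best_theta = float(theta)
    return best_theta


def threshold_search(
    preds: pd.DataFrame,
    labels: dict[str, int],
    splitter=None,
    retention_min: float = 0.9,
) -> ThresholdPair:
    """Search tile- and slide-level uncertainty cutoffs on validation data.

    ``preds`` holds tile predictions (``slide_id``, ``p_*``,
    ``uncertainty``); ``labels`` maps slide_id to the true class index.
    The splitter (default 3-fold over slides) provides the nested
    cross-validation: thresholds are scanned on each fold's training
    slides and averaged; retention is measured on the held-out slides.
    """
    from sklearn.model_selection import KFold

    cols = _prob_columns(preds)
    slides = np.array(sorted(preds["slide_id"].unique()))
    if splitter is None:
        splitter = KFold(n_splits=min(3, len(slides)))

    probs = preds[cols].to_numpy()
    pred_class = probs.argmax(axis=1)
    true_class = preds["slide_id"].map(labels).to_numpy()
    correct = (pred_class == true_class).astype(float)
    unc = preds["uncertainty"].to_numpy()

    if correct.all() or not correct.any():
        warnings.warn(
            "validation predictions are all correct or all wrong; "
            "retaining everything"
        )
        theta = float(unc.max())
        return ThresholdPair(theta_tile=theta, theta_slide=theta, retention=1.0)

    tile_thetas, slide_thetas, retentions = [], [], []
    for train_idx, test_idx in splitter.split(slides):
        train_slides = set(slides[train_idx])
        in_train = preds["slide_id"].isin(train_slides).to_numpy()
        if in_train.sum() == 0:
            continue
        theta_t = _scan_threshold(unc[in_train], correct[in_train], retention_min)
        tile_thetas.append(theta_t)

        # aggregate surviving training tiles to slides, scan slide level
        keep = in_train & (unc <= theta_t)
        if keep.sum():
            sub = preds.loc[keep]
            slide_df = aggregate(sub, level="slide")
            s_pred = slide_df[cols].to_numpy().argmax(axis=1)
            s_true = slide_df["slide_id"].map(labels).to_numpy()
            s_unc = slide_df["uncertainty"].to_numpy()
            slide_thetas.append(
                _scan_threshold(s_unc, (s_pred == s_true).astype(float), retention_min)
            )
        # outer retention
        test_slides = set(slides[test_idx])
        in_test = preds["slide_id"].isin(test_slides).to_numpy()
        if in_test.sum():
            retentions.append(float((unc[in_test] <= theta_t).mean()))

    theta_tile = float(np.mean(tile_thetas)) if tile_thetas else float(unc.max())
    theta_slide = float(np.mean(slide_thetas)) if slide_thetas else theta_tile
    retention = float(np.mean(retentions)) if retentions else 1.0
    return ThresholdPair(
        theta_tile=theta_tile, theta_slide=theta_slide, retention=retention
    )


def apply_thresholds(
    preds: pd.DataFrame, thetas: ThresholdPair
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Discard uncertain tiles, then flag uncertain slides.

    Returns (kept tile predictions, per-tile dropped flags, slide table).
    Slide predictions aggregate surviving tiles; slide uncertainty is the
    mean surviving-tile uncertainty; slides above the slide cutoff — or
    with no surviving tiles at all — are flagged low-confidence (the
    latter get NaN predictions).
    """
    cols = _prob_columns(preds)
    dropped = (preds["uncertainty"] > thetas.theta_tile).to_numpy()
    kept = preds.loc[~dropped].reset_index(drop=True)

    all_slides = sorted(preds["slide_id"].unique())
    if len(kept):
        slide_df = aggregate(kept, level="slide").set_index("slide_id")
    else:
        slide_df = pd.DataFrame(columns=cols + ["uncertainty"])
    rows = []
    for sid in all_slides:
        if sid in slide_df.index:
            row = slide_df.loc[sid]
            low_conf = bool(row["uncertainty"] > thetas.theta_slide)
            rows.append([sid, *row[cols], row["uncertainty"], low_conf])
        else:
            rows.append([sid, *[np.nan] * len(cols), np.nan, True])
    slides = pd.DataFrame(
        rows, columns=["slide_id", *cols, "uncertainty", "low_confidence"]
    )
    return kept, dropped, slides


# ---------------------------------------------------------------------------
# heatmaps


def assemble_heatmap(
    grid: TileGrid,
    tile_preds: pd.DataFrame,
    class_index: int = 1,
    value_column: str | None = None,
) -> np.ndarray:
    """2-D float map of tile predictions aligned to the tile grid.

    Cell (i, j) holds the prediction of the tile at grid position (row i,
    column j); grid positions without a prediction are NaN.  Set
    ``value_column="uncertainty"`` for an uncertainty map.
    """
    if grid.n_tiles == 0:
        raise ConsistencyError("empty tile grid")
    xs = np.array([c[0] for c in grid.coords])
    ys = np.array([c[1] for c in grid.coords])
    stride = grid.stride_um
    x0, y0 = xs.min(), ys.min()
    n_cols = int(round((xs.max() - x0) / stride)) + 1
    n_rows = int(round((ys.max() - y0) / stride)) + 1
    heat = np.full((n_rows, n_cols), np.nan)

    col = value_column if value_column else f"p_{class_index}"
    if col not in tile_preds.columns:
        raise ConsistencyError(f"prediction table lacks column {col!r}")
    coord_set = {(round(x, 3), round(y, 3)) for x, y in grid.coords}
    for _, row in tile_preds.iterrows():
        key = (round(float(row["x_um"]), 3), round(float(row["y_um"]), 3))
        if key not in coord_set:
            raise ConsistencyError(f"prediction at {key} has no grid tile")
        j = int(round((key[0] - x0) / stride))
        i = int(round((key[1] - y0) / stride))
        heat[i, j] = row[col]
    return heat


def render_heatmap(
    heat: np.ndarray,
    out_path: str,
    thumbnail: np.ndarray | None = None,
    cmap: str = "inferno",
    alpha: float = 0.6,
) -> str:
    """Render a heatmap (NaN cells transparent), optionally over a thumbnail."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if thumbnail is not None:
        ax.imshow(thumbnail, extent=(0, heat.shape[1], heat.shape[0], 0))
    masked = np.ma.masked_invalid(heat)
    im = ax.imshow(
        masked, cmap=cmap, alpha=alpha if thumbnail is not None else 1.0,
        interpolation="nearest", vmin=0, vmax=np.nanmax(heat) if masked.count() else 1,
    )
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.axis("off")
    fig.savefig(out_path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    np.save(out_path + ".npy", heat)
    return out_path
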