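"""H&E stain normalization and randomized-target stain augmentation.

Two normalizer families are provided:

* **Reinhard** — color transfer in CIELAB: each channel of the input is
  shifted and scaled so its mean and standard deviation match those of a
  reference image.  Variants: *masked* (statistics and transform restricted
  to non-white pixels, so blank glass is not tinted pink) and *fast*
  (brightness standardization disabled).
* **Macenko** — stain deconvolution in optical density (OD) space.  Pixel
  OD vectors of H&E tissue lie (to good approximation) in the plane
  spanned by the hematoxylin and eosin absorbance vectors; the fit finds
  those vectors as the angular extremes of the OD point cloud projected on
  its top-2 principal plane, and records the 99th-percentile stain
  concentrations.  Normalization re-expresses an image in the reference's
  stain basis with concentrations rescaled to the reference maxima.
  *Contextual* normalization takes the concentration maxima from a context
  image (e.g. a slide thumbnail) instead of the tile being transformed,
  which stabilizes faint or homogeneous tiles.

Stain *augmentation* perturbs the normalization target itself — every fit
parameter gets independent Gaussian noise before the normal transform is
applied — so augmented tiles are simultaneously normalized and jittered
around the reference staining.  (This is deliberately not deconvolution-
space jitter without normalization.)

Optical density uses base 10 with a +1 offset: ``OD = -log10((I+1)/256)``,
mapping intensity 255 to OD 0 and avoiding log(0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .errors import StainFitError

__all__ = [
    "ReinhardFit",
    "MacenkoFit",
    "AugmentConfig",
    "ReinhardNormalizer",
    "MacenkoNormalizer",
    "fit_reinhard",
    "reinhard_normalize",
    "fit_macenko",
    "macenko_normalize",
    "stain_augment",
    "make_stain_field",
    "default_fit",
    "HE_REFERENCE_MATRIX",
]

WHITE_BRIGHTNESS = 230.0  # same convention as the whitespace tile filter
_BRIGHTNESS_TARGET = 240.0  # 95th-percentile brightness after standardization

# widely used H&E absorbance vectors (rows: hematoxylin, eosin), unit norm
HE_REFERENCE_MATRIX = np.array(
    [[0.65, 0.70, 0.29], [0.07, 0.99, 0.11]], dtype=float
)
HE_REFERENCE_MATRIX /= np.linalg.norm(HE_REFERENCE_MATRIX, axis=1, keepdims=True)

# stain basis for the synthetic stain model: every component clears the
# default OD transparency cutoff (beta 0.15) at unit concentration, so
# near-pure pixels survive the fit's background cut and the true vectors
# remain identifiable; the classic eosin vector's 0.07 red component does not
SIM_STAIN_MATRIX = np.array(
    [[0.65, 0.70, 0.29], [0.19, 0.90, 0.25]], dtype=float
)
SIM_STAIN_MATRIX /= np.linalg.norm(SIM_STAIN_MATRIX, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# fits


@dataclass
class ReinhardFit:
    target_means: np.ndarray  # LAB, shape (3,)
    target_stds: np.ndarray  # LAB, shape (3,)
    mask_white: bool = False
    brightness_standardize: bool = True

    def __post_init__(self):
        self.target_means = np.asarray(self.target_means, dtype=float)
        self.target_stds = np.asarray(self.target_stds, dtype=float)
        if np.any(self.target_stds <= 0):
            raise StainFitError("Reinhard target stds must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "reinhard",
                "version": 1,
                "target_means": self.target_means.tolist(),
                "target_stds": self.target_stds.tolist(),
                "mask_white": self.mask_white,
                "brightness_standardize": self.brightness_standardize,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReinhardFit":
        d = json.loads(text)
        return cls(
            target_means=d["target_means"],
            target_stds=d["target_stds"],
            mask_white=d.get("mask_white", False),
            brightness_standardize=d.get("brightness_standardize", True),
        )


@dataclass
class MacenkoFit:
    stain_matrix: np.ndarray  # (2, 3), rows H then E, unit norm
    max_concentrations: np.ndarray  # (2,), 99th percentiles
    alpha: float = 1.0
    beta: float = 0.15

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        norms = np.linalg.norm(self.stain_matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainFitError("stain matrix rows must have unit norm")
        if np.any(self.max_concentrations <= 0):
            raise StainFitError("max concentrations must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "macenko",
                "version": 1,
                "stain_matrix": self.stain_matrix.tolist(),
                "max_concentrations": self.max_concentrations.tolist(),
                "alpha": self.alpha,
                "beta": self.beta,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MacenkoFit":
        d = json.loads(text)
        return cls(
            stain_matrix=d["stain_matrix"],
            max_concentrations=d["max_concentrations"],
            alpha=d.get("alpha", 1.0),
            beta=d.get("beta", 0.15),
        )


@dataclass(frozen=True)
class AugmentConfig:
    """Randomized-target stain augmentation settings.

    ``sigma_matrix`` jitters the color target (LAB means/stds for Reinhard,
    stain-vector entries for Macenko); ``sigma_cmax`` jitters Macenko's
    maximum concentrations.  Zero sigmas reduce augmentation to plain
    normalization.  Defaults keep augmented images in-gamut and are
    implementation-defined.
    """

    sigma_matrix: float = 0.05
    sigma_cmax: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_matrix < 0 or self.sigma_cmax < 0:
            raise ValueError("augmentation sigmas must be >= 0")


# ---------------------------------------------------------------------------
# helpers


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return img


def _brightness(img: np.ndarray) -> np.ndarray:
    return img.mean(axis=-1)


def _standardize_brightness(img: np.ndarray) -> np.ndarray:
    """Rescale so the 95th-percentile brightness maps to a fixed reference."""
    p95 = np.percentile(_brightness(img.astype(float)), 95)
    if p95 <= 0:
        return img
    out = img.astype(float) * (_BRIGHTNESS_TARGET / p95)
    return np.clip(out, 0, 255).astype(np.uint8)


def rgb_to_od(img: np.ndarray) -> np.ndarray:
    return -np.log10((img.astype(np.float64) + 1.0) / 256.0)

def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(256.0 * np.power(10.0, -od) - 1.0, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Reinhard


def fit_reinhard(
    reference: np.ndarray,
    masked: bool = False,
    brightness_standardize: bool = True,
) -> ReinhardFit:
    """LAB channel statistics of a reference image.

    With ``masked`` the statistics cover non-white pixels only (white:
    mean-RGB brightness >= 230).  With brightness standardization the
    reference is first rescaled exactly as inputs will be at transform
    time, so normalizing the reference under its own fit is (near) the
    identity.
    """
    reference = _as_rgb(reference)
    if brightness_standardize:
        reference = _standardize_brightness(reference)
    lab = rgb2lab(reference)
    if masked:
        keep = _brightness(reference.astype(float)) < WHITE_BRIGHTNESS
        if not keep.any():
            raise StainFitError("masked Reinhard fit: no non-white pixels")
        pixels = lab[keep]
    else:
        pixels = lab.reshape(-1, 3)
    means = pixels.mean(axis=0)
    stds = pixels.std(axis=0)
    if np.any(stds < 1e-6):
        raise StainFitError("degenerate reference: zero variance in a LAB channel")
    return ReinhardFit(
        target_means=means,
        target_stds=stds,
        mask_white=masked,
        brightness_standardize=brightness_standardize,
    )


def reinhard_normalize(img: np.ndarray, fit: ReinhardFit) -> np.ndarray:
    """Map an image's LAB statistics onto a Reinhard fit's targets."""
    img = _as_rgb(img)
    work = _standardize_brightness(img) if fit.brightness_standardize else img
    lab = rgb2lab(work)
    if fit.mask_white:
        keep = _brightness(work.astype(float)) < WHITE_BRIGHTNESS
        if not keep.any():
            warnings.warn("no non-white pixels; returning input unchanged")
            return img.copy()
        pixels = lab[keep]
    else:
        keep = None
        pixels = lab.reshape(-1, 3)
    means = pixels.mean(axis=0)
    stds = pixels.std(axis=0)
    if np.any(stds < 1e-6):
        warnings.warn("zero channel variance; returning input unchanged")
        return img.copy()
    transformed = (lab - means) * (fit.target_stds / stds) + fit.target_means
    out = np.clip(lab2rgb(transformed) * 255.0, 0, 255).astype(np.uint8)
    if keep is not None:
        # masked variant: white pixels keep their original values
        result = img.copy()
        result[keep] = out[keep]
        return result
    return out


# ---------------------------------------------------------------------------
# Macenko


def fit_macenko(
    reference: np.ndarray, alpha: float = 1.0, beta: float = 0.15
) -> MacenkoFit:
    """Estimate H&E stain vectors and maximum concentrations.

    ``alpha`` is the angular-extreme percentile; ``beta`` the OD cutoff
    below which pixels count as transparent background and are dropped.
    The hematoxylin row is the vector with the larger blue-channel OD
    component.
    """
    reference = _as_rgb(reference)
    od = rgb_to_od(reference).reshape(-1, 3)
    tissue = od[np.all(od > beta, axis=1)]
    if tissue.shape[0] < 100:
        raise StainFitError(
            f"too few tissue pixels for Macenko fit: {tissue.shape[0]} < 100"
        )
    # top-2 principal plane of the OD cloud
    _, eigvecs = np.linalg.eigh(np.cov(tissue.T))
    plane = eigvecs[:, [2, 1]]  # columns: leading two eigenvectors
    plane[:, np.sum(plane, axis=0) < 0] *= -1.0
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    v1, v2 = np.abs(v1), np.abs(v2)  # absorbances are nonnegative
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    # hematoxylin absorbs more in the blue channel
    stains = np.vstack([v1, v2]) if v1[2] >= v2[2] else np.vstack([v2, v1])
    conc = _concentrations(od, stains)
    cmax = np.percentile(
        conc[:, np.all(od > beta, axis=1)], 99, axis=1
    )
    cmax = np.maximum(cmax, 1e-6)
    return MacenkoFit(
        stain_matrix=stains, max_concentrations=cmax, alpha=alpha, beta=beta
    )


def _concentrations(od_flat: np.ndarray, stains: np.ndarray) -> np.ndarray:
    """Per-pixel stain concentrations (2 x N), least squares clipped at 0."""
    sol, *_ = np.linalg.lstsq(stains.T, od_flat.T, rcond=None)
    return np.clip(sol, 0.0, None)


def macenko_normalize(
    img: np.ndarray, fit: MacenkoFit, context: np.ndarray | None = None
) -> np.ndarray:
    """Re-express an image in a reference stain basis.

    The image's own stain vectors are estimated, its concentrations
    rescaled so their maxima match the reference fit's, and the image is
    reconstructed through the reference stain matrix.  With ``context``,
    the source maxima come from the context image (contextual
    normalization); a context without enough tissue triggers a warning and
    self-context fallback.
    """
    img = _as_rgb(img)
    try:
        source = fit_macenko(img, alpha=fit.alpha, beta=fit.beta)
    except StainFitError as exc:
        warnings.warn(f"degenerate source stain fit ({exc}); returning input")
        return img.copy()
    source_max = source.max_concentrations
    if context is not None:
        try:
            source_max = fit_macenko(
                context, alpha=fit.alpha, beta=fit.beta
            ).max_concentrations
        except StainFitError:
            warnings.warn("context image has no usable tissue; using self-context")
    od = rgb_to_od(img).reshape(-1, 3)
    conc = _concentrations(od, source.stain_matrix)
    conc *= (fit.max_concentrations / source_max)[:, None]
    od_out = (fit.stain_matrix.T @ conc).T
    return od_to_rgb(od_out).reshape(img.shape)


# ---------------------------------------------------------------------------
# augmentation


def _perturbed_fit(fit, cfg: AugmentConfig, rng: np.random.Generator):
    if isinstance(fit, ReinhardFit):
        means = fit.target_means + rng.normal(0.0, cfg.sigma_matrix, 3)
        stds = fit.target_stds + rng.normal(0.0, cfg.sigma_matrix, 3)
        return ReinhardFit(
            target_means=means,
            target_stds=np.maximum(stds, 1e-3),
            mask_white=fit.mask_white,
            brightness_standardize=fit.brightness_standardize,
        )
    if isinstance(fit, MacenkoFit):
        delta_m = rng.normal(0.0, cfg.sigma_matrix, fit.stain_matrix.shape)
        delta_c = rng.normal(0.0, cfg.sigma_cmax, fit.max_concentrations.shape)
        matrix = fit.stain_matrix + delta_m
        if np.any(delta_m != 0.0):
            matrix = np.abs(matrix)
            matrix /= np.linalg.norm(matrix, axis=1, keepdims=True)
        cmax = np.maximum(fit.max_concentrations + delta_c, 1e-3)
        return MacenkoFit(
            stain_matrix=matrix, max_concentrations=cmax,
            alpha=fit.alpha, beta=fit.beta,
        )
    raise TypeError(f"unsupported fit type {type(fit).__name__}")


def stain_augment(
    img: np.ndarray,
    fit: ReinhardFit | MacenkoFit,
    cfg: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | None = None,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize toward a Gaussian-perturbed copy of the target fit."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    perturbed = _perturbed_fit(fit, cfg, rng)
    if isinstance(perturbed, ReinhardFit):
        return reinhard_normalize(img, perturbed)
    return macenko_normalize(img, perturbed, context=context)


# ---------------------------------------------------------------------------
# class API (fit/transform shaped)


class ReinhardNormalizer:
    """Reinhard color-transfer normalizer with masked and fast variants."""

    def __init__(self, masked: bool = False, brightness_standardize: bool = True):
        self.masked = masked
        self.brightness_standardize = brightness_standardize
        self.fit_: ReinhardFit | None = None

    def fit(self, reference: np.ndarray) -> "ReinhardNormalizer":
        self.fit_ = fit_reinhard(
            reference,
            masked=self.masked,
            brightness_standardize=self.brightness_standardize,
        )
        return self

    def transform(self, img: np.ndarray, context: np.ndarray | None = None) -> np.ndarray:
        self._check_fitted()
        return reinhard_normalize(img, self.fit_)

    def augment(
        self,
        img: np.ndarray,
        cfg: AugmentConfig = AugmentConfig(),
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        self._check_fitted()
        return stain_augment(img, self.fit_, cfg, rng=rng)

    def _check_fitted(self):
        if self.fit_ is None:
            raise StainFitError("normalizer is not fitted; call fit() first")


class MacenkoNormalizer:
    """Macenko stain-deconvolution normalizer, optionally contextual."""

    def __init__(self, alpha: float = 1.0, beta: float = 0.15):
        self.alpha = alpha
        self.beta = beta
        self.fit_: MacenkoFit | None = None

    def fit(self, reference: np.ndarray) -> "MacenkoNormalizer":
        self.fit_ = fit_macenko(reference, alpha=self.alpha, beta=self.beta)
        return self

    def transform(self, img: np.ndarray, context: np.ndarray | None = None) -> np.ndarray:
        self._check_fitted()
        return macenko_normalize(img, self.fit_, context=context)

    def augment(
        self,
        img: np.ndarray,
        cfg: AugmentConfig = AugmentConfig(),
        rng: np.random.Generator | None = None,
        context: np.ndarray | None = None,
    ) -> np.ndarray:
        self._check_fitted()
        return stain_augment(img, self.fit_, cfg, rng=rng, context=context)

    def _check_fitted(self):
        if self.fit_ is None:
            raise StainFitError("normalizer is not fitted; call fit() first")


# ---------------------------------------------------------------------------
# synthetic stain fields and default fits


def make_stain_field(
    shape: tuple[int, int] = (96, 96),
    stain_matrix: np.ndarray = SIM_STAIN_MATRIX,
    rng: np.random.Generator | None = None,
    max_conc: tuple[float, float] = (1.2, 0.9),
    grain: int = 8,
    sparsity: float = 0.25,
) -> np.ndarray:
    """Render a synthetic H&E-like field from known stain vectors.

    Concentration maps are blocky nonnegative random fields (coarse noise
    upsampled by ``grain``) combined through the stain matrix in OD space.
    A ``sparsity`` fraction of each stain's patches is zeroed, emulating
    regions where one stain is nearly absent (eosin-only stroma,
    hematoxylin-dense nuclei); without such near-pure pixels the stain
    vectors are not identifiable from the angular extremes.  Used for
    parameter-recovery tests and to generate the shipped default reference
    fits; it emulates staining chemistry, not tissue morphology.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = shape
    maps = []
    for cm in max_conc:
        coarse = rng.random((h // grain + 2, w // grain + 2))
        coarse *= rng.random(coarse.shape) > sparsity
        up = np.kron(coarse, np.ones((grain, grain)))[:h, :w]
        maps.append(cm * up)
    conc = np.stack([m.ravel() for m in maps])  # (2, N)
    od = (np.asarray(stain_matrix).T @ conc).T
    return od_to_rgb(od).reshape(h, w, 3)


def make_reference(
    shape: tuple[int, int] = (128, 128), seed: int = 2026
) -> np.ndarray:
    """The package's synthetic H&E reference image.

    A :func:`make_stain_field` render, brightness-standardized so its
    95th-percentile brightness sits at the standard target — references
    are stored in standardized form by convention, which makes standard
    Reinhard normalization a fixed point on its own reference.
    """
    field = make_stain_field(shape, rng=np.random.default_rng(seed))
    return _standardize_brightness(field)


def default_fit(method: str) -> ReinhardFit | MacenkoFit:
    """Load a bundled default reference fit ('reinhard' or 'macenko').

    These are synthetic references generated from :func:`make_stain_field`;
    they are reasonable H&E targets but are not claimed to match any other
    toolkit's bundled fits.
    """
    name = f"{method}_default.json"
    text = resources.files("histotile").joinpath("data", name).read_text()
    if method == "reinhard":
        return ReinhardFit.from_json(text)
    if method == "macenko":
        return MacenkoFit.from_json(text)
    raise ValueError(f"unknown stain method {method!r}")
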