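"""Whole-image QC, patch tiling, and the grayscale pipeline feeding SHRQA.

Three stages of pre-processing:

1. **Cohort-level outlier rejection** — whole images whose mean RGB intensity
   sits more than ``threshold_sd`` standard deviations from the cohort mean
   are discarded (slide-level staining/exposure artefacts).
2. **Tiling** — non-overlapping square patches from the top-left origin, with
   partial edge tiles dropped and tiles below a minimum tissue fraction
   rejected (background suppression).
3. **Per-patch grayscale pipeline** — luminance conversion, idempotent
   morphological noise reduction, percentile contrast stretch, min–max
   normalization to [0, 1].  Applying the pipeline to its own output is a
   no-op (to floating-point exactness), so patches may be preprocessed
   defensively without drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, OutlierMixin, TransformerMixin

from .patch import ImagePatch

__all__ = [
    "OutlierReport",
    "TileResult",
    "mean_rgb_intensity",
    "remove_intensity_outliers",
    "tissue_fraction",
    "tile_image",
    "preprocess_for_shrqa",
    "to_grayscale",
    "IntensityOutlierFilter",
    "PatchPreprocessor",
]

# Rec. 709 luminance weights for RGB -> relative luminance
_LUMA = np.array([0.2126, 0.7152, 0.0722])

#: relative luminance above which a pixel counts as slide background
DEFAULT_BACKGROUND_LUMINANCE = 0.86


@dataclass
class OutlierReport:
    """Outcome of cohort-level RGB-mean outlier screening."""

    cohort_mean: float
    cohort_sd: float
    threshold_sd: float
    retained: list[str]
    discarded: list[tuple[str, float]]  # (source_id, rgb mean)


@dataclass
class TileResult:
    """Non-overlapping tiling of one image with tissue-content filtering."""

    tiles: list[ImagePatch]
    grid_origin: list[tuple[int, int]]  # 0-based (row, col) per retained tile
    rejected_count: int
    tissue_threshold: float


def mean_rgb_intensity(image: ImagePatch) -> float:
    """Arithmetic mean over all pixels and all three channels, in [0, 255]."""
    if image.mode != "RGB":
        raise ValueError("mean_rgb_intensity requires an RGB patch")
    return float(image.pixels.astype(np.float64).mean())


def remove_intensity_outliers(
    images: list[ImagePatch], threshold_sd: float = 2.0
) -> OutlierReport:
    """Flag images whose RGB mean is > ``threshold_sd`` SDs from the cohort mean.

    Cohort mean and SD are computed in a single pass over *all* inputs
    (including eventual outliers); there is no iterative re-screening.
    """
    if len(images) < 3:
        raise ValueError("need at least 3 images to estimate a cohort SD")
    means = np.array([mean_rgb_intensity(im) for im in images])
    cohort_mean = float(means.mean())
    cohort_sd = float(means.std(ddof=1))
    retained, discarded = [], []
    if cohort_sd == 0.0:
        warnings.warn("cohort SD is zero; all images retained", stacklevel=2)
        retained = [im.source_id for im in images]
    else:
        for im, m in zip(images, means):
            if abs(m - cohort_mean) > threshold_sd * cohort_sd:
                discarded.append((im.source_id, float(m)))
            else:
                retained.append(im.source_id)
    return OutlierReport(cohort_mean, cohort_sd, float(threshold_sd), retained, discarded)


def _relative_luminance(patch: ImagePatch) -> np.ndarray:
    if patch.mode == "RGB":
        return patch.pixels.astype(np.float64) @ _LUMA / 255.0
    return patch.pixels


def tissue_fraction(
    tile: ImagePatch, background_luminance: float = DEFAULT_BACKGROUND_LUMINANCE
) -> float:
    """Fraction of pixels darker than the slide-background luminance.

    Sets ``tile.tissue_fraction`` as a side effect and returns it.
    """
    lum = _relative_luminance(tile)
    frac = float(np.mean(lum < background_luminance))
    tile.tissue_fraction = frac
    return frac


def tile_image(
    image: ImagePatch,
    patch_size: int,
    tissue_threshold: float,
    background_luminance: float = DEFAULT_BACKGROUND_LUMINANCE,
) -> TileResult:
    """Cut a non-overlapping grid of ``patch_size`` squares, keeping tiles with
    ``tissue_fraction >= tissue_threshold``.

    Grid is 0-based row-major from the top-left corner, half-open pixel
    ranges; partial tiles at the right/bottom edges are dropped.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    if patch_size not in (64, 128, 256):
        warnings.warn(
            f"patch_size {patch_size} is outside the standard set {{64, 128, 256}}",
            stacklevel=2,
        )
    if not 0.0 <= tissue_threshold <= 1.0:
        raise ValueError("tissue_threshold must lie in [0, 1]")
    n_rows = image.height_px // patch_size
    n_cols = image.width_px // patch_size
    if n_rows == 0 or n_cols == 0:
        warnings.warn("image smaller than patch_size; no tiles produced", stacklevel=2)
        return TileResult([], [], 0, float(tissue_threshold))
    tiles, origins, rejected = [], [], 0
    for r in range(n_rows):
        for c in range(n_cols):
            sub = image.pixels[
                r * patch_size : (r + 1) * patch_size,
                c * patch_size : (c + 1) * patch_size,
            ]
            tile = ImagePatch(
                pixels=sub.copy(), mode=image.mode, source_id=f"{image.source_id}_r{r}c{c}"
            )
            frac = tissue_fraction(tile, background_luminance)
            if frac >= tissue_threshold:
                tiles.append(tile)
                origins.append((r, c))
            else:
                rejected += 1
    return TileResult(tiles, origins, rejected, float(tissue_threshold))


def to_grayscale(patch: ImagePatch) -> np.ndarray:
    """Relative-luminance grayscale in [0, 1] (identity for GRAY input)."""
    return _relative_luminance(patch).astype(np.float64, copy=True)


# 4-connected (cross-shaped) structuring element: the minimal symmetric
# neighbourhood; removes speckle with less edge bias than the full square
_CROSS3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _open_close(arr: np.ndarray) -> np.ndarray:
    """Grey opening followed by closing with the 3x3 cross window.

    Removes bright and dark speckle up to the window scale.  The composition
    of an opening and a closing is idempotent, and flat (rank-based)
    morphology commutes with monotone point transforms — both properties the
    pipeline's no-drift guarantee relies on.
    """
    return ndimage.grey_closing(
        ndimage.grey_opening(arr, footprint=_CROSS3), footprint=_CROSS3
    )


#: half-width of the contrast window in IQR units (Tukey-fence style)
STRETCH_IQR_HALFWIDTH = 1.5


def preprocess_for_shrqa(
    patch: ImagePatch, iqr_halfwidth: float = STRETCH_IQR_HALFWIDTH
) -> ImagePatch:
    """Grayscale → morphological noise reduction → robust contrast stretch.

    The stretch maps the window ``median ± iqr_halfwidth·IQR`` linearly onto
    [0, 1] and clips outside it.  Anchoring on quartile order statistics
    (``method="lower"``) rather than extreme percentiles makes the mapping
    insensitive to the image's noise floor — additive pixel noise inflates
    the 1st/99th percentiles far more than the quartiles — so recurrence
    features do not drift when only the noise level changes.  Because the
    quartiles are order statistics untouched by tail clipping and the
    morphological smoother is idempotent and commutes with monotone maps,
    the whole pipeline is exactly idempotent on its own output.

    A constant input degenerates to an all-zero patch (with a warning),
    since there is no contrast to stretch.
    """
    gray = to_grayscale(patch)
    smoothed = _open_close(gray)
    med = np.percentile(smoothed, 50.0, method="lower")
    q1 = np.percentile(smoothed, 25.0, method="lower")
    q3 = np.percentile(smoothed, 75.0, method="lower")
    iqr = q3 - q1
    if iqr <= 0:
        warnings.warn(
            "degenerate contrast stretch (constant patch); returning zeros",
            stacklevel=2,
        )
        out = np.zeros_like(smoothed)
    else:
        lo = med - iqr_halfwidth * iqr
        span = 2.0 * iqr_halfwidth * iqr
        out = np.clip((smoothed - lo) / span, 0.0, 1.0)
    return ImagePatch(pixels=out, mode="GRAY", source_id=patch.source_id)


class IntensityOutlierFilter(BaseEstimator, OutlierMixin):
    """Cohort RGB-mean outlier screen as a scikit-learn-style detector.

    ``fit`` learns the cohort mean/SD from per-image RGB means; ``predict``
    returns +1 (inlier) / -1 (outlier) per image, matching the sklearn
    outlier-detector convention.

    Parameters
    ----------
    threshold_sd : float, default 2.0
        Number of cohort standard deviations beyond which an image is flagged.
    """

    def __init__(self, threshold_sd: float = 2.0):
        self.threshold_sd = threshold_sd

    @staticmethod
    def _means(X) -> np.ndarray:
        return np.array([mean_rgb_intensity(im) for im in X])

    def fit(self, X, y=None):
        if len(X) < 3:
            raise ValueError("need at least 3 images to estimate a cohort SD")
        means = self._means(X)
        self.cohort_mean_ = float(means.mean())
        self.cohort_sd_ = float(means.std(ddof=1))
        self.n_samples_fit_ = len(X)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margin: positive inside the band, negative outside."""
        means = self._means(X)
        if self.cohort_sd_ == 0.0:
            return np.full(len(X), np.inf)
        return self.threshold_sd - np.abs(means - self.cohort_mean_) / self.cohort_sd_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


class PatchPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying :func:`preprocess_for_shrqa` per patch."""

    def __init__(self, iqr_halfwidth: float = STRETCH_IQR_HALFWIDTH):
        self.iqr_halfwidth = iqr_halfwidth

    def fit(self, X, y=None):
        self.n_features_in_ = 0  # image input; no tabular features
        return self

    def transform(self, X) -> list[ImagePatch]:
        return [preprocess_for_shrqa(p, iqr_halfwidth=self.iqr_halfwidth) for p in X]
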