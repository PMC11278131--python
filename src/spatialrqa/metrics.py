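"""Generative-model evaluation metrics with pluggable embeddings.

FID, Inception Score and Relative Inception Score operate on *embeddings* and
*class-probability tables* supplied by the caller — any image embedder can
stand behind them.  A deterministic mock embedder (random projection of
downsampled pixels) ships for tests and demos, so every metric path runs end
to end without a trained network.  The whole-image intensity PCA keeps the
positional layout of each image (channel-averaged, optionally downsampled)
and decomposes the cohort with the standardized PCA from
:mod:`spatialrqa.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patch import ImagePatch
from .stats import PCASummary, pca_summary

__all__ = [
    "EmbeddingGaussian",
    "MetricResult",
    "fit_embedding_gaussian",
    "frechet_distance",
    "inception_score",
    "relative_inception_score",
    "intensity_pca",
    "mock_embedder",
    "mock_classifier_probs",
]


@dataclass
class EmbeddingGaussian:
    """Moment-matched Gaussian summary of an embedding cloud."""

    mean: np.ndarray
    covariance: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=np.float64))
        d = self.mean.size
        if self.covariance.shape != (d, d):
            raise ValueError("covariance must be d x d matching the mean")
        if np.abs(self.covariance - self.covariance.T).max() > 1e-10:
            raise ValueError("covariance must be symmetric (within 1e-10)")

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class MetricResult:
    """A single metric value plus a summary of its inputs."""

    metric: str  # "FID" | "IS" | "RIS"
    value: float
    inputs_summary: dict
    notes: str = ""
    sd: float | None = None


def fit_embedding_gaussian(embeddings) -> EmbeddingGaussian:
    """Sample mean and unbiased sample covariance of an (n, d) embedding table."""
    X = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 embedding rows")
    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    cov = (cov + cov.T) / 2.0
    return EmbeddingGaussian(mean=mean, covariance=cov, n_samples=X.shape[0])


def _psd_eigvals(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    vals = np.linalg.eigvalsh((M + M.T) / 2.0)
    if vals.min() < -tol * max(1.0, abs(vals.max())):
        raise ValueError(
            f"matrix is not positive semi-definite (min eigenvalue {vals.min():.3g})"
        )
    return np.clip(vals, 0.0, None)


def frechet_distance(g1: EmbeddingGaussian, g2: EmbeddingGaussian) -> MetricResult:
    """Fréchet (Wasserstein-2) distance between two embedding Gaussians.

    ``FID = ||mu1-mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``.  The cross term
    is computed from the symmetric product ``S1^{1/2} S2 S1^{1/2}`` by
    eigendecomposition (numerically stabler than a direct product root);
    eigenvalues above -1e-8 are clipped to zero.  Lower is more similar.
    """
    if g1.dim != g2.dim:
        raise ValueError(f"dimension mismatch: {g1.dim} vs {g2.dim}")
    vals1 = _psd_eigvals(g1.covariance)
    # S1^{1/2} via its own eigendecomposition
    w, V = np.linalg.eigh((g1.covariance + g1.covariance.T) / 2.0)
    w = np.clip(w, 0.0, None)
    root1 = (V * np.sqrt(w)) @ V.T
    inner = root1 @ g2.covariance @ root1
    cross = np.sqrt(_psd_eigvals(inner)).sum()
    _psd_eigvals(g2.covariance)  # validate the second input as well
    delta = g1.mean - g2.mean
    value = float(delta @ delta + np.trace(g1.covariance) + np.trace(g2.covariance) - 2.0 * cross)
    value = max(value, 0.0)  # guard tiny negative round-off
    return MetricResult(
        metric="FID",
        value=value,
        inputs_summary={"d": g1.dim, "n1": g1.n_samples, "n2": g2.n_samples},
    )


def inception_score(probs, n_splits: int = 1) -> MetricResult:
    """exp(mean KL(row || marginal)) over a class-probability table.

    With ``n_splits > 1`` the table is cut into equal consecutive splits and
    the mean ± SD of the per-split scores is reported (the usual convention).
    Bounded by 1 <= IS <= K for K classes.
    """
    P = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if P.shape[1] < 2:
        raise ValueError("need at least 2 classes")
    if (P < 0).any():
        raise ValueError("probabilities must be non-negative")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("each row must sum to 1 (within 1e-6)")
    if not 1 <= n_splits <= P.shape[0]:
        raise ValueError("n_splits must lie in [1, n_rows]")

    def _score(block: np.ndarray) -> float:
        marginal = block.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.where(block > 0, np.log(block / marginal), 0.0)
        kl = (block * logratio).sum(axis=1)
        return float(np.exp(kl.mean()))

    if n_splits == 1:
        value, sd = _score(P), None
    else:
        scores = [_score(block) for block in np.array_split(P, n_splits)]
        value, sd = float(np.mean(scores)), float(np.std(scores, ddof=0))
    return MetricResult(
        metric="IS",
        value=value,
        sd=sd,
        inputs_summary={"n": P.shape[0], "K": P.shape[1], "n_splits": n_splits},
    )


def relative_inception_score(
    is_synthetic: MetricResult, is_real: MetricResult
) -> MetricResult:
    """Ratio IS(synthetic) / IS(real) under the same classifier.

    When split SDs are present on both inputs, the SD of the ratio is
    propagated with the first-order rule
    ``sd = ris * sqrt((sd_s/IS_s)^2 + (sd_r/IS_r)^2)``.
    """
    for mr in (is_synthetic, is_real):
        if mr.metric != "IS":
            raise ValueError("inputs must be IS results")
        if mr.value < 1.0 - 1e-9:
            raise ValueError("inception scores must be >= 1")
    ris = is_synthetic.value / is_real.value
    sd = None
    if is_synthetic.sd is not None and is_real.sd is not None:
        sd = ris * np.sqrt(
            (is_synthetic.sd / is_synthetic.value) ** 2
            + (is_real.sd / is_real.value) ** 2
        )
        sd = float(sd)
    return MetricResult(
        metric="RIS",
        value=float(ris),
        sd=sd,
        inputs_summary={
            "is_synthetic": is_synthetic.value,
            "is_real": is_real.value,
        },
    )


# ---------------------------------------------------------------------------
# whole-image intensity PCA


def _intensity_grid(patch: ImagePatch, grid: int | None) -> np.ndarray:
    """Channel-averaged intensity with positions retained, optionally
    block-averaged down to ``grid`` x ``grid``."""
    if patch.mode == "RGB":
        arr = patch.pixels.astype(np.float64).mean(axis=2) / 255.0
    else:
        arr = patch.pixels.astype(np.float64)
    if grid is not None and grid < min(arr.shape):
        h, w = arr.shape
        bh, bw = h // grid, w // grid
        arr = arr[: bh * grid, : bw * grid].reshape(grid, bh, grid, bw).mean(axis=(1, 3))
    return arr.ravel()


def intensity_pca(
    images: list[ImagePatch], labels, n_components: int = 5, grid: int | None = 16
) -> tuple[PCASummary, pd.DataFrame]:
    """PCA of whole-image intensity grids, plus per-group scores for plotting.

    Each image contributes one row: the channel-averaged intensity field with
    its positional layout retained (downsampled to ``grid`` x ``grid`` by block
    means when smaller than the image).  Returns the PCA summary and a tidy
    score table (group, pc1..pcK).
    """
    if not images:
        raise ValueError("no images given")
    shapes = {im.pixels.shape[:2] for im in images}
    if len(shapes) != 1:
        raise ValueError(f"images must share dimensions, got {sorted(shapes)}")
    X = np.vstack([_intensity_grid(im, grid) for im in images])
    summary = pca_summary(X, n_components=n_components)
    scores = pd.DataFrame(
        summary.scores, columns=[f"pc{k + 1}" for k in range(summary.n_components)]
    )
    scores.insert(0, "group", list(labels))
    return summary, scores


# ---------------------------------------------------------------------------
# mock embedder / classifier (deterministic stand-ins for tests and demos)


def _downsampled_gray(images: list[ImagePatch], grid: int = 16) -> np.ndarray:
    return np.vstack([_intensity_grid(im, grid) for im in images])


def mock_embedder(
    images: list[ImagePatch], dim: int = 64, seed: int = 0, grid: int = 16
) -> np.ndarray:
    """Synthetic embedder: fixed-seed Gaussian random projection of the
    downsampled intensity grid.  Deterministic; exercises the metric paths
    without any trained network."""
    X = _downsampled_gray(images, grid)
    rng = np.random.Generator(np.random.Philox(key=seed))
    W = rng.normal(size=(X.shape[1], dim)) / np.sqrt(X.shape[1])
    return X @ W


def mock_classifier_probs(
    images: list[ImagePatch], n_classes: int = 8, seed: int = 0, grid: int = 16
) -> np.ndarray:
    """Synthetic classifier: softmax over a fixed-seed random projection of
    the downsampled intensity grid.  Rows sum to 1."""
    X = _downsampled_gray(images, grid)
    rng = np.random.Generator(np.random.Philox(key=seed))
    W = rng.normal(size=(X.shape[1], n_classes)) * 3.0
    logits = X @ W
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    return expl / expl.sum(axis=1, keepdims=True)
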