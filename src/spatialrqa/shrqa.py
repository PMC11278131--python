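"""Spatial heterogeneous recurrence quantification (SHRQA) of image patches.

The extractor turns a square grayscale patch into 112 recurrence features via
six steps:

1. **Haar 2D-DWT** — the level-1 approximation (LL) subband, i.e. dyadic
   block means, suppressing pixel noise while keeping layout;
2. **Hilbert flattening** — the subband is read out along a Hilbert
   space-filling curve, so pixels that are close in the plane stay close in
   the resulting 1-D attribute vector;
3. **delay embedding** — consecutive vector entries form 2-D state-space
   points (dimension 2, delay 1);
4. **quadtree symbolization** — the unit square is cut into 4^depth dyadic
   cells (16 at the default depth 2) and each point becomes its cell index;
5. **IFS projection** — a chaos-game orbit of the symbol sequence, giving the
   address-prefix fractal view of the trajectory (diagnostic, not used for
   features);
6. **heterogeneous recurrence quantification** — seven recurrence statistics
   per cell (occupancy, pairwise recurrence rate, run-length mean and
   entropy, recurrence-time mean and entropy, self-transition probability),
   16 x 7 = 112 features.

Everything here is deterministic; the same patch always yields the same
feature vector.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .patch import ImagePatch
from .preprocess import preprocess_for_shrqa

__all__ = [
    "ShrqaConfig",
    "AttributeVector",
    "StateTrajectory",
    "CellSequence",
    "IFSPlot",
    "RecurrenceFeatureVector",
    "MEASURE_NAMES",
    "dwt2_haar",
    "hilbert_flatten",
    "hilbert_order",
    "embed_trajectory",
    "quadtree_partition",
    "ifs_project",
    "quantify_recurrence",
    "shrqa_features",
    "feature_names",
    "ShrqaExtractor",
]

#: the seven per-cell heterogeneous recurrence measures, in output order
MEASURE_NAMES = (
    "occupancy",
    "recurrence_rate",
    "mean_run_length",
    "run_length_entropy",
    "mean_recurrence_time",
    "recurrence_time_entropy",
    "self_transition",
)


@dataclass(frozen=True)
class ShrqaConfig:
    """Extractor parameters.

    Defaults give 4^2 = 16 state-space cells x 7 measures = 112 features.

    Parameters
    ----------
    dwt_levels
        Haar approximation levels before flattening (0 = raw patch).
    embed_dim, embed_delay
        Delay-embedding dimension and lag for the state-space trajectory.
    quadtree_depth
        Dyadic partition depth of the unit square; 4^depth cells.
    patch_size_px
        Expected input side; ``None`` disables the check.
    run_min
        Minimum maximal-run length entering the run-based statistics
        (analogous to the minimum line length in recurrence quantification).
    """

    dwt_levels: int = 1
    embed_dim: int = 2
    embed_delay: int = 1
    quadtree_depth: int = 2
    patch_size_px: int | None = 256
    run_min: int = 2

    def __post_init__(self) -> None:
        if self.dwt_levels < 0:
            raise ValueError("dwt_levels must be >= 0")
        if self.embed_dim != 2:
            raise ValueError("only embed_dim=2 is supported (planar quadtree symbolization)")
        if self.embed_delay < 1:
            raise ValueError("embed_delay must be >= 1")
        if self.quadtree_depth < 1:
            raise ValueError("quadtree_depth must be >= 1")
        if self.run_min < 1:
            raise ValueError("run_min must be >= 1")

    @property
    def n_cells(self) -> int:
        return 4**self.quadtree_depth

    @property
    def n_features(self) -> int:
        return self.n_cells * len(MEASURE_NAMES)


@dataclass
class AttributeVector:
    """1-D readout of a square patch along the Hilbert curve."""

    values: np.ndarray
    curve_order: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StateTrajectory:
    """Delay-embedded state-space trajectory; points in [0, 1]^dim."""

    points: np.ndarray  # (n_points, dim)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class CellSequence:
    """Quadtree-symbolized trajectory: one cell index per state-space point."""

    symbols: np.ndarray
    depth: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 1:
            raise ValueError("symbols must be a 1-D sequence")
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.n_cells
        ):
            raise ValueError(f"symbols must lie in [0, {self.n_cells})")

    @property
    def n_cells(self) -> int:
        return 4**self.depth

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass
class IFSPlot:
    """Chaos-game orbit of a symbol sequence (one plotted point per symbol)."""

    points: np.ndarray  # (n, 2) in [0, 1]^2
    addresses: np.ndarray  # parallel symbols


@dataclass
class RecurrenceFeatureVector:
    """112 SHRQA features, cell-major (cell 0..15) x measure-minor (7)."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names must align")

    def __len__(self) -> int:
        return len(self.values)


def feature_names(depth: int = 2) -> list[str]:
    return [f"cell{c}_{m}" for c in range(4**depth) for m in MEASURE_NAMES]


# ---------------------------------------------------------------------------
# step 1: Haar wavelet approximation


def _require_pow2_square(arr: np.ndarray) -> int:
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"patch must be square, got shape {arr.shape}")
    side = arr.shape[0]
    if side & (side - 1):
        raise ValueError(
            f"patch side must be a power of 2, got {side}; crop or resize first"
        )
    return side


def dwt2_haar(patch: ImagePatch, levels: int) -> ImagePatch:
    """Level-``levels`` Haar approximation (LL) subband on the [0, 1] scale.

    Dividing the LL coefficients by 2^levels makes them exact dyadic block
    means, so the output stays in [0, 1]; ``levels=0`` is the identity.
    """
    if patch.mode != "GRAY":
        raise ValueError("dwt2_haar expects a GRAY patch")
    if levels < 0:
        raise ValueError("levels must be >= 0")
    side = _require_pow2_square(patch.pixels)
    if levels == 0:
        return patch
    if side >> levels < 1:
        raise ValueError(f"side {side} too small for {levels} DWT levels")
    coeffs = pywt.wavedec2(patch.pixels, "haar", level=levels)
    ll = np.asarray(coeffs[0]) / (2.0**levels)
    return ImagePatch(
        pixels=np.clip(ll, 0.0, 1.0), mode="GRAY", source_id=patch.source_id
    )


# ---------------------------------------------------------------------------
# step 2: Hilbert space-filling curve


@functools.lru_cache(maxsize=16)
def hilbert_order(order: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) indices of the 2^order x 2^order Hilbert traversal.

    Consecutive positions are always 4-adjacent and every pixel is visited
    exactly once.  Orientation convention: with rows counted downward from the
    top-left (image convention), the order-1 curve visits bottom-left,
    top-left, top-right, bottom-right.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = 1 << order
    d = np.arange(n * n, dtype=np.int64)
    t = d.copy()
    x = np.zeros_like(d)
    y = np.zeros_like(d)
    s = 1
    while s < n:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        flip = (ry == 0) & (rx == 1)
        x[flip] = s - 1 - x[flip]
        y[flip] = s - 1 - y[flip]
        swap = ry == 0
        x[swap], y[swap] = y[swap], x[swap].copy()
        x = x + s * rx
        y = y + s * ry
        t //= 4
        s *= 2
    # math (x right, y up) -> image (row down, col right)
    return (n - 1 - y, x)


def hilbert_flatten(patch: ImagePatch) -> AttributeVector:
    """Read a square power-of-2 GRAY patch along the Hilbert curve."""
    if patch.mode != "GRAY":
        raise ValueError("hilbert_flatten expects a GRAY patch")
    side = _require_pow2_square(patch.pixels)
    order = int(side).bit_length() - 1
    rows, cols = hilbert_order(order)
    return AttributeVector(values=patch.pixels[rows, cols], curve_order=order)


# ---------------------------------------------------------------------------
# step 3: delay embedding


def embed_trajectory(vec: AttributeVector, dim: int = 2, delay: int = 1) -> StateTrajectory:
    """Delay embedding: point t = (v_t, v_{t+delay}, ..., v_{t+(dim-1)delay})."""
    if dim < 1 or delay < 1:
        raise ValueError("dim and delay must be >= 1")
    v = np.asarray(vec.values, dtype=np.float64)
    n_points = len(v) - (dim - 1) * delay
    if n_points < 1:
        raise ValueError(
            f"attribute vector of length {len(v)} too short for dim={dim}, delay={delay}"
        )
    cols = [v[i * delay : i * delay + n_points] for i in range(dim)]
    return StateTrajectory(points=np.column_stack(cols))


# ---------------------------------------------------------------------------
# step 4: quadtree symbolization


def quadtree_partition(traj: StateTrajectory, depth: int) -> CellSequence:
    """Assign each 2-D point its dyadic-cell index at the given depth.

    Cells are half-open boxes partitioning [0, 1]^2; the boundary value 1.0
    falls in the last cell of its axis.  The symbol interleaves the quadrant
    bits level by level (first-coordinate bit, then second-coordinate bit),
    so e.g. at depth 1 the point (0.1, 0.1) is symbol 0.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pts = np.asarray(traj.points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("quadtree_partition requires a 2-D trajectory")
    if pts.size and (pts.min() < 0.0 or pts.max() > 1.0):
        raise ValueError("trajectory points must lie in [0, 1]^2")
    m = 1 << depth
    ia = np.minimum((pts[:, 0] * m).astype(np.int64), m - 1)
    ib = np.minimum((pts[:, 1] * m).astype(np.int64), m - 1)
    symbols = np.zeros(len(pts), dtype=np.int64)
    for level in range(depth):
        shift = depth - 1 - level
        symbols = symbols * 4 + 2 * ((ia >> shift) & 1) + ((ib >> shift) & 1)
    return CellSequence(symbols=symbols, depth=depth)


# ---------------------------------------------------------------------------
# step 5: IFS (chaos-game) projection

# quadrant digit d = 2*b1 + b2 maps to corner (b1, b2) of the unit square
_IFS_CORNERS = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])


def ifs_project(cells: CellSequence) -> IFSPlot:
    """Chaos-game orbit from (0.5, 0.5): each symbol's quadrant digits (most
    significant first) each apply z <- z/2 + corner/2; one point is recorded
    per symbol, after all of its digits."""
    if len(cells) == 0:
        raise ValueError("empty symbol sequence")
    z = np.array([0.5, 0.5])
    pts = np.empty((len(cells), 2))
    for k, sym in enumerate(cells.symbols):
        for shift in range(cells.depth - 1, -1, -1):
            digit = (int(sym) >> (2 * shift)) & 3
            z = z / 2.0 + _IFS_CORNERS[digit] / 2.0
        pts[k] = z
    return IFSPlot(points=pts, addresses=cells.symbols.copy())


# ---------------------------------------------------------------------------
# step 6: heterogeneous recurrence quantification


def _entropy(values: np.ndarray) -> float:
    """Shannon entropy (nats) of the empirical distribution of ``values``."""
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def quantify_recurrence(cells: CellSequence, run_min: int = 2) -> RecurrenceFeatureVector:
    """Seven recurrence statistics per quadtree cell.

    Per cell c (k visits in a length-T sequence):

    1. occupancy ``k/T``;
    2. pairwise recurrence rate ``C(k,2)/C(T,2)`` normalized by occupancy
       (0 when k < 2);
    3. mean length of maximal runs in c with length >= ``run_min``;
    4. Shannon entropy of that run-length distribution;
    5. mean recurrence time (gap between successive visits);
    6. Shannon entropy of the recurrence-time distribution;
    7. self-transition probability ``P(s_{t+1}=c | s_t=c)``.

    Unvisited cells contribute a zero block; occupancies sum to 1.
    """
    s = cells.symbols
    T = len(s)
    if T < 2:
        raise ValueError("need a symbol sequence of length >= 2")
    if run_min < 1:
        raise ValueError("run_min must be >= 1")
    n_cells = cells.n_cells
    feats = np.zeros((n_cells, len(MEASURE_NAMES)))

    # run-length encoding of the whole sequence, once
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate(([0], change + 1))
    run_lengths = np.diff(np.concatenate((starts, [T])))
    run_cells = s[starts]

    total_pairs = T * (T - 1) / 2.0
    prev_, next_ = s[:-1], s[1:]

    for c in range(n_cells):
        visits = np.flatnonzero(s == c)
        k = visits.size
        if k == 0:
            continue
        occ = k / T
        feats[c, 0] = occ
        if k >= 2:
            feats[c, 1] = (k * (k - 1) / 2.0 / total_pairs) / occ
            gaps = np.diff(visits)
            feats[c, 4] = gaps.mean()
            feats[c, 5] = _entropy(gaps)
        runs = run_lengths[run_cells == c]
        runs = runs[runs >= run_min]
        if runs.size:
            feats[c, 2] = runs.mean()
            feats[c, 3] = _entropy(runs)
        from_c = prev_ == c
        n_from = int(from_c.sum())
        if n_from:
            feats[c, 6] = int((from_c & (next_ == c)).sum()) / n_from

    return RecurrenceFeatureVector(
        values=feats.ravel(), feature_names=feature_names(cells.depth)
    )


# ---------------------------------------------------------------------------
# full pipeline


def shrqa_features(
    patch: ImagePatch, config: ShrqaConfig | None = None
) -> RecurrenceFeatureVector:
    """Run the six-step pipeline on one patch (RGB or GRAY). Deterministic."""
    cfg = config or ShrqaConfig()
    if cfg.patch_size_px is not None and (
        patch.height_px != cfg.patch_size_px or patch.width_px != cfg.patch_size_px
    ):
        raise ValueError(
            f"patch is {patch.height_px}x{patch.width_px}, "
            f"config expects {cfg.patch_size_px}"
        )
    gray = preprocess_for_shrqa(patch)
    ll = dwt2_haar(gray, cfg.dwt_levels)
    vec = hilbert_flatten(ll)
    traj = embed_trajectory(vec, dim=cfg.embed_dim, delay=cfg.embed_delay)
    cells = quadtree_partition(traj, depth=cfg.quadtree_depth)
    return quantify_recurrence(cells, run_min=cfg.run_min)


class ShrqaExtractor(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: iterable of patches -> (n, 112) feature matrix.

    Parameters mirror :class:`ShrqaConfig`; ``patch_size_px=None`` (default)
    accepts any square power-of-2 side.  Stateless — ``fit`` only validates
    the configuration and records the output feature names.

    Examples
    --------
    >>> from spatialrqa.texture import default_templates, generate_cohort
    >>> cohort = generate_cohort(default_templates(64), n_per_class=2, seed=0)
    >>> X = ShrqaExtractor().fit_transform(cohort.patches)
    >>> X.shape
    (4, 112)
    """

    def __init__(
        self,
        dwt_levels: int = 1,
        embed_dim: int = 2,
        embed_delay: int = 1,
        quadtree_depth: int = 2,
        run_min: int = 2,
        patch_size_px: int | None = None,
    ):
        self.dwt_levels = dwt_levels
        self.embed_dim = embed_dim
        self.embed_delay = embed_delay
        self.quadtree_depth = quadtree_depth
        self.run_min = run_min
        self.patch_size_px = patch_size_px

    def _config(self) -> ShrqaConfig:
        return ShrqaConfig(
            dwt_levels=self.dwt_levels,
            embed_dim=self.embed_dim,
            embed_delay=self.embed_delay,
            quadtree_depth=self.quadtree_depth,
            patch_size_px=self.patch_size_px,
            run_min=self.run_min,
        )

    def fit(self, X=None, y=None):
        cfg = self._config()
        self.feature_names_out_ = np.asarray(feature_names(cfg.quadtree_depth), dtype=object)
        self.n_features_out_ = cfg.n_features
        return self

    @staticmethod
    def _coerce(item) -> ImagePatch:
        if isinstance(item, ImagePatch):
            return item
        arr = np.asarray(item)
        if arr.ndim == 3:
            return ImagePatch(pixels=arr, mode="RGB")
        return ImagePatch(pixels=arr, mode="GRAY")

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        cfg = self._config()
        rows = [shrqa_features(self._coerce(p), cfg).values for p in X]
        return np.vstack(rows) if rows else np.empty((0, cfg.n_features))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        return self.feature_names_out_
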