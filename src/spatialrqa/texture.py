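"""Synthetic texture cohorts with controllable microstructural regularity.

Histologically "normal" glandular tissue shows a near-uniform spatial
arrangement of repeating elements, while adenocarcinoma disrupts that
regularity.  The generator emulates this single axis of contrast: dark
Gaussian-profile discs ("glands") composited multiplicatively on a pink-noise
background, placed on a hexagonal lattice whose positional jitter and
element-size dispersion are the regularity knob.  A low-jitter REGULAR class
stands in for normal tissue, a high-jitter IRREGULAR class for cancer, and a
small stochastic perturbation of an existing patch stands in for generative
model output (same structure, slight deviation).

Every output is a pure function of its spec, including the seed: identical
specs yield bit-identical pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .patch import ImagePatch, save_patch

__all__ = [
    "PatternClass",
    "TextureSpec",
    "LabeledPatchSet",
    "generate_texture_patch",
    "perturb_patch",
    "generate_cohort",
    "perturb_cohort",
    "generate_outlier_image",
    "default_templates",
    "write_patch_set",
]


class PatternClass(Enum):
    """Microstructural regularity class of a generated patch."""

    REGULAR = "REGULAR"
    IRREGULAR = "IRREGULAR"
    NOISE = "NOISE"


# eosin-like tint endpoints (background near-white pink, stain dark purple)
_BG_COLOR = np.array([0.93, 0.86, 0.92])
_STAIN_COLOR = np.array([0.38, 0.22, 0.52])


@dataclass(frozen=True)
class TextureSpec:
    """Full description of one generated patch (a pure function of this spec).

    Parameters
    ----------
    pattern_class
        REGULAR (jittered lattice), IRREGULAR (heavy jitter plus element-size
        dispersion) or NOISE (spatially uncorrelated pixels).
    size_px
        Square side in pixels, at least 32.
    element_scale_px
        Characteristic gland/blob diameter in pixels.
    jitter
        Placement irregularity in [0, 1]; fraction of the lattice spacing used
        as the SD of positional displacement (and it drives size dispersion).
    noise_sd
        Additive pixel noise SD on the [0, 1] intensity scale.
    seed
        Integer seed; part of the patch identity.
    """

    pattern_class: PatternClass = PatternClass.REGULAR
    size_px: int = 256
    element_scale_px: float = 14.0
    jitter: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.pattern_class, PatternClass):
            raise ValueError(f"pattern_class must be a PatternClass, got {self.pattern_class!r}")
        if int(self.size_px) < 32:
            raise ValueError(f"size_px must be >= 32, got {self.size_px}")
        if self.element_scale_px <= 0:
            raise ValueError("element_scale_px must be positive")
        if not 0.0 <= self.jitter <= 1.0:
            raise ValueError(f"jitter must lie in [0, 1], got {self.jitter}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LabeledPatchSet:
    """An ordered cohort of patches with parallel group labels and a manifest.

    ``manifest`` is a DataFrame with one row per patch recording its
    generation parameters and derivation (fresh vs. perturbed-from).
    """

    patches: list[ImagePatch]
    labels: list[str]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must have equal length")
        if len(self.manifest) != len(self.patches):
            raise ValueError("manifest must have one row per patch")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, label: str) -> list[ImagePatch]:
        return [p for p, l in zip(self.patches, self.labels) if l == label]


def _rng(seed: int) -> np.random.Generator:
    # Philox is counter-based: cheap independent streams per patch.
    return np.random.Generator(np.random.Philox(key=int(seed) & ((1 << 64) - 1)))


def _child_seed(master_seed: int, *indices: int) -> int:
    """Derive a stable per-patch seed from a master seed and position indices.

    Depends only on (master, indices), so cohorts are reproducible under
    subsetting and reordering of the surrounding code.
    """
    ss = np.random.SeedSequence(entropy=[int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0]) % (2**31)


def _pink_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Low-frequency-dominated (1/f) luminance field around slide-background level."""
    white = rng.normal(size=(n, n))
    f = np.fft.fftfreq(n)
    radius = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    radius[0, 0] = 1.0
    field = np.real(np.fft.ifft2(np.fft.fft2(white) / radius))
    field = (field - field.mean()) / (field.std() + 1e-12)
    return 0.88 + 0.035 * field


def _gland_layout(rng: np.random.Generator, spec: TextureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Hexagonal-lattice centres with jitter, and per-gland radii."""
    n = spec.size_px
    spacing = 1.8 * spec.element_scale_px
    dy = spacing * np.sqrt(3) / 2
    rows = np.arange(-1, n / dy + 2)
    centers = []
    for r_i, row in enumerate(rows):
        offset = (r_i % 2) * spacing / 2
        xs = np.arange(-1, n / spacing + 2) * spacing + offset
        ys = np.full_like(xs, row * dy)
        centers.append(np.column_stack([ys, xs]))
    centers = np.concatenate(centers)
    centers = centers + rng.normal(0.0, spec.jitter * spacing, size=centers.shape)
    base_radius = spec.element_scale_px / 2.0
    log_sd = 0.08 + 0.6 * spec.jitter  # size dispersion grows with irregularity
    radii = base_radius * np.exp(rng.normal(0.0, log_sd, size=len(centers)))
    # keep only glands that can touch the canvas
    margin = 3.0 * radii
    keep = (
        (centers[:, 0] > -margin)
        & (centers[:, 0] < n + margin)
        & (centers[:, 1] > -margin)
        & (centers[:, 1] < n + margin)
    )
    return centers[keep], radii[keep]


def _render_glands(
    lum: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    amps: np.ndarray,
) -> np.ndarray:
    n = lum.shape[0]
    out = lum.copy()
    for (cy, cx), radius, amp in zip(centers, radii, amps):
        sigma = 0.6 * radius
        half = int(np.ceil(3 * sigma))
        y0, y1 = max(0, int(np.floor(cy)) - half), min(n, int(np.ceil(cy)) + half + 1)
        x0, x1 = max(0, int(np.floor(cx)) - half), min(n, int(np.ceil(cx)) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1, dtype=float)[:, None] - cy
        xx = np.arange(x0, x1, dtype=float)[None, :] - cx
        profile = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        out[y0:y1, x0:x1] *= 1.0 - amp * profile  # multiplicative absorption
    return out


def _tint(lum: np.ndarray) -> np.ndarray:
    """Map a [0,1] luminance field onto the eosin-like colour axis, as uint8."""
    rgb = _STAIN_COLOR[None, None, :] + lum[:, :, None] * (_BG_COLOR - _STAIN_COLOR)[None, None, :]
    return np.round(np.clip(rgb, 0.0, 1.0) * 255).astype(np.uint8)


def generate_texture_patch(spec: TextureSpec) -> ImagePatch:
    """Render one RGB patch from its spec. Deterministic: same spec, same pixels."""
    rng = _rng(spec.seed)
    n = int(spec.size_px)
    if spec.pattern_class is PatternClass.NOISE:
        lum = np.full((n, n), 0.5)
        if spec.noise_sd > 0:
            lum = lum + rng.normal(0.0, spec.noise_sd, size=(n, n))
    else:
        # Patch-level macro variability: patches cut from different slide
        # regions differ in stain/illumination level, gland caliber and
        # stain uptake, independent of the within-patch regularity knob.
        bg_level = rng.normal(0.88, 0.02)
        scale_mult = float(np.exp(rng.normal(0.0, 0.10)))
        amp_level = rng.normal(0.50, 0.04)
        lum = bg_level + (_pink_background(rng, n) - 0.88)
        centers, radii = _gland_layout(
            rng, replace(spec, element_scale_px=spec.element_scale_px * scale_mult)
        )
        amps = amp_level - 0.05 + 0.1 * rng.random(len(centers))
        lum = _render_glands(lum, centers, radii, amps)
        if spec.noise_sd > 0:
            lum = lum + rng.normal(0.0, spec.noise_sd, size=(n, n))
    lum = np.clip(lum, 0.0, 1.0)
    return ImagePatch(
        pixels=_tint(lum),
        mode="RGB",
        source_id=f"tex-{spec.pattern_class.value.lower()}-s{spec.seed}",
    )


def perturb_patch(
    patch: ImagePatch, noise_sd: float, warp_px: float, seed: int
) -> ImagePatch:
    """Near-copy of ``patch``: smooth elastic warp plus additive pixel noise.

    Emulates generative-model output — the same structure with a small
    stochastic deviation.  ``noise_sd=0, warp_px=0`` returns an identical copy.
    """
    if noise_sd < 0 or warp_px < 0:
        raise ValueError("noise_sd and warp_px must be >= 0")
    if noise_sd == 0 and warp_px == 0:
        out = patch.copy()
        out.source_id = f"{patch.source_id}-perturb{seed}"
        return out

    rng = _rng(seed)
    if patch.mode == "RGB":
        arr = patch.pixels.astype(np.float64) / 255.0
    else:
        arr = patch.pixels.astype(np.float64).copy()
    h, w = arr.shape[:2]

    if warp_px > 0:
        # smooth displacement field, unit SD, scaled to warp_px
        def _field() -> np.ndarray:
            f = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=8.0)
            return warp_px * f / (f.std() + 1e-12)

        dy, dx = _field(), _field()
        row, col = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        coords = np.array([row + dy, col + dx])
        if arr.ndim == 3:
            arr = np.stack(
                [
                    ndimage.map_coordinates(arr[:, :, c], coords, order=1, mode="reflect")
                    for c in range(arr.shape[2])
                ],
                axis=2,
            )
        else:
            arr = ndimage.map_coordinates(arr, coords, order=1, mode="reflect")

    if noise_sd > 0:
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    arr = np.clip(arr, 0.0, 1.0)

    if patch.mode == "RGB":
        pixels = np.round(arr * 255).astype(np.uint8)
    else:
        pixels = arr
    return ImagePatch(pixels=pixels, mode=patch.mode, source_id=f"{patch.source_id}-perturb{seed}")


_MANIFEST_COLUMNS = [
    "patch_id",
    "label",
    "seed",
    "pattern_class",
    "size_px",
    "element_scale_px",
    "jitter",
    "noise_sd",
    "derived_from",
]


def generate_cohort(
    classes: Mapping[str, TextureSpec], n_per_class: int, seed: int
) -> LabeledPatchSet:
    """Generate ``n_per_class`` fresh patches per labeled template.

    Per-patch seeds are derived from the master seed and the (class, index)
    position, so any subset of the cohort is reproducible on its own.
    """
    if not classes:
        raise ValueError("classes must contain at least one template")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    patches: list[ImagePatch] = []
    labels: list[str] = []
    rows = []
    for class_idx, (label, template) in enumerate(classes.items()):
        for i in range(n_per_class):
            child = _child_seed(seed, class_idx, i)
            spec = replace(template, seed=child)
            patch = generate_texture_patch(spec)
            patch.source_id = f"{label}_{i:04d}"
            patches.append(patch)
            labels.append(label)
            rows.append(
                {
                    "patch_id": patch.source_id,
                    "label": label,
                    "seed": child,
                    "pattern_class": spec.pattern_class.value,
                    "size_px": spec.size_px,
                    "element_scale_px": spec.element_scale_px,
                    "jitter": spec.jitter,
                    "noise_sd": spec.noise_sd,
                    "derived_from": "",
                }
            )
    return LabeledPatchSet(patches, labels, pd.DataFrame(rows, columns=_MANIFEST_COLUMNS))


def perturb_cohort(
    base: LabeledPatchSet,
    source_label: str,
    new_label: str,
    noise_sd: float,
    warp_px: float,
    seed: int,
) -> LabeledPatchSet:
    """Perturbed near-copies of one group of an existing cohort (the
    generative-model analogue of that group)."""
    base_patches = base.subset(source_label)
    if not base_patches:
        raise ValueError(f"no patches with label {source_label!r} in base cohort")
    patches, labels, rows = [], [], []
    for i, src in enumerate(base_patches):
        child = _child_seed(seed, i)
        p = perturb_patch(src, noise_sd=noise_sd, warp_px=warp_px, seed=child)
        p.source_id = f"{new_label}_{i:04d}"
        patches.append(p)
        labels.append(new_label)
        rows.append(
            {
                "patch_id": p.source_id,
                "label": new_label,
                "seed": child,
                "pattern_class": "",
                "size_px": src.height_px,
                "element_scale_px": np.nan,
                "jitter": np.nan,
                "noise_sd": noise_sd,
                "derived_from": src.source_id,
            }
        )
    return LabeledPatchSet(patches, labels, pd.DataFrame(rows, columns=_MANIFEST_COLUMNS))


def generate_outlier_image(
    base_spec: TextureSpec, intensity_shift_sd: float, cohort_sd: float
) -> ImagePatch:
    """A patch whose whole-image RGB mean is shifted by ``intensity_shift_sd``
    cohort standard deviations (``cohort_sd`` in 0–255 intensity units).

    Raises if channel saturation makes the target mean unreachable
    (achieved shift off by more than 5%).
    """
    base = generate_texture_patch(base_spec)
    shift = float(intensity_shift_sd) * float(cohort_sd)
    arr = base.pixels.astype(np.float64) + shift
    arr = np.clip(arr, 0.0, 255.0)
    achieved = arr.mean() - base.pixels.astype(np.float64).mean()
    if shift != 0 and abs(achieved - shift) > 0.05 * abs(shift):
        raise ValueError(
            f"target RGB-mean shift {shift:+.1f} unreachable after clipping "
            f"(achieved {achieved:+.1f})"
        )
    return ImagePatch(
        pixels=np.round(arr).astype(np.uint8),
        mode="RGB",
        source_id=f"{base.source_id}-shift{intensity_shift_sd:+g}sd",
    )


def default_templates(size_px: int = 256, noise_sd: float = 0.02) -> dict[str, TextureSpec]:
    """The two phenotype templates used throughout: REGULAR (normal-like,
    jitter 0.05) and IRREGULAR (cancer-like, jitter 0.6)."""
    return {
        "REGULAR": TextureSpec(
            pattern_class=PatternClass.REGULAR,
            size_px=size_px,
            jitter=0.05,
            noise_sd=noise_sd,
        ),
        "IRREGULAR": TextureSpec(
            pattern_class=PatternClass.IRREGULAR,
            size_px=size_px,
            jitter=0.6,
            noise_sd=noise_sd,
        ),
    }


def write_patch_set(patch_set: LabeledPatchSet, out_dir: str | Path) -> Path:
    """Write one PNG per patch into per-label subdirectories plus manifest.csv.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    manifest = patch_set.manifest.copy()
    paths = []
    for patch, label in zip(patch_set.patches, patch_set.labels):
        rel = Path(label) / f"{patch.source_id}.png"
        save_patch(patch, out_dir / rel)
        paths.append(str(rel))
    manifest.insert(0, "patch_path", paths)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
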