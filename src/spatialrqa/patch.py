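"""Image patch container and PNG/TIFF round-trip helpers.

The package works on small square histology patches.  Two pixel
representations are used throughout:

* ``RGB`` — ``(H, W, 3)`` ``uint8`` array, values 0–255;
* ``GRAY`` — ``(H, W)`` ``float64`` array, values in [0, 1]
  (the representation the recurrence analysis consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["ImagePatch", "load_patch", "save_patch", "discover_images"]

#: file extensions recognised when scanning a directory for patches
IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")


@dataclass
class ImagePatch:
    """A single image patch with its provenance label.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 for RGB, ``(H, W)`` float in [0, 1] for GRAY.
    mode
        ``"RGB"`` or ``"GRAY"``.
    source_id
        Free-form identifier (file stem, generator tag, ...).
    tissue_fraction
        Fraction of non-background pixels, set by
        :func:`spatialrqa.preprocess.tissue_fraction`; ``None`` until computed.
    """

    pixels: np.ndarray
    mode: str = "RGB"
    source_id: str = ""
    tissue_fraction: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.mode == "RGB":
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ValueError(
                    f"RGB patch needs an (H, W, 3) array, got {self.pixels.shape}"
                )
            if self.pixels.dtype != np.uint8:
                if self.pixels.min() < 0 or self.pixels.max() > 255:
                    raise ValueError("RGB values must lie in [0, 255]")
                self.pixels = self.pixels.astype(np.uint8)
        elif self.mode == "GRAY":
            if self.pixels.ndim != 2:
                raise ValueError(
                    f"GRAY patch needs an (H, W) array, got {self.pixels.shape}"
                )
            self.pixels = self.pixels.astype(np.float64, copy=False)
            if self.pixels.size and (self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12):
                raise ValueError("GRAY values must lie in [0, 1]")
        else:
            raise ValueError(f"unknown mode {self.mode!r} (expected 'RGB' or 'GRAY')")
        if self.pixels.size == 0:
            raise ValueError("patch must contain at least one pixel")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    def copy(self) -> "ImagePatch":
        return ImagePatch(
            pixels=self.pixels.copy(),
            mode=self.mode,
            source_id=self.source_id,
            tissue_fraction=self.tissue_fraction,
        )


def load_patch(path: str | Path) -> ImagePatch:
    """Read a PNG/TIFF file into an :class:`ImagePatch` (RGB or GRAY)."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3:
        return ImagePatch(pixels=arr.astype(np.uint8), mode="RGB", source_id=path.stem)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    return ImagePatch(pixels=arr, mode="GRAY", source_id=path.stem)


def save_patch(patch: ImagePatch, path: str | Path) -> None:
    """Write a patch as PNG (RGB stays uint8; GRAY is quantized to 8 bit)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if patch.mode == "RGB":
        iio.imwrite(path, patch.pixels)
    else:
        iio.imwrite(path, np.round(patch.pixels * 255).astype(np.uint8))


def discover_images(directory: str | Path) -> list[Path]:
    """List image files in ``directory``, case-insensitive, sorted lexically."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"image directory not found: {directory}")
    hits = [
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    return sorted(hits, key=lambda p: p.name)
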