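"""Grayscale intensity images with a physical pixel size.

The analysis operates on 2D scalar fields f(x).  Scales are specified in
physical units (micrometres), so every image carries the edge length of one
pixel.  The default pixel size corresponds to a 512-pixel scan of a 180 µm
field of view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

#: 180 µm field of view over 512 px.
DEFAULT_PIXEL_SIZE_UM = 180.0 / 512.0


@dataclass(frozen=True)
class IntensityImage:
    """A 2D non-negative intensity field with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size_um : float
        Physical edge length of one pixel in micrometres; must be > 0.
    label : str
        Optional identifier carried through result tables.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite pixels")
        if (px < 0).any():
            raise ValueError("image contains negative pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um


def load_image(path: str | os.PathLike, pixel_size_um: float | None = None,
               label: str | None = None) -> IntensityImage:
    """Read a single-channel TIFF or PNG as an :class:`IntensityImage`.

    ``pixel_size_um`` falls back to a YAML sidecar (``<stem>.yaml`` with a
    ``pixel_size_um`` key) next to the image, then to the package default.
    Multi-channel images are rejected rather than silently flattened.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not single-channel (shape {arr.shape})")
    if pixel_size_um is None:
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
            pixel_size_um = float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
        else:
            pixel_size_um = DEFAULT_PIXEL_SIZE_UM
    return IntensityImage(arr.astype(float), pixel_size_um,
                          label=path.stem if label is None else label)


def save_image(image: IntensityImage, path: str | os.PathLike) -> None:
    """Write as 16-bit single-channel TIFF, clipping to the uint16 range."""
    path = Path(path)
    px = np.clip(np.rint(image.pixels), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, px.astype(np.uint16))
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump({"pixel_size_um": float(image.pixel_size_um)}, fh)
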