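"""Image and table I/O shared by all stages.

TIFF (8/16-bit, multi-page) and PNG are supported.  Multi-page TIFFs map
to channel-first stacks with pages in channel order; RGB PNGs map to
3-plane rasters in R, G, B order.  Float rasters in [0, 1] are quantized
to 16-bit on export; integer label maps are written verbatim as 16-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["ImageBundle", "read_image", "write_image", "write_labels"]

SUPPORTED = (".tif", ".tiff", ".png")


@dataclass
class ImageBundle:
    """A raster plus channel names (single-channel rasters have one name)."""

    data: np.ndarray  # (h, w) or (c, h, w)
    channels: list[str]

    @property
    def is_multichannel(self) -> bool:
        return self.data.ndim == 3


def read_image(path: str | Path) -> ImageBundle:
    """Read TIFF or PNG, preserving intensities bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
        if len(pages) == 1:
            arr = pages[0]
            if arr.ndim == 3 and arr.shape[-1] in (3, 4):
                arr = np.moveaxis(arr[..., :3], -1, 0)
                return ImageBundle(data=arr, channels=["R", "G", "B"])
            return ImageBundle(data=arr, channels=["page0"])
        return ImageBundle(
            data=np.stack(pages), channels=[f"page{i}" for i in range(len(pages))]
        )
    if suffix == ".png":
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = np.moveaxis(arr[..., :3], -1, 0)
            return ImageBundle(data=arr, channels=["R", "G", "B"])
        return ImageBundle(data=arr, channels=["gray"])
    raise ValueError(f"unsupported format {suffix!r}; supported: {', '.join(SUPPORTED)}")


def _quantize16(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.uint16)
    return np.round(np.clip(arr, 0.0, 1.0) * 65535.0).astype(np.uint16)


def write_image(path: str | Path, data: np.ndarray, channels: list[str] | None = None) -> None:
    """Write a raster; floats in [0, 1] are quantized to 16-bit.

    Multi-channel (c, h, w) arrays become multi-page TIFFs (page order =
    channel order) or, for PNG, an (h, w, 3) colour image.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    arr = np.asarray(data)
    if suffix in (".tif", ".tiff"):
        # minisblack keeps (c, h, w) stacks as one page per channel
        tifffile.imwrite(path, _quantize16(arr), photometric="minisblack")
        return
    if suffix == ".png":
        if arr.ndim == 3:
            arr = np.moveaxis(arr, 0, -1)
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
        iio.imwrite(path, arr)
        return
    raise ValueError(f"unsupported format {suffix!r}; supported: {', '.join(SUPPORTED)}")


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write an instance map as a 16-bit label TIFF."""
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))
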