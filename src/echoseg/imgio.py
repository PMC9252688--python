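"""Image and manifest I/O: 8/16-bit grayscale PNG/TIFF in, [0, 1] floats out."""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_manifest",
    "read_manifest",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float64 in [0, 1], scaled by bit depth.

    RGB(A) inputs are collapsed to luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValueError(f"unsupported image format: {path}")
    raw = iio.imread(path)
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return np.clip(arr, 0.0, 1.0)


def read_mask(path) -> np.ndarray:
    """Read a binary mask: values above half-scale become 1, the rest 0."""
    return (read_image(path) > 0.5).astype(np.uint8)


def write_image(path, image: np.ndarray, bits: int = 8) -> None:
    """Write a [0, 1] raster as an 8- or 16-bit grayscale PNG/TIFF."""
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bits == 8:
        arr = np.round(image * 255).astype(np.uint8)
    elif bits == 16:
        arr = np.round(image * 65535).astype(np.uint16)
    else:
        raise ValueError(f"bits must be 8 or 16, got {bits}")
    iio.imwrite(Path(path), arr)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a {0, 255} 8-bit PNG."""
    write_image(path, np.asarray(mask).astype(bool).astype(np.float64), bits=8)


def write_manifest(path, rows: list[dict]) -> None:
    """Write a TSV manifest with columns id, image, mask."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "image", "mask"],
                                delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
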