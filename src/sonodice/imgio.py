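"""Raster readers and writers.

PNG is the canonical interchange format (lossless, 1-bit capable); TIFF is
accepted for input.  Grayscale frames round-trip as 8-bit, overlays and
agreement renderings as 24-bit RGB, binary masks as 1-bit PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_raster", "write_raster"]

_READ_SUFFIXES = {".png", ".tif", ".tiff"}
_WRITE_SUFFIXES = {".png", ".tif", ".tiff"}


def read_raster(path) -> np.ndarray:
    """Read a raster as bool (1-bit), uint8 grayscale, or uint8 RGB."""
    path = Path(path)
    if path.suffix.lower() not in _READ_SUFFIXES:
        raise ValueError(
            f"unsupported raster format {path.suffix!r} for {path}; "
            f"expected one of {sorted(_READ_SUFFIXES)}"
        )
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    try:
        with Image.open(path) as img:
            if img.mode == "1":
                return np.array(img, dtype=bool)
            if img.mode == "L":
                return np.array(img, dtype=np.uint8)
            if img.mode in ("RGB", "RGBA", "P"):
                return np.array(img.convert("RGB"), dtype=np.uint8)
            if img.mode.startswith("I") or img.mode == "F":
                arr = np.array(img)
                return np.clip(arr, 0, 255).astype(np.uint8)
            return np.array(img.convert("L"), dtype=np.uint8)
    except (OSError, SyntaxError) as err:
        raise ValueError(f"corrupt or unreadable raster {path}: {err}") from err


def write_raster(raster: np.ndarray, path) -> Path:
    """Write a raster; dtype picks the mode (bool→1-bit, uint8→L/RGB)."""
    path = Path(path)
    if path.suffix.lower() not in _WRITE_SUFFIXES:
        raise ValueError(
            f"unsupported raster format {path.suffix!r} for {path}; "
            f"expected one of {sorted(_WRITE_SUFFIXES)}"
        )
    arr = np.asarray(raster)
    if arr.dtype == bool:
        img = Image.fromarray(arr)  # mode "1"
    elif arr.ndim == 2:
        img = Image.fromarray(arr.astype(np.uint8), mode="L")
    elif arr.ndim == 3 and arr.shape[2] == 3:
        img = Image.fromarray(arr.astype(np.uint8), mode="RGB")
    else:
        raise ValueError(f"cannot write raster of shape {arr.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    img.save(path)
    return path
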