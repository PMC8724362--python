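"""Tracing overlays and their conversion to filled binary masks.

A tracing is a closed curve drawn over a scan image, either by the automated
device or by a human reviewer.  The analysis pipeline converts each tracing
into a filled binary mask — white inside the traced border, black outside —
by isolating the overlay curve, bridging small rasterization gaps, flood
filling the exterior, and cropping to the sector scan area.  This module also
supports obscuring a device tracing in place so that reviewers can free-trace
the same image blinded to the device's answer.

Conventions
-----------
* Rasters are row-major, 0-based, origin at top-left; images and masks share
  the convention everywhere.
* Curve (boundary) pixels count as *inside* the filled mask.
* The exterior is identified by 4-connected flood fill from the raster
  border; an 8-connected curve is therefore a watertight barrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BACKGROUND_VALUE, SectorGeometry

__all__ = [
    "TracingOverlay",
    "BinaryMask",
    "NoTracingError",
    "OpenContourError",
    "DEVICE_COLOR",
    "REVIEWER_COLOR",
    "extract_overlay",
    "render_overlay",
    "obscure_tracing",
    "crop_to_scan_area",
    "fill_tracing",
    "mask_boundary",
]

logger = logging.getLogger(__name__)

#: default overlay colors: device = pure blue, reviewers = magenta
DEVICE_COLOR = (0, 0, 255)
REVIEWER_COLOR = (255, 0, 255)

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class NoTracingError(ValueError):
    """Raised when no overlay pixels match the requested color."""


class OpenContourError(ValueError):
    """Raised when a curve does not enclose any region after gap closure."""


@dataclass(frozen=True)
class TracingOverlay:
    """A closed annotation curve registered to a scan image.

    Attributes
    ----------
    pixels
        ``(N, 2)`` integer array of (row, col) curve coordinates.
    source
        Provenance tag, e.g. ``"device"`` or ``"reviewer:R2"``.
    image_ref
        Identifier of the underlying scan image.
    color
        RGB triple used when the overlay is rendered.
    """

    pixels: np.ndarray
    source: str = "unknown"
    image_ref: str = ""
    color: tuple[int, int, int] = DEVICE_COLOR

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2:
            raise ValueError(f"pixels must be (N, 2), got shape {px.shape}")
        px = np.unique(px, axis=0) if len(px) else px.reshape(0, 2)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    def __len__(self) -> int:
        return len(self.pixels)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the curve on a grid of ``shape``."""
        out = np.zeros(shape, dtype=bool)
        if len(self.pixels):
            r, c = self.pixels[:, 0], self.pixels[:, 1]
            if r.min() < 0 or c.min() < 0 or r.max() >= shape[0] or c.max() >= shape[1]:
                raise ValueError(
                    f"overlay coordinates exceed raster shape {shape}"
                )
            out[r, c] = True
        return out

    def translated(self, drow: int, dcol: int) -> "TracingOverlay":
        return TracingOverlay(
            self.pixels + np.array([drow, dcol]),
            source=self.source,
            image_ref=self.image_ref,
            color=self.color,
        )

    def to_csv(self, path) -> None:
        """Write curve coordinates as ``row,col`` lines (with header)."""
        lines = ["row,col"] + [f"{r},{c}" for r, c in self.pixels]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TracingOverlay":
        with open(path) as fh:
            rows = fh.read().strip().splitlines()
        if rows and rows[0].strip() == "row,col":
            rows = rows[1:]
        pixels = [tuple(int(v) for v in line.split(",")) for line in rows if line]
        return cls(np.array(pixels, int).reshape(-1, 2), **kwargs)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster; True = pixel within the tracing."""

    grid: np.ndarray
    image_ref: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise ValueError(f"grid must be 2-D, got {g.ndim}-D")
        g = g.copy()
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def area(self) -> int:
        return int(self.grid.sum())


def as_grid(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Boolean ndarray view of a mask argument (BinaryMask or array)."""
    if isinstance(mask, BinaryMask):
        return mask.grid
    return np.asarray(mask, dtype=bool)


def extract_overlay(
    rgb_image: np.ndarray,
    color_spec: tuple[int, int, int],
    tolerance: int = 0,
    source: str = "unknown",
    image_ref: str = "",
) -> TracingOverlay:
    """Recover the tracing curve pixels matching ``color_spec``.

    ``tolerance`` is a per-channel absolute bound; 0 demands an exact match
    (appropriate for synthetic rasters), ~30 accommodates lossy compression.
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim == 2:  # pure grayscale carries no colored overlay
        rgb = np.stack([rgb] * 3, axis=-1)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    target = np.array(color_spec, dtype=int)
    diff = np.abs(rgb.astype(int) - target)
    hit = (diff <= int(tolerance)).all(axis=2)
    if not hit.any():
        raise NoTracingError(
            f"no tracing found for color {tuple(color_spec)} "
            f"at tolerance {tolerance}"
        )
    rows, cols = np.nonzero(hit)
    return TracingOverlay(
        np.stack([rows, cols], axis=1),
        source=source,
        image_ref=image_ref,
        color=tuple(int(v) for v in color_spec),
    )


def render_overlay(image: np.ndarray, overlay: TracingOverlay) -> np.ndarray:
    """Paint the overlay curve onto a copy of ``image`` (returned as RGB)."""
    img = np.asarray(image)
    if img.ndim == 2:
        rgb = np.stack([img] * 3, axis=-1).astype(np.uint8)
    else:
        rgb = img.astype(np.uint8).copy()
    curve = overlay.raster(rgb.shape[:2])
    rgb[curve] = overlay.color
    return rgb


def obscure_tracing(rgb_image: np.ndarray, overlay: TracingOverlay) -> np.ndarray:
    """Replace each curve pixel by the median of non-curve 5×5 neighbors.

    The result contains no pixel matching the overlay color at tolerance 0,
    so a subsequent free-trace review cannot see the original tracing.
    Non-curve pixels are left untouched, and the operation is idempotent on
    the curve pixel set.
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    out = rgb.astype(np.uint8).copy()
    if len(overlay) == 0:
        logger.warning("obscure_tracing: empty overlay, image returned unchanged")
        return out
    h, w = out.shape[:2]
    curve = overlay.raster((h, w))
    for r, c in overlay.pixels:
        r0, r1 = max(r - 2, 0), min(r + 3, h)
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        window = out[r0:r1, c0:c1].reshape(-1, 3)
        keep = ~curve[r0:r1, c0:c1].reshape(-1)
        pool = window[keep] if keep.any() else window
        out[r, c] = np.median(pool, axis=0).astype(np.uint8)
    # Per-channel medians of arbitrary neighborhoods could coincide with the
    # overlay color; nudge any such pixel so the post-condition is exact.
    residual = (out[curve] == np.array(overlay.color)).all(axis=1)
    if residual.any():
        rc = overlay.pixels[residual]
        ch = int(np.argmax(overlay.color))  # move the brightest channel
        vals = out[rc[:, 0], rc[:, 1], ch].astype(int)
        out[rc[:, 0], rc[:, 1], ch] = np.where(vals > 0, vals - 1, vals + 1)
    return out


def crop_to_scan_area(
    data: BinaryMask | np.ndarray, sector: SectorGeometry | None = None
):
    """Zero out everything outside the sector scan area.

    Masks get False outside; grayscale/RGB images get the reserved background
    value (0).  Pixels inside the sector are unchanged.  Returns the same
    type as the input.
    """
    is_mask_obj = isinstance(data, BinaryMask)
    arr = data.grid if is_mask_obj else np.asarray(data)
    shape = arr.shape[:2]
    sector = sector or SectorGeometry(shape)
    if tuple(sector.shape) != tuple(shape):
        raise ValueError(
            f"raster shape {tuple(shape)} does not match sector shape "
            f"{tuple(sector.shape)}"
        )
    sec = sector.mask()
    if arr.dtype == bool:
        out = arr & sec
        return BinaryMask(out, image_ref=data.image_ref) if is_mask_obj else out
    out = arr.copy()
    out[~sec] = BACKGROUND_VALUE
    return out


def fill_tracing(
    overlay: TracingOverlay,
    dims: tuple[int, int],
    closing_radius: int = 2,
    sector: SectorGeometry | None = None,
    image_ref: str | None = None,
) -> BinaryMask:
    """Fill a tracing outline into a binary mask.

    The curve is used as a barrier for a 4-connected flood fill started from
    every raster border pixel; the mask is the complement of the flooded
    exterior (interior plus the curve itself), cropped to the sector.

    Hand and AI tracings rasterize with occasional 1–2 px discontinuities, so
    when the raw curve does not enclose anything it is thickened by a growing
    radius (1 … ``closing_radius``) until the barrier is watertight.
    Thickening pixels count as inside only when 4-adjacent to the recovered
    interior — bridging pixels at genuine gaps are kept, while the rest of
    the thickened band is trimmed — so the fill is exact for curves that
    were already watertight.

    Raises
    ------
    OpenContourError
        If no interior exists even at the maximum closing radius.
    """
    if len(overlay) == 0:
        raise OpenContourError("open contour: overlay is empty")
    curve = overlay.raster(dims)
    interior = None
    for radius in range(0, int(closing_radius) + 1):
        barrier = curve if radius == 0 else ndimage.binary_dilation(
            curve, structure=_CROSS, iterations=radius
        )
        filled = ndimage.binary_fill_holes(barrier, structure=_CROSS)
        cand = filled & ~barrier
        if cand.any():
            interior = cand
            break
    if interior is None:
        raise OpenContourError(
            f"open contour: no enclosed region after gap closure up to "
            f"radius {closing_radius}"
        )

    labels, n = ndimage.label(interior, structure=_CROSS)
    significant = 1
    if n > 1:
        sizes = ndimage.sum_labels(interior, labels, index=np.arange(1, n + 1))
        # single-pixel pockets from stair-step rasterization are part of the
        # boundary band, not genuine extra loops
        significant = int((sizes >= max(9.0, 0.01 * sizes.max())).sum())
        if significant > 1:
            keep = int(np.argmax(sizes)) + 1
            logger.warning(
                "fill_tracing: curve encloses %d distinct regions; keeping "
                "the largest (%d px)", significant, int(sizes.max()),
            )
            interior = labels == keep
    if significant > 1:
        near = ndimage.binary_dilation(interior, structure=np.ones((3, 3), bool))
        mask = interior | (curve & near)
    else:
        extra = barrier & ~curve
        mask = interior | curve
        if extra.any():
            near = ndimage.binary_dilation(interior, structure=_CROSS)
            mask |= extra & near

    sector = sector or SectorGeometry(dims)
    mask &= sector.mask()
    return BinaryMask(
        mask, image_ref=overlay.image_ref if image_ref is None else image_ref
    )


def mask_boundary(
    mask: BinaryMask | np.ndarray, source: str = "boundary", image_ref: str = ""
) -> TracingOverlay:
    """Inner 4-boundary of a mask as a tracing overlay.

    The returned curve, fed back through :func:`fill_tracing`, recovers the
    original mask exactly for simply-connected masks.
    """
    grid = as_grid(mask)
    eroded = ndimage.binary_erosion(grid, structure=_CROSS, border_value=0)
    rows, cols = np.nonzero(grid & ~eroded)
    ref = image_ref or (mask.image_ref if isinstance(mask, BinaryMask) else "")
    return TracingOverlay(np.stack([rows, cols], axis=1), source=source, image_ref=ref)
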