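"""Sector scan-area geometry.

B-mode images carry echo data only inside a fan-shaped sector whose apex sits
at the transducer.  All pixel statistics in this package (confusion areas,
Dice indices, area percentages) are restricted to that sector; pixels outside
it carry no signal and are held at a reserved background value.

The sector is modeled as a circular sector with its apex at the top-center of
the raster, opening downward with a configurable aperture (default 120°).
The default radius is the largest that keeps the sector inscribed in the
raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["SectorGeometry", "DEFAULT_APERTURE_DEG"]

DEFAULT_APERTURE_DEG = 120.0

#: intensity value reserved for pixels outside the sector
BACKGROUND_VALUE = 0


@dataclass(frozen=True)
class SectorGeometry:
    """Circular-sector scan area, apex at top-center, opening downward."""

    shape: tuple[int, int]  # (height, width)
    aperture_deg: float = DEFAULT_APERTURE_DEG
    radius: float | None = None

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 2 or w < 2:
            raise ValueError(f"shape must be at least 2x2, got {self.shape}")
        if not 0 < self.aperture_deg < 180:
            raise ValueError(
                f"aperture_deg must be in (0, 180), got {self.aperture_deg}"
            )
        object.__setattr__(self, "shape", (int(h), int(w)))
        if self.radius is None:
            half = math.radians(self.aperture_deg / 2)
            r = min(h - 1.0, ((w - 1) / 2.0) / math.sin(half))
            object.__setattr__(self, "radius", r)

    @property
    def apex(self) -> tuple[float, float]:
        """(row, col) of the sector apex."""
        return (0.0, (self.shape[1] - 1) / 2.0)

    @property
    def area(self) -> float:
        """Analytic sector area in pixels² (aperture/360 · πR²)."""
        return self.aperture_deg / 360.0 * math.pi * self.radius**2

    def mask(self) -> np.ndarray:
        """Boolean raster, True inside the sector (read-only, cached)."""
        return _sector_mask(self.shape, self.aperture_deg, self.radius)


@lru_cache(maxsize=32)
def _sector_mask(
    shape: tuple[int, int], aperture_deg: float, radius: float
) -> np.ndarray:
    h, w = shape
    half = math.radians(aperture_deg / 2)
    rows, cols = np.indices(shape)
    dy = rows.astype(float)
    dx = cols - (w - 1) / 2.0
    inside = (np.hypot(dx, dy) <= radius) & (np.arctan2(np.abs(dx), dy) <= half)
    inside.setflags(write=False)
    return inside
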