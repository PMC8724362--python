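"""Pixel-wise agreement between two filled tracings.

The reviewer mask is treated as the reference ("known truth") and the device
mask as the test ("estimated truth").  Pixel-by-pixel comparison inside the
sector scan area yields the four confusion areas

    TP  traced by both          (rendered yellow)
    TN  traced by neither       (rendered white)
    FP  device only             (rendered red)
    FN  reviewer only           (rendered green)

and the Sørensen–Dice index SDI = 2·TP / (2·TP + FP + FN), equivalently
2|A∩B| / (|A| + |B|): 1 is perfect agreement, 0 is none.  SDI is symmetric
in the two masks (swapping roles swaps FP and FN, leaving the formula
unchanged), so the reference/test orientation matters only for the FP/FN
labels and colors, not for the index.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .geometry import SectorGeometry
from .tracing import BinaryMask, as_grid

__all__ = [
    "ConfusionAreas",
    "ConcordanceRecord",
    "UndefinedSDIError",
    "confusion_areas",
    "sdi",
    "sdi_value",
    "area_percentages",
    "render_agreement",
    "AGREEMENT_COLORS",
]

#: Fig.-style agreement rendering palette
AGREEMENT_COLORS = {
    "tp": (255, 255, 0),
    "tn": (255, 255, 255),
    "fp": (255, 0, 0),
    "fn": (0, 255, 0),
    "outside": (0, 0, 0),
}


class UndefinedSDIError(ValueError):
    """Raised when both masks are empty (tp = fp = fn = 0)."""


@dataclass(frozen=True)
class ConfusionAreas:
    """TP/TN/FP/FN pixel counts over the evaluable (sector) region."""

    tp: int
    tn: int
    fp: int
    fn: int
    total: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn", "total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.tn + self.fp + self.fn != self.total:
            raise ValueError(
                f"counts {self.tp}+{self.tn}+{self.fp}+{self.fn} "
                f"do not sum to total {self.total}"
            )


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-(image, reviewer) agreement result carried through the study."""

    image_code: str
    reviewer_id: str
    sdi: float
    areas: ConfusionAreas

    def __post_init__(self) -> None:
        # the stored index must be recomputable from the stored areas
        if abs(self.sdi - sdi(self.areas)) > 1e-12:
            raise ValueError("sdi inconsistent with confusion areas")


def confusion_areas(
    reference: BinaryMask | np.ndarray,
    test: BinaryMask | np.ndarray,
    sector: SectorGeometry | None = None,
) -> ConfusionAreas:
    """Pixel-by-pixel confusion decomposition of two masks.

    ``reference`` is the reviewer (known-truth) mask, ``test`` the device
    (estimated-truth) mask.  Counts are restricted to the sector scan area;
    pass ``sector=None`` to use the default inscribed 120° sector for the
    mask shape.
    """
    ref = as_grid(reference)
    tst = as_grid(test)
    if ref.shape != tst.shape:
        raise ValueError(
            f"mask shapes differ: reference {ref.shape} vs test {tst.shape}"
        )
    sector = sector or SectorGeometry(ref.shape)
    if tuple(sector.shape) != ref.shape:
        raise ValueError(
            f"sector shape {tuple(sector.shape)} does not match masks {ref.shape}"
        )
    sec = sector.mask()
    ref = ref & sec
    tst = tst & sec
    tp = int((ref & tst).sum())
    fn = int((ref & ~tst).sum())
    fp = int((~ref & tst).sum())
    total = int(sec.sum())
    return ConfusionAreas(tp=tp, tn=total - tp - fp - fn, fp=fp, fn=fn, total=total)


def sdi_value(tp: float, fp: float, fn: float) -> float:
    """Sørensen–Dice index from raw (count or percentage) areas."""
    denom = 2.0 * tp + fp + fn
    if denom == 0:
        raise UndefinedSDIError(
            "undefined SDI: tp = fp = fn = 0 (both masks empty)"
        )
    return 2.0 * tp / denom


def sdi(areas: ConfusionAreas) -> float:
    """Sørensen–Dice index 2·TP / (2·TP + FP + FN) of a confusion record."""
    return sdi_value(areas.tp, areas.fp, areas.fn)


def area_percentages(areas: ConfusionAreas) -> tuple[float, float, float, float]:
    """(TP, TN, FP, FN) as percentages of the sector area.

    Rounded half-away-from-zero to 3 decimals; the four rounded values sum
    to 100.000 within ±0.002.
    """
    if areas.total <= 0:
        raise ValueError("total must be positive to compute percentages")

    def pct(count: int) -> float:
        exact = Decimal(count) * 100 / Decimal(areas.total)
        return float(exact.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))

    return (pct(areas.tp), pct(areas.tn), pct(areas.fp), pct(areas.fn))


def render_agreement(
    reference: BinaryMask | np.ndarray,
    test: BinaryMask | np.ndarray,
    sector: SectorGeometry | None = None,
) -> np.ndarray:
    """Four-color agreement rendering (RGB uint8).

    TP yellow, TN white, FP red, FN green; pixels outside the sector black.
    Per-color pixel counts equal :func:`confusion_areas` exactly.
    """
    ref = as_grid(reference)
    tst = as_grid(test)
    if ref.shape != tst.shape:
        raise ValueError(
            f"mask shapes differ: reference {ref.shape} vs test {tst.shape}"
        )
    sector = sector or SectorGeometry(ref.shape)
    sec = sector.mask()
    out = np.zeros(ref.shape + (3,), dtype=np.uint8)
    out[sec] = AGREEMENT_COLORS["tn"]
    out[sec & ref & tst] = AGREEMENT_COLORS["tp"]
    out[sec & ~ref & tst] = AGREEMENT_COLORS["fp"]
    out[sec & ref & ~tst] = AGREEMENT_COLORS["fn"]
    return out
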