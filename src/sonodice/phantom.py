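"""Synthetic biplane B-mode scan phantom.

Stands in for the porcine study data: an automated scanner placed over an
intercostal space (ICS 4–8) records 12 B-mode frames per scan (6 orthogonal
biplane pairs).  The heart appears as a dark (hypoechoic) elliptical chamber
on a bright speckled background inside a fan-shaped sector; the scanner's AI
and the human reviewers each trace the chamber border.

Three physiologic states drive distinct tracer-error behavior:

``pre_arrest``
    The beating heart: chamber semiaxes scale per frame by
    ``1 + cycle_amplitude·sin(phase_k)`` with phases spread over the 12
    frames, and the simulated device tracer carries larger radial jitter.
``arrest``
    Cardiac standstill: fixed chamber, crisp borders, smallest jitter.
``late_arrest``
    Prolonged arrest: echogenic clot blobs form inside the chamber.  The
    simulated device undertraces — its border cuts inside clots straddling
    the chamber wall — while reviewers trace the full chamber outline,
    reproducing the device-undertraces / human-includes disagreement mode.

Rib shadows (a dark vertical band where the transducer sat over a rib) occur
independently per frame with a configurable probability and flag the frame
for exclusion at screening.

All outputs are pure functions of (config, identifiers, seed): regenerating
any single scan set in isolation is bit-identical to generating it within a
full study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import draw

from ._rng import substream
from .geometry import SectorGeometry
from .tracing import (
    DEVICE_COLOR,
    REVIEWER_COLOR,
    BinaryMask,
    TracingOverlay,
    fill_tracing,
)

__all__ = [
    "State",
    "PhantomConfig",
    "EllipseGeometry",
    "ScanImage",
    "ScanSet",
    "generate_scan_set",
    "generate_frame",
    "simulate_device_tracing",
    "simulate_reviewer_tracing",
    "simulate_eligibility",
    "generate_study",
    "plan_study",
    "plan_acquisition",
    "StudyData",
    "IMAGES_PER_SCAN",
    "ICS_RANGE",
]

IMAGES_PER_SCAN = 12
ICS_RANGE = (4, 8)  # inclusive

_CHAMBER_MEAN = 40.0
_BACKGROUND_MEAN = 160.0
_CLOT_MEAN = 150.0
_RIB_SHADOW_MEAN = 20.0
_RIB_SHADOW_WIDTH_FRAC = 0.15


class State(str, Enum):
    """Physiologic state of the animal at scan time."""

    PRE_ARREST = "pre_arrest"
    ARREST = "arrest"
    LATE_ARREST = "late_arrest"


def _coerce_state(state: "State | str") -> State:
    try:
        return State(state)
    except ValueError:
        raise ValueError(
            f"state must be one of {[s.value for s in State]}, got {state!r}"
        ) from None


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic scan generator.

    Defaults emulate the acquisition geometry of the study design: full-size
    1616×1216 rasters (≈1.97 M pixels per image) with the heart chamber
    centered low in the sector.  ``heart_center`` / ``heart_semiaxes`` left
    as None are derived from the raster size.  Jitter values are standard
    deviations of radial tracing error in pixels.
    """

    image_width: int = 1616
    image_height: int = 1216
    heart_center: tuple[float, float] | None = None  # (row, col)
    heart_semiaxes: tuple[float, float] | None = None  # (major=cols, minor=rows)
    cycle_amplitude: float = 0.12
    clot_fraction: float = 0.30
    clot_count: int = 4
    speckle_noise_sd: float = 20.0
    rib_shadow_probability: float = 0.05
    tracer_jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            State.PRE_ARREST.value: 3.0,
            State.ARREST.value: 1.0,
            State.LATE_ARREST.value: 4.0,
        }
    )
    reviewer_jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"R1": 1.2, "R2": 1.5, "R3": 1.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_width, self.image_height
        if w < 16 or h < 16:
            raise ValueError(f"image dimensions too small: {w}x{h}")
        if not 0 <= self.cycle_amplitude <= 0.5:
            raise ValueError(
                f"cycle_amplitude must be in [0, 0.5], got {self.cycle_amplitude}"
            )
        if not 0 <= self.clot_fraction <= 0.8:
            raise ValueError(
                f"clot_fraction must be in [0, 0.8], got {self.clot_fraction}"
            )
        if self.clot_count < 0:
            raise ValueError(f"clot_count must be >= 0, got {self.clot_count}")
        if not 0 <= self.rib_shadow_probability <= 1:
            raise ValueError(
                "rib_shadow_probability must be in [0, 1], "
                f"got {self.rib_shadow_probability}"
            )
        if self.speckle_noise_sd < 0:
            raise ValueError(
                f"speckle_noise_sd must be >= 0, got {self.speckle_noise_sd}"
            )
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")
        a, b = self.semiaxes
        if a <= 0 or b <= 0:
            raise ValueError(f"heart_semiaxes must be positive, got {(a, b)}")
        if a >= w / 2 or b >= h / 2:
            raise ValueError(
                f"heart_semiaxes {(a, b)} must be smaller than half the "
                f"image dimensions ({w / 2}, {h / 2})"
            )
        for state in State:
            if state.value not in self.tracer_jitter_sd:
                raise ValueError(
                    f"tracer_jitter_sd missing state '{state.value}'"
                )
        for key, sd in {**self.tracer_jitter_sd, **self.reviewer_jitter_sd}.items():
            if sd < 0:
                raise ValueError(f"jitter sd for '{key}' must be >= 0, got {sd}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height, self.image_width)

    @property
    def center(self) -> tuple[float, float]:
        if self.heart_center is not None:
            return tuple(float(v) for v in self.heart_center)
        return (0.55 * self.image_height, (self.image_width - 1) / 2.0)

    @property
    def semiaxes(self) -> tuple[float, float]:
        if self.heart_semiaxes is not None:
            return tuple(float(v) for v in self.heart_semiaxes)
        return (0.18 * self.image_width, 0.12 * self.image_width)

    @property
    def sector(self) -> SectorGeometry:
        return SectorGeometry(self.shape)


@dataclass(frozen=True)
class EllipseGeometry:
    """Analytic chamber geometry of one frame (used by the tracers)."""

    center: tuple[float, float]  # (row, col)
    semiaxes: tuple[float, float]  # (a along cols, b along rows)
    clots: tuple[tuple[float, float, float], ...] = ()  # (row, col, radius)


@dataclass(frozen=True)
class ScanImage:
    """One B-mode-like frame with acquisition metadata."""

    pixels: np.ndarray | None
    animal_id: str
    ics: int
    state: State
    scan_index: int
    plane_index: int
    rib_shadow_flag: bool
    geometry: EllipseGeometry | None = None

    def __post_init__(self) -> None:
        if not ICS_RANGE[0] <= self.ics <= ICS_RANGE[1]:
            raise ValueError(
                f"ics must be in {ICS_RANGE[0]}..{ICS_RANGE[1]}, got {self.ics}"
            )
        if not 1 <= self.plane_index <= IMAGES_PER_SCAN:
            raise ValueError(
                f"plane_index must be in 1..{IMAGES_PER_SCAN}, got {self.plane_index}"
            )
        object.__setattr__(self, "state", _coerce_state(self.state))

    @property
    def pair_index(self) -> int:
        """Biplane pair number: planes (2k−1, 2k) form orthogonal pair k."""
        return (self.plane_index + 1) // 2

    @property
    def image_id(self) -> str:
        return (
            f"{self.animal_id}_{self.state.value}_ics{self.ics}"
            f"_scan{self.scan_index}_p{self.plane_index:02d}"
        )


@dataclass(frozen=True)
class ScanSet:
    """One scan: exactly 12 frames plus their ground-truth chamber masks."""

    images: tuple[ScanImage, ...]
    truth_masks: tuple[BinaryMask, ...]

    def __post_init__(self) -> None:
        if len(self.images) != IMAGES_PER_SCAN:
            raise ValueError(
                f"a scan set holds exactly {IMAGES_PER_SCAN} images, "
                f"got {len(self.images)}"
            )
        if len(self.truth_masks) != IMAGES_PER_SCAN:
            raise ValueError("need one truth mask per image")
        meta = {(im.animal_id, im.ics, im.state, im.scan_index) for im in self.images}
        if len(meta) != 1:
            raise ValueError("all images in a scan set must share metadata")
        object.__setattr__(self, "images", tuple(self.images))
        object.__setattr__(self, "truth_masks", tuple(self.truth_masks))

    @property
    def animal_id(self) -> str:
        return self.images[0].animal_id

    @property
    def state(self) -> State:
        return self.images[0].state

    @property
    def ics(self) -> int:
        return self.images[0].ics

    @property
    def scan_index(self) -> int:
        return self.images[0].scan_index


# ---------------------------------------------------------------------------
# curve construction shared by ground truth and simulated tracers
# ---------------------------------------------------------------------------


def _theta_grid(semiaxes: tuple[float, float]) -> np.ndarray:
    # ~2 vertices per pixel of arc keeps the rasterized chain gap-free
    n = max(256, int(4 * math.pi * max(semiaxes)))
    return np.linspace(0.0, 2 * math.pi, n, endpoint=False)


def _ellipse_radii(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 / np.sqrt((np.cos(theta) / a) ** 2 + (np.sin(theta) / b) ** 2)


def _cut_clots(
    theta: np.ndarray,
    radii: np.ndarray,
    geometry: EllipseGeometry,
) -> np.ndarray:
    """Shorten boundary rays where a clot straddles the chamber wall.

    For each clot disk, rays whose chamber border lies inside the disk are
    cut back to the disk entry point — the device's border dips inward around
    wall-adherent clot.  Clots fully interior along a ray leave it untouched.
    """
    out = radii.copy()
    u_row, u_col = np.sin(theta), np.cos(theta)
    for crow, ccol, rc in geometry.clots:
        q_row = crow - geometry.center[0]
        q_col = ccol - geometry.center[1]
        proj = u_row * q_row + u_col * q_col
        disc = proj**2 - (q_row**2 + q_col**2 - rc**2)
        hit = disc > 0
        root = np.sqrt(np.where(hit, disc, 0.0))
        t_enter = proj - root
        t_exit = proj + root
        cut = hit & (t_enter > 0) & (t_enter < out) & (t_exit > out)
        out = np.where(cut, t_enter, out)
    return out


def _smooth_periodic_jitter(
    rng: np.random.Generator, theta: np.ndarray, sd: float, n_ctrl: int = 24
) -> np.ndarray:
    """Radial jitter ~ Normal(0, sd) at control angles, interpolated.

    Interpolating between control points keeps the traced curve closed and
    smooth, mimicking how a hand or AI tracer deviates coherently rather than
    pixel-by-pixel.
    """
    if sd == 0:
        return np.zeros_like(theta)
    g = rng.normal(0.0, sd, n_ctrl)
    ctrl = np.linspace(0.0, 2 * math.pi, n_ctrl, endpoint=False)
    return np.interp(theta, np.append(ctrl, 2 * math.pi), np.append(g, g[0]))


def _rasterize_curve(
    center: tuple[float, float],
    theta: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    radii = np.maximum(radii, 1.0)
    rows = center[0] + radii * np.sin(theta)
    cols = center[1] + radii * np.cos(theta)
    rr, cc = draw.polygon_perimeter(rows, cols, shape=shape, clip=True)
    return np.stack([rr, cc], axis=1)


def _trace_curve(
    geometry: EllipseGeometry,
    shape: tuple[int, int],
    jitter: np.ndarray | None = None,
    exclude_clots: bool = False,
) -> np.ndarray:
    theta = _theta_grid(geometry.semiaxes)
    radii = _ellipse_radii(theta, *geometry.semiaxes)
    if exclude_clots and geometry.clots:
        radii = _cut_clots(theta, radii, geometry)
    if jitter is not None:
        radii = radii + jitter
    return _rasterize_curve(geometry.center, theta, radii, shape)


# ---------------------------------------------------------------------------
# frame synthesis
# ---------------------------------------------------------------------------


def _phase_scale(config: PhantomConfig, state: State, plane_index: int) -> float:
    if state is not State.PRE_ARREST:
        return 1.0
    phase = 2 * math.pi * (plane_index - 1) / IMAGES_PER_SCAN
    return 1.0 + config.cycle_amplitude * math.sin(phase)


def _truth_geometry(
    config: PhantomConfig, state: State, plane_index: int
) -> EllipseGeometry:
    s = _phase_scale(config, state, plane_index)
    a, b = config.semiaxes
    return EllipseGeometry(center=config.center, semiaxes=(s * a, s * b))


def _make_clots(
    config: PhantomConfig,
    geometry: EllipseGeometry,
    truth: np.ndarray,
    rng: np.random.Generator,
) -> tuple[tuple[float, float, float], ...]:
    """Place clot disks covering ≈ clot_fraction of the chamber interior.

    Centers are drawn uniformly from a slightly shrunken chamber ellipse (so
    some clots straddle the wall); a shared radius is calibrated in a few
    fixed-point steps against the measured in-chamber coverage, which
    absorbs disk overlap and the part of each disk falling outside the
    chamber.
    """
    if config.clot_count == 0 or config.clot_fraction == 0:
        return ()
    target = config.clot_fraction * truth.sum()
    (crow, ccol), (a, b) = geometry.center, geometry.semiaxes
    # uniform sample in the 0.92-scaled ellipse via the unit-disk sqrt trick;
    # the slight wall-ward bias makes wall-adherent clot (the undertracing
    # trigger) common, as thrombus forms along the dependent chamber wall
    phi = rng.uniform(0, 2 * math.pi, config.clot_count)
    rad = np.sqrt(rng.uniform(0, 1, config.clot_count))
    rows = crow + 0.92 * b * rad * np.sin(phi)
    cols = ccol + 0.92 * a * rad * np.cos(phi)
    radius = math.sqrt(target / (config.clot_count * math.pi))
    for _ in range(4):
        cov = _clot_raster(rows, cols, radius, truth.shape) & truth
        measured = cov.sum()
        if measured == 0:
            radius *= 1.5
            continue
        factor = math.sqrt(target / measured)
        if abs(factor - 1.0) < 0.02:
            break
        radius *= factor
    return tuple(
        (float(r), float(c), float(radius)) for r, c in zip(rows, cols)
    )


def _clot_raster(
    rows: np.ndarray, cols: np.ndarray, radius: float, shape: tuple[int, int]
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for r, c in zip(rows, cols):
        rr, cc = draw.disk((r, c), radius, shape=shape)
        out[rr, cc] = True
    return out


def _rib_flag(
    config: PhantomConfig,
    seed: int,
    animal_id: str,
    state: State,
    ics: int,
    scan_index: int,
    plane_index: int,
) -> bool:
    rng = substream(seed, animal_id, state.value, ics, scan_index, plane_index, "rib")
    return bool(rng.uniform() < config.rib_shadow_probability)


def _render_frame(
    config: PhantomConfig,
    truth: np.ndarray,
    clot_mask: np.ndarray | None,
    rib_flag: bool,
    rng_rib: np.random.Generator,
    rng_speckle: np.random.Generator,
) -> np.ndarray:
    h, w = config.shape
    mean = np.full((h, w), _BACKGROUND_MEAN)
    mean[truth] = _CHAMBER_MEAN
    if clot_mask is not None:
        mean[clot_mask & truth] = _CLOT_MEAN
    if rib_flag:
        band_w = max(1, int(round(_RIB_SHADOW_WIDTH_FRAC * w)))
        center_col = config.center[1] + rng_rib.uniform(-0.1, 0.1) * w
        c0 = int(round(center_col - band_w / 2))
        mean[:, max(c0, 0): max(c0, 0) + band_w] = _RIB_SHADOW_MEAN
    noise = rng_speckle.normal(1.0, config.speckle_noise_sd / _BACKGROUND_MEAN, (h, w))
    img = np.clip(mean * noise, 0, 255).astype(np.uint8)
    img[~config.sector.mask()] = 0
    return img


def generate_frame(
    config: PhantomConfig,
    animal_id: str,
    ics: int,
    state: "State | str",
    scan_index: int,
    plane_index: int,
    seed: int | None = None,
) -> tuple[ScanImage, BinaryMask]:
    """Generate a single frame plus its ground-truth mask.

    Frames are pure functions of (config, identifiers, seed): the frame
    produced here is bit-identical to the same plane inside
    :func:`generate_scan_set`.
    """
    state = _coerce_state(state)
    if not ICS_RANGE[0] <= ics <= ICS_RANGE[1]:
        raise ValueError(f"ics must be in {ICS_RANGE[0]}..{ICS_RANGE[1]}, got {ics}")
    if not 1 <= plane_index <= IMAGES_PER_SCAN:
        raise ValueError(
            f"plane_index must be in 1..{IMAGES_PER_SCAN}, got {plane_index}"
        )
    if seed is None:
        seed = config.seed
    shape = config.shape
    sector = config.sector
    ids = (animal_id, state.value, ics, scan_index, plane_index)
    geom = _truth_geometry(config, state, plane_index)
    curve = _trace_curve(geom, shape)
    truth = fill_tracing(
        TracingOverlay(curve, source="truth"), shape, sector=sector
    ).grid
    clot_mask = None
    if state is State.LATE_ARREST:
        rng_cl = substream(seed, *ids, "clots")
        clots = _make_clots(config, geom, truth, rng_cl)
        geom = replace(geom, clots=clots)
        if clots:
            clot_mask = _clot_raster(
                np.array([c[0] for c in clots]),
                np.array([c[1] for c in clots]),
                clots[0][2],
                shape,
            )
    flag = _rib_flag(config, seed, animal_id, state, ics, scan_index, plane_index)
    rng_rib = substream(seed, *ids, "ribpos")
    rng_sp = substream(seed, *ids, "speckle")
    pixels = _render_frame(config, truth, clot_mask, flag, rng_rib, rng_sp)
    image = ScanImage(
        pixels=pixels,
        animal_id=animal_id,
        ics=ics,
        state=state,
        scan_index=scan_index,
        plane_index=plane_index,
        rib_shadow_flag=flag,
        geometry=geom,
    )
    return image, BinaryMask(truth, image_ref=image.image_id)


def generate_scan_set(
    config: PhantomConfig,
    animal_id: str,
    ics: int,
    state: "State | str",
    scan_index: int = 1,
    seed: int | None = None,
) -> ScanSet:
    """Generate one seeded scan: 12 frames plus 12 ground-truth masks.

    Raises
    ------
    ValueError
        If ``ics`` is outside 4..8 or ``state`` is not a valid enum value.
    """
    images, truths = [], []
    for plane in range(1, IMAGES_PER_SCAN + 1):
        image, truth = generate_frame(
            config, animal_id, ics, state, scan_index, plane, seed
        )
        images.append(image)
        truths.append(truth)
    return ScanSet(images=tuple(images), truth_masks=tuple(truths))


# ---------------------------------------------------------------------------
# simulated tracers
# ---------------------------------------------------------------------------


def _radii_from_mask(truth: np.ndarray) -> EllipseGeometry:
    """Fallback analytic geometry when a frame carries no stored geometry."""
    rows, cols = np.nonzero(truth)
    center = (float(rows.mean()), float(cols.mean()))
    a = (cols.max() - cols.min() + 1) / 2.0
    b = (rows.max() - rows.min() + 1) / 2.0
    return EllipseGeometry(center=center, semiaxes=(a, b))


def _tracing(
    image: ScanImage,
    truth: BinaryMask | np.ndarray,
    sd: float,
    rng: np.random.Generator,
    exclude_clots: bool,
    source: str,
    color: tuple[int, int, int],
) -> TracingOverlay:
    grid = truth.grid if isinstance(truth, BinaryMask) else np.asarray(truth, bool)
    if not grid.any():
        raise ValueError("truth mask is empty; nothing to trace")
    geom = image.geometry or _radii_from_mask(grid)
    theta = _theta_grid(geom.semiaxes)
    jitter = _smooth_periodic_jitter(rng, theta, sd)
    pixels = _trace_curve(geom, grid.shape, jitter=jitter, exclude_clots=exclude_clots)
    return TracingOverlay(
        pixels, source=source, image_ref=image.image_id, color=color
    )


def simulate_device_tracing(
    image: ScanImage,
    truth: BinaryMask | np.ndarray,
    config: PhantomConfig,
    seed: int | None = None,
) -> TracingOverlay:
    """Simulate the automated scanner's border tracing for one frame.

    The curve follows the chamber boundary with smooth radial jitter of
    state-dependent magnitude ``tracer_jitter_sd[state]``; in late arrest it
    additionally cuts inside clots straddling the chamber wall
    (undertracing).
    """
    if seed is None:
        seed = config.seed
    sd = config.tracer_jitter_sd[image.state.value]
    rng = substream(seed, "device", image.image_id)
    return _tracing(
        image,
        truth,
        sd,
        rng,
        exclude_clots=image.state is State.LATE_ARREST,
        source="device",
        color=DEVICE_COLOR,
    )


def simulate_reviewer_tracing(
    image: ScanImage,
    truth: BinaryMask | np.ndarray,
    reviewer_id: str,
    config: PhantomConfig,
    seed: int | None = None,
) -> TracingOverlay:
    """Simulate an expert reviewer's free-trace of the chamber border.

    Reviewers trace the full chamber outline — clot included — with radial
    jitter ``reviewer_jitter_sd[reviewer_id]``.  Each reviewer draws from an
    independent substream, so two reviewers given the same seed produce
    different tracings.
    """
    if reviewer_id not in config.reviewer_jitter_sd:
        raise ValueError(
            f"unknown reviewer_id {reviewer_id!r}; configured reviewers: "
            f"{sorted(config.reviewer_jitter_sd)}"
        )
    if seed is None:
        seed = config.seed
    rng = substream(seed, "reviewer", reviewer_id, image.image_id)
    return _tracing(
        image,
        truth,
        config.reviewer_jitter_sd[reviewer_id],
        rng,
        exclude_clots=False,
        source=f"reviewer:{reviewer_id}",
        color=REVIEWER_COLOR,
    )


# ---------------------------------------------------------------------------
# study-scale batch generation
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "animal_id",
    "ics",
    "state",
    "scan_index",
    "plane_index",
    "rib_shadow_flag",
    "image_path",
    "truth_path",
]


def _animal_ids(n_animals: int) -> list[str]:
    return [f"A{i:02d}" for i in range(1, n_animals + 1)]


def _image_relpath(image_id: str, kind: str) -> str:
    return f"{kind}/{image_id}.png"


def plan_study(
    config: PhantomConfig,
    n_animals: int,
    states: Sequence["State | str"] | None = None,
    seed: int | None = None,
    scans_per_ics: int = 1,
) -> pd.DataFrame:
    """Manifest of a full study without rendering any pixels.

    Rib-shadow flags are drawn from the same substreams the renderer uses,
    so the plan matches a later materialization image for image.
    """
    if n_animals < 1:
        raise ValueError(f"n_animals must be >= 1, got {n_animals}")
    if states is None:
        states = list(State)
    if not states:
        raise ValueError("states list must not be empty")
    states = [_coerce_state(s) for s in states]
    if seed is None:
        seed = config.seed
    rows = []
    for animal in _animal_ids(n_animals):
        for state in states:
            for ics in range(ICS_RANGE[0], ICS_RANGE[1] + 1):
                for scan in range(1, scans_per_ics + 1):
                    for plane in range(1, IMAGES_PER_SCAN + 1):
                        flag = _rib_flag(config, seed, animal, state, ics, scan, plane)
                        image_id = (
                            f"{animal}_{state.value}_ics{ics}_scan{scan}_p{plane:02d}"
                        )
                        rows.append(
                            {
                                "animal_id": animal,
                                "ics": ics,
                                "state": state.value,
                                "scan_index": scan,
                                "plane_index": plane,
                                "rib_shadow_flag": flag,
                                "image_path": _image_relpath(image_id, "images"),
                                "truth_path": _image_relpath(image_id, "truth"),
                            }
                        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def plan_acquisition(
    n_scan_sets: int,
    n_animals: int = 7,
    states: Sequence["State | str"] | None = None,
) -> pd.DataFrame:
    """Image-level manifest for an arbitrary number of scan sets.

    Scan-set slots cycle over (animal, ICS, state) with increasing scan
    index, mirroring repeated scanning of the same spaces; each set
    contributes exactly 12 image rows.  Useful for acquisition arithmetic
    and for building screening pools of a prescribed size.
    """
    if n_scan_sets < 1:
        raise ValueError(f"n_scan_sets must be >= 1, got {n_scan_sets}")
    if states is None:
        states = list(State)
    if not states:
        raise ValueError("states list must not be empty")
    states = [_coerce_state(s) for s in states]
    slots = [
        (animal, ics, state)
        for animal in _animal_ids(n_animals)
        for ics in range(ICS_RANGE[0], ICS_RANGE[1] + 1)
        for state in states
    ]
    rows = []
    scan_counts: dict[tuple, int] = {}
    for k in range(n_scan_sets):
        animal, ics, state = slots[k % len(slots)]
        scan = scan_counts.get((animal, ics, state), 0) + 1
        scan_counts[(animal, ics, state)] = scan
        for plane in range(1, IMAGES_PER_SCAN + 1):
            image_id = f"{animal}_{state.value}_ics{ics}_scan{scan}_p{plane:02d}"
            rows.append(
                {
                    "animal_id": animal,
                    "ics": ics,
                    "state": state.value,
                    "scan_index": scan,
                    "plane_index": plane,
                    "rib_shadow_flag": False,
                    "image_path": _image_relpath(image_id, "images"),
                    "truth_path": _image_relpath(image_id, "truth"),
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def simulate_eligibility(n_animals: int, seed: int):
    """Synthetic per-(animal, ICS) anatomy labels.

    Mirrors the anatomical survey narrowing analysis to 2–3 intercostal
    spaces per animal where the LV or LVOT was visualized; the remaining
    spaces show only the aortic root or apex.
    """
    from .study import EligibilityLabel  # local import avoids a cycle

    labels = []
    for animal in _animal_ids(n_animals):
        rng = substream(seed, "eligibility", animal)
        width = int(rng.integers(2, 4))  # 2 or 3 contiguous spaces
        lo = ICS_RANGE[0]
        hi = ICS_RANGE[1] - width + 1
        start = int(rng.integers(lo + 1, hi + 1))  # biased away from ICS 4
        lv_spaces = set(range(start, start + width))
        for ics in range(ICS_RANGE[0], ICS_RANGE[1] + 1):
            if ics in lv_spaces:
                seen = {"lv", "lvot"} if rng.uniform() < 0.5 else {"lv"}
            else:
                seen = {"aortic_root"} if ics < start else {"apex"}
            labels.append(EligibilityLabel(animal_id=animal, ics=ics, visualized=seen))
    return labels


@dataclass
class StudyData:
    """Batch-generation result: scan sets plus their image-level manifest."""

    scan_sets: list[ScanSet]
    manifest: pd.DataFrame


def generate_study(
    config: PhantomConfig,
    n_animals: int,
    states: Sequence["State | str"] | None = None,
    seed: int | None = None,
    scans_per_ics: int = 1,
    outdir=None,
    keep_pixels: bool = True,
) -> StudyData:
    """Generate every scan set of a study: one per (animal, state, ICS, scan).

    With ``outdir`` set, frames are written as 8-bit grayscale PNG and truth
    masks as 1-bit PNG under ``images/`` and ``truth/``, and the manifest
    records the written paths.  ``keep_pixels=False`` drops pixel data after
    writing (for full-size rasters).
    """
    if n_animals < 1:
        raise ValueError(f"n_animals must be >= 1, got {n_animals}")
    if states is None:
        states = list(State)
    if not states:
        raise ValueError("states list must not be empty")
    states = [_coerce_state(s) for s in states]
    if seed is None:
        seed = config.seed
    if outdir is not None:
        from pathlib import Path

        from .imgio import write_raster

        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)

    scan_sets: list[ScanSet] = []
    rows = []
    for animal in _animal_ids(n_animals):
        for state in states:
            for ics in range(ICS_RANGE[0], ICS_RANGE[1] + 1):
                for scan in range(1, scans_per_ics + 1):
                    sset = generate_scan_set(config, animal, ics, state, scan, seed)
                    for image, truth in zip(sset.images, sset.truth_masks):
                        image_path = _image_relpath(image.image_id, "images")
                        truth_path = _image_relpath(image.image_id, "truth")
                        if outdir is not None:
                            write_raster(image.pixels, outdir / image_path)
                            write_raster(truth.grid, outdir / truth_path)
                            image_path = str(outdir / image_path)
                            truth_path = str(outdir / truth_path)
                        rows.append(
                            {
                                "animal_id": animal,
                                "ics": ics,
                                "state": state.value,
                                "scan_index": scan,
                                "plane_index": image.plane_index,
                                "rib_shadow_flag": image.rib_shadow_flag,
                                "image_path": image_path,
                                "truth_path": truth_path,
                            }
                        )
                    if keep_pixels:
                        scan_sets.append(sset)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return StudyData(scan_sets=scan_sets, manifest=manifest)
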