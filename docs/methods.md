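# Methods

This note documents the models, conventions and numerical choices behind
`sonodice`: what the synthetic scan generator emulates, how tracings become
masks, how concordance is scored and aggregated, and where the design was
genuinely open.

## Phantom acquisition model

One *scan* is 12 B-mode-like frames (6 orthogonal biplane pairs) recorded at
one intercostal space (ICS 4–8) of one animal in one physiologic state. The
heart chamber is a dark (hypoechoic) axis-aligned ellipse on a bright
speckled background inside a fan-shaped sector; everything outside the
sector is held at the reserved background value 0 and excluded from all
pixel statistics.

**Raster.** Default 1616×1216 (≈1.97 M pixels, matching the device's frame
size); studies, tests and the acceptance script use 128×96 rasters via
`RunConfig.study_scale()` so that replicated full-pipeline experiments run
in seconds. The error model is identical at both scales; only absolute
pixel counts change. Coordinates are row-major, 0-based, origin top-left,
shared by images, masks and overlays everywhere.

**Sector.** A circular sector with apex at the top-center of the raster,
opening downward with a 120° aperture and the largest inscribed radius
(`SectorGeometry`). The pixel census of the sector agrees with
aperture/360·πR² to well under 1%.

**Appearance.** Background speckle has mean 160 with multiplicative
Gaussian noise (`speckle_noise_sd`, default 20, in intensity units at the
background mean); the chamber mean is 40; clot blobs are 150; a rib shadow
is a vertical band of width 15% of the image at mean 20 crossing the heart
column. Intensities are a visual-plausibility choice — no physical wave
simulation (point-spread functions, attenuation) is attempted, so absolute
gray levels carry no quantitative meaning beyond thresholdability.

**States.**

* *pre_arrest* — chamber semiaxes scale per frame by
  `1 + cycle_amplitude·sin(2πk/12)` (k = 0…11), emulating frames caught at
  different phases of the cardiac cycle; the device tracer jitter is
  largest but one (default SD 3 px).
* *arrest* — fixed chamber, smallest tracer jitter (default 1 px).
* *late_arrest* — fixed chamber plus `clot_count` echogenic disks covering
  `clot_fraction` (default 0.30) of the chamber interior, and the largest
  tracer jitter (default 4 px).

The per-state tracer jitter defaults (3/1/4 px) together with clot
undertracing make expected device–reviewer disagreement order
arrest < pre-arrest < late arrest by construction. Why a beating heart
degrades an automated tracer is encoded here as *per-frame scale variation
plus larger jitter*; that is a modeling choice of this package, not an
observed mechanism.

**Clots.** `clot_count` disks share one radius calibrated by a short
fixed-point iteration against the measured in-chamber coverage (absorbing
disk overlap and spill-over outside the chamber), so the echogenic fraction
inside the truth mask tracks `clot_fraction` within ±0.05. Centers are
drawn uniformly from the 0.92-scaled chamber ellipse; the slight wall-ward
bias makes wall-adherent clot — the undertracing trigger — common, as
thrombus forms along the chamber wall.

**Tracers.** Both simulated tracers perturb the analytic chamber boundary
radially: smooth periodic noise (Normal(0, sd) at 24 control angles,
linearly interpolated) keeps the curve closed and coherent, as a hand or AI
tracer errs over stretches of border rather than per pixel. The device
tracer in late arrest additionally cuts each boundary ray back to the entry
point of any clot disk that straddles the chamber wall along that ray
(undertracing); simulated reviewers always trace the full chamber outline,
clot included. With zero jitter and no clot, a tracer's filled overlay
equals the ground-truth mask exactly, because the truth mask itself is
produced by filling the same rasterized boundary curve.

**Randomness.** One master seed; every entity draws from a substream keyed
by hashing its identifier tuple (animal, state, ICS, scan, plane, role), so
outputs are pure functions of (config, identifiers, seed) and regenerating
any single frame in isolation is bit-identical to generating it inside a
full study. This is what lets the study pipeline screen on a pixel-free
manifest and materialize only the retained frames.

**Rib shadows** occur independently per frame with
`rib_shadow_probability` (default 0.05) and set a flag in the manifest; the
flag, not the pixels, drives screening exclusion in synthetic mode (a flag
file supplies human decisions for real images).

## From tracing to mask

`fill_tracing` converts an overlay curve to a filled mask: the curve is a
barrier for a 4-connected flood fill started from every raster border
pixel; the mask is the complement of the flooded exterior — interior plus
the curve itself — cropped to the sector. Curve pixels count as inside;
whether the original analysis software included them is unknowable from
the outside, and including them keeps agreement symmetric between raters.

Rasterized tracings occasionally carry 1–2 px discontinuities. Gap closure
escalates: the raw curve is tried first; if nothing is enclosed, the curve
is thickened by cross-dilation of radius 1, then 2 (the configurable
`closing_radius`). Thickening pixels are kept only where 4-adjacent to the
recovered interior, so bridging pixels at genuine gaps survive while the
rest of the band is trimmed — and a curve that was already watertight fills
*exactly*, which is what makes the boundary-extraction → fill round-trip an
identity on simply-connected masks (a property the test suite checks on
randomized blobs). Plain morphological closing was rejected for this job:
on 1-px curves the erosion step undoes the dilation and diagonal gaps stay
open, while at corners it can add pixels that break round-trip exactness.

If the curve genuinely encloses several regions (self-intersection), only
the largest is kept and a warning is logged; single-pixel pockets produced
by stair-step rasterization are treated as part of the boundary band, not
as extra regions. A curve that encloses nothing at any radius raises an
"open contour" error naming the radius used.

`obscure_tracing` replaces each curve pixel with the per-channel median of
the non-curve pixels in its 5×5 neighborhood (clipped at borders), then
nudges any residual exact color match by one intensity step; the obscured
image therefore never contains the overlay color at tolerance 0, the
operation is idempotent, and non-curve pixels are untouched. Obscuring here
is exact by construction — the residual-visibility risk of manual obscuring
in image editors is not modeled.

## Concordance scoring

`confusion_areas` counts TP/TN/FP/FN over sector pixels only, with the
reviewer mask as reference and the device mask as test; TN and the area
percentages use the sector as denominator because out-of-sector pixels
carry no signal (the full-rectangle alternative changes TN/percentages but
not the SDI; the sector geometry is an explicit argument throughout).
Percentages are rounded half-away-from-zero to 3 decimals and sum to
100.000 ± 0.002.

`sdi` implements 2·TP/(2·TP + FP + FN). Two empty masks raise an
"undefined SDI" error rather than returning a convention value: a silent 0
or 1 would hide an upstream fill failure. The index is symmetric under
swapping the masks (FP↔FN), equals the set formula 2|A∩B|/(|A|+|B|), and
never increases when an agreeing pixel is flipped to disagreement — all
verified against independent oracles in the suite.

`render_agreement` colors TP yellow, TN white, FP red, FN green, outside
black; per-color pixel censuses equal the confusion counts exactly.

## Study workflow

*Eligibility*: analysis is narrowed to (animal, ICS) pairs whose anatomical
survey visualized the LV or LVOT. The synthetic survey marks 2–3 contiguous
spaces per animal, mirroring the 2–3 eligible spaces per animal typical of
a porcine chest.

*Screening*: stratified draws without replacement per state, in seeded
random order over a canonically sorted pool (so results are independent of
manifest row order); rib-flagged draws are excluded and logged; the walk
stops when every state reaches `quota_per_state`, and a state whose pool is
exhausted first raises an error naming it. Stratification is required to
guarantee exact per-state quotas; the random mechanism is uniform without
replacement. `make_screening_pool` packages the study-sized case: an
828-image eligible pool (69 scan sets balanced over the three states) with
10 rib-shadowed frames planted among each state's early draws — never at a
position that would let a quota complete early — so screening at quota
50/state walks exactly 160 frames: 150 retained, 10 excluded.

*Blinding*: retained rows are shuffled (seeded Fisher–Yates via
`Generator.permutation`) and opaque zero-padded sequential codes are
assigned *after* shuffling, so code order leaks nothing. The reviewer
packet references images only as `blinded/<code>.png`; original paths,
which encode animal/state/ICS, live exclusively in the blinding key (the
CLI copies images under their codes when materialized). String-scanning the
packet for state tokens is part of the acceptance suite.

*Scoring and aggregation*: one record per (image, reviewer), reviewer as
reference. Cells report mean and sample SD (n−1 denominator — the
convention for summary tables; with n = 1 the SD is reported as 0). The
pooled row per state is the unweighted mean of the reviewer means, with SD
over all (image, reviewer) pairs; the all-pairs mean is reported alongside
for transparency. A (reviewer, state) cell with no records is an error.

## Replicated-study experiments

`ordering_experiment` runs the full pipeline at consecutive master seeds
(default 20 replicates, quota 20/state, 128×96 rasters, the default error
model) and reports the fraction of replicates whose pooled means order
arrest > pre-arrest > late arrest. `jitter_recovery_experiment` triples one
simulated reviewer's jitter and reports how often that reviewer's overall
mean SDI falls strictly below every other reviewer's (default 10
replicates, quota 15/state).

## What passing tests do and do not show

The generator reproduces the *structure* of the analysis — state-dependent
error modes, acquisition failures, blinded stratified screening, the
aggregation contract — not real ultrasound physics: no speckle correlation,
no probe-angle or depth-gain effects, elliptical chambers rather than true
cardiac cross-sections, and an idealized device tracer whose failure modes
are exactly the two modeled ones. Passing the ordering test shows the
pipeline detects the error structure the simulator encodes; it is not
evidence about any physical device. Absolute SDI levels depend on the
jitter/clot defaults and the raster scale and are not comparable to values
measured on real images.

## Known limitations

* The two late-arrest animals' timing (clot growth over minutes) is not
  modeled; clot burden is stationary per state.
* Orthogonal biplane pairs share the same chamber geometry; plane pairing
  is metadata only.
* Unbalanced animal×state availability (e.g. animals lost to ROSC) is
  representable in manifests but the batch generator produces balanced
  designs.
* `obscure_tracing` loops per curve pixel in Python; at full raster scale
  with long curves it is the slowest primitive (~10⁴ pixels per tracing).
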