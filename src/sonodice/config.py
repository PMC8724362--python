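"""Run configuration: YAML-backed parameters for an end-to-end study."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .phantom import PhantomConfig, State

__all__ = ["ReviewerProfile", "RunConfig", "validate_config", "load_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReviewerProfile:
    """One simulated reviewer: identifier and radial tracing jitter (px)."""

    id: str
    jitter_sd: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reviewer id must be non-empty")
        if self.jitter_sd < 0:
            raise ValueError(
                f"reviewer {self.id!r}: jitter_sd must be >= 0, got {self.jitter_sd}"
            )


_DEFAULT_REVIEWERS = (
    ReviewerProfile("R1", 1.2),
    ReviewerProfile("R2", 1.5),
    ReviewerProfile("R3", 1.8),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a study run bit-identically."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    quota_per_state: int = 50
    reviewers: tuple[ReviewerProfile, ...] = _DEFAULT_REVIEWERS
    n_animals: int = 7
    states: tuple[str, ...] = tuple(s.value for s in State)
    scans_per_ics: int = 1
    output_dir: str | None = None
    master_seed: int = 0
    render_sample_size: int = 4

    def __post_init__(self) -> None:
        if self.quota_per_state < 1:
            raise ValueError(
                f"quota_per_state must be >= 1, got {self.quota_per_state}"
            )
        if not self.reviewers:
            raise ValueError("at least one reviewer is required")
        ids = [r.id for r in self.reviewers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate reviewer ids: {ids}")
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals}")
        if not self.states:
            raise ValueError("states must not be empty")
        for s in self.states:
            State(s)  # raises on invalid value
        if self.scans_per_ics < 1:
            raise ValueError(f"scans_per_ics must be >= 1, got {self.scans_per_ics}")
        if self.master_seed < 0:
            raise ValueError(f"master_seed must be >= 0, got {self.master_seed}")
        if self.render_sample_size < 0:
            raise ValueError(
                f"render_sample_size must be >= 0, got {self.render_sample_size}"
            )
        object.__setattr__(self, "reviewers", tuple(self.reviewers))
        object.__setattr__(self, "states", tuple(self.states))

    def phantom_config(self) -> PhantomConfig:
        """Phantom config with the reviewer jitter map from the profiles."""
        return replace(
            self.phantom,
            reviewer_jitter_sd={r.id: r.jitter_sd for r in self.reviewers},
            seed=self.master_seed,
        )

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, master_seed=seed)

    def with_boosted_reviewer(self, reviewer_id: str, factor: float) -> "RunConfig":
        if reviewer_id not in {r.id for r in self.reviewers}:
            raise ValueError(f"unknown reviewer {reviewer_id!r}")
        boosted = tuple(
            replace(r, jitter_sd=r.jitter_sd * factor) if r.id == reviewer_id else r
            for r in self.reviewers
        )
        return replace(self, reviewers=boosted)

    @classmethod
    def study_scale(cls, quota_per_state: int = 20, **kwargs) -> "RunConfig":
        """Desk-scale study defaults: 128×96 rasters, full error model.

        The default error model (state-dependent tracer jitter, clot
        undertracing) is unchanged; only the raster is scaled down so that
        replicated studies run in seconds.
        """
        phantom = kwargs.pop(
            "phantom", PhantomConfig(image_width=128, image_height=96)
        )
        return cls(phantom=phantom, quota_per_state=quota_per_state, **kwargs)

    def to_dict(self) -> dict:
        doc = {
            "phantom": _phantom_to_dict(self.phantom),
            "quota_per_state": self.quota_per_state,
            "reviewers": [
                {"id": r.id, "jitter_sd": r.jitter_sd} for r in self.reviewers
            ],
            "n_animals": self.n_animals,
            "states": list(self.states),
            "scans_per_ics": self.scans_per_ics,
            "output_dir": self.output_dir,
            "master_seed": self.master_seed,
            "render_sample_size": self.render_sample_size,
        }
        return doc

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _phantom_to_dict(cfg: PhantomConfig) -> dict:
    return {
        "image_width": cfg.image_width,
        "image_height": cfg.image_height,
        "heart_center": list(cfg.heart_center) if cfg.heart_center else None,
        "heart_semiaxes": list(cfg.heart_semiaxes) if cfg.heart_semiaxes else None,
        "cycle_amplitude": cfg.cycle_amplitude,
        "clot_fraction": cfg.clot_fraction,
        "clot_count": cfg.clot_count,
        "speckle_noise_sd": cfg.speckle_noise_sd,
        "rib_shadow_probability": cfg.rib_shadow_probability,
        "tracer_jitter_sd": dict(cfg.tracer_jitter_sd),
        "reviewer_jitter_sd": dict(cfg.reviewer_jitter_sd),
        "seed": cfg.seed,
    }


_PHANTOM_FIELDS = {f.name for f in dataclasses.fields(PhantomConfig)}
_RUN_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(document: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML document.

    Unknown keys are rejected (typo guard); omitted optional fields receive
    the documented defaults; every invariant violation is reported with its
    field name.  The effective configuration is echoed to the log.
    """
    if document is None:
        document = {}
    if not isinstance(document, dict):
        raise ValueError(f"config document must be a mapping, got {type(document)}")
    doc = dict(document)
    unknown = set(doc) - _RUN_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "phantom" in doc:
        pdoc = doc.pop("phantom") or {}
        if not isinstance(pdoc, dict):
            raise ValueError("phantom: must be a mapping")
        bad = set(pdoc) - _PHANTOM_FIELDS
        if bad:
            raise ValueError(f"unknown phantom keys: {sorted(bad)}")
        for key in ("heart_center", "heart_semiaxes"):
            if pdoc.get(key) is not None:
                pdoc[key] = tuple(pdoc[key])
        kwargs["phantom"] = PhantomConfig(**pdoc)
    if "reviewers" in doc:
        rdoc = doc.pop("reviewers")
        if not isinstance(rdoc, list):
            raise ValueError("reviewers: must be a list of {id, jitter_sd}")
        profiles = []
        for item in rdoc:
            bad = set(item) - {"id", "jitter_sd"}
            if bad:
                raise ValueError(f"unknown reviewer keys: {sorted(bad)}")
            profiles.append(ReviewerProfile(**item))
        kwargs["reviewers"] = tuple(profiles)
    if "states" in doc:
        kwargs["states"] = tuple(doc.pop("states"))
    kwargs.update({k: v for k, v in doc.items() if v is not None or k == "output_dir"})
    cfg = RunConfig(**kwargs)
    logger.info("effective configuration:\n%s", cfg.to_yaml())
    return cfg


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration file."""
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))
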