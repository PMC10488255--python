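"""Experiment configuration: parsing, defaulting and validation.

A config file (YAML or JSON — YAML is a superset) describes a full in-silico
experiment: the imaging setup, a base cell population, named conditions with
per-condition overrides of the depolarized fraction, the number of
biological replicates and images, which condition anchors the depolarization
threshold, and the statistics options.  Validation collects *all* problems
and reports them together with field paths.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml

from .imgseg import SegmentationParams
from .synthgen import ImagingSpec, PopulationSpec

__all__ = ["ExperimentConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised with a combined list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


_POPULATION_FIELDS = {
    "n_cells",
    "frac_depolarized",
    "mu_pol",
    "sigma_pol",
    "mu_depol",
    "sigma_depol",
    "replicate_sd",
    "n_debris_small",
    "n_debris_large",
}
_IMAGING_FIELDS = {
    "width_px",
    "height_px",
    "background_bf",
    "background_fl",
    "read_noise_sd",
    "psf_sigma_px",
    "bit_depth",
}
_SEGMENTATION_FIELDS = {"threshold_method", "min_area_px", "max_area_px", "connectivity"}
_TOP_LEVEL_KEYS = {
    "conditions",
    "control",
    "replicates",
    "images_per_replicate",
    "population",
    "imaging",
    "segmentation",
    "histogram_bin_width",
    "working_correlation",
    "seed",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """A fully validated experiment description."""

    conditions: dict[str, PopulationSpec]
    control: str
    replicates: int = 3
    images_per_replicate: int = 1
    imaging: ImagingSpec = field(default_factory=ImagingSpec)
    segmentation: SegmentationParams | None = None  # None -> derived from geometry
    histogram_bin_width: float = 1.0
    working_correlation: str = "exchangeable"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.conditions:
            raise ConfigError(
                [f"control: condition {self.control!r} is not among conditions "
                 f"{sorted(self.conditions)}"]
            )
        if self.replicates < 1:
            raise ConfigError(["replicates: must be >= 1"])

    def segmentation_params(self) -> SegmentationParams:
        """Explicit params, or size bounds derived from the control geometry."""
        if self.segmentation is not None:
            return self.segmentation
        spec = self.conditions[self.control]
        return SegmentationParams.from_median_cell_area(spec.median_cell_area())

    def content_hash(self) -> str:
        payload = {
            "conditions": {k: asdict(v) for k, v in sorted(self.conditions.items())},
            "control": self.control,
            "replicates": self.replicates,
            "images_per_replicate": self.images_per_replicate,
            "imaging": asdict(self.imaging),
            "segmentation": None if self.segmentation is None else asdict(self.segmentation),
            "histogram_bin_width": self.histogram_bin_width,
            "working_correlation": self.working_correlation,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_dataclass(cls, raw: dict, allowed: set[str], path: str, problems: list[str]):
    unknown = set(raw) - allowed
    for key in sorted(unknown):
        problems.append(f"{path}.{key}: unknown key")
    kwargs = {k: v for k, v in raw.items() if k in allowed}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"{path}: {exc}")
        return None


def validate_config(raw: dict) -> ExperimentConfig:
    """Turn a parsed mapping into a validated :class:`ExperimentConfig`.

    All problems are collected and raised together as :class:`ConfigError`.
    """
    if not isinstance(raw, dict):
        raise ConfigError(["top level: expected a mapping"])
    problems: list[str] = []
    for key in sorted(set(raw) - _TOP_LEVEL_KEYS):
        problems.append(f"{key}: unknown key")

    base_raw = raw.get("population", {}) or {}
    base = _build_dataclass(
        PopulationSpec, base_raw, _POPULATION_FIELDS, "population", problems
    )
    imaging = _build_dataclass(
        ImagingSpec, raw.get("imaging", {}) or {}, _IMAGING_FIELDS, "imaging", problems
    )
    seg_raw = raw.get("segmentation")
    segmentation = None
    if seg_raw:
        segmentation = _build_dataclass(
            SegmentationParams, seg_raw, _SEGMENTATION_FIELDS, "segmentation", problems
        )

    conditions: dict[str, PopulationSpec] = {}
    cond_raw = raw.get("conditions")
    if not cond_raw or not isinstance(cond_raw, dict):
        problems.append("conditions: must be a non-empty mapping of condition name -> overrides")
    elif base is not None:
        for name, overrides in cond_raw.items():
            overrides = overrides or {}
            unknown = set(overrides) - _POPULATION_FIELDS
            for key in sorted(unknown):
                problems.append(f"conditions.{name}.{key}: unknown key")
            try:
                conditions[str(name)] = replace(
                    base, **{k: v for k, v in overrides.items() if k in _POPULATION_FIELDS}
                )
            except ValueError as exc:
                problems.append(f"conditions.{name}: {exc}")

    control = raw.get("control")
    if control is None:
        problems.append("control: required (name of the threshold-defining condition)")
    elif conditions and str(control) not in conditions:
        problems.append(
            f"control: {control!r} not among conditions {sorted(conditions)}"
        )

    replicates = raw.get("replicates", 3)
    if not isinstance(replicates, int) or replicates < 1:
        problems.append("replicates: must be an integer >= 1")
    images = raw.get("images_per_replicate", 1)
    if not isinstance(images, int) or images < 1:
        problems.append("images_per_replicate: must be an integer >= 1")
    bin_width = raw.get("histogram_bin_width", 1.0)
    if not isinstance(bin_width, (int, float)) or bin_width <= 0:
        problems.append("histogram_bin_width: must be a positive number")
    corr = raw.get("working_correlation", "exchangeable")
    if corr not in ("independence", "exchangeable"):
        problems.append(
            "working_correlation: must be 'independence' or 'exchangeable'"
        )
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed: must be an integer")

    if problems:
        raise ConfigError(problems)
    return ExperimentConfig(
        conditions=conditions,
        control=str(control),
        replicates=replicates,
        images_per_replicate=images,
        imaging=imaging,
        segmentation=segmentation,
        histogram_bin_width=float(bin_width),
        working_correlation=corr,
        seed=seed,
    )


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML/JSON experiment config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
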