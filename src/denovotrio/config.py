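"""Cohort-generator configuration.

The configuration is the single place where the generative model of a
simulated trio cohort is pinned down: the joint parental-age distribution,
the linear model for expected DNM counts, the parent-of-origin and mutation
spectrum models, the genome partition, and the detection (sensitivity /
precision) channel.  A packaged configuration, ``paper_cohort.yaml``,
carries the published point estimates for a 693-trio whole-genome cohort so
that every downstream stage can be exercised at realistic operating
conditions without any external data.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import yaml


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class AgeModel:
    """Truncated bivariate-normal model for parental ages at conception."""

    mean_father: float = 33.4
    mean_mother: float = 31.2
    sd_father: float = 5.5
    sd_mother: float = 4.5
    pearson_r: float = 0.70
    bounds_father: tuple[float, float] = (17.0, 63.0)
    bounds_mother: tuple[float, float] = (17.0, 43.0)

    def validate(self) -> None:
        if not -1.0 < self.pearson_r < 1.0:
            raise ConfigurationError(f"pearson_r must be in (-1, 1), got {self.pearson_r}")
        for name, (lo, hi) in (("father", self.bounds_father), ("mother", self.bounds_mother)):
            if lo >= hi:
                raise ConfigurationError(f"{name} age bounds must satisfy lo < hi, got ({lo}, {hi})")
        if self.sd_father <= 0 or self.sd_mother <= 0:
            raise ConfigurationError("age standard deviations must be positive")


@dataclass
class CountModel:
    """Linear predictor for the expected number of true DNMs per proband.

    mean_i = beta0 + beta_father*F_i + beta_mother*M_i
             + maternal_quadratic*(M_i - mean_mother)^2
             + beta_art*ART_i + beta_preterm*preterm_i

    Counts are Poisson around this mean (floored at zero).
    """

    beta0: float = 6.61
    beta_father: float = 0.64
    beta_mother: float = 0.35
    beta_art: float = 4.25
    beta_preterm: float = 0.0
    maternal_quadratic: float = 0.0
    art_fraction: float = 0.0
    preterm_fraction: float = 0.30


@dataclass
class OriginModel:
    paternal_fraction: float = 0.78
    phased_fraction: float = 0.30


@dataclass
class SpectrumModel:
    """Per-base relative mutation intensities by context and class.

    ``cpg_transition_multiplier`` (and the transversion analogue) scale the
    per-base intensity at CpG positions relative to non-CpG positions.
    ``ts_tv_intensity_ratio`` is the per-base transition:transversion
    intensity at non-CpG sites.  ``strong_to_weak_ratio`` is the ratio of
    strong->weak (G:C -> A:T) to weak->strong intensity within each class;
    ``transversion_neutral_fraction`` is the share of transversions that are
    strength-neutral (C<->G, A<->T).
    """

    cpg_transition_multiplier: float = 13.1
    cpg_transversion_multiplier: float = 2.4
    strong_to_weak_ratio: float = 1.69
    ts_tv_intensity_ratio: float = 2.0
    transversion_neutral_fraction: float = 1.0 / 3.0


@dataclass
class GenomeModel:
    """Simulated effective genome: sizes in bp, split across 22 autosomes."""

    L_effective: int = 1_620_000_000
    cpg_bases: int = 29_040_000
    noncpg_bases: int = 1_590_960_000
    n_chromosomes: int = 22
    cluster_artifact_rate: float = 0.0  # expected artifact PAIRS per trio
    cluster_window: int = 200          # bp between members of an artifact pair
    nocall_rate: float = 0.0           # fraction of genome no-called per individual

    def validate(self) -> None:
        if self.L_effective <= 0:
            raise ConfigurationError("L_effective must be positive")
        if self.cpg_bases + self.noncpg_bases != self.L_effective:
            raise ConfigurationError(
                "cpg_bases + noncpg_bases must equal L_effective "
                f"({self.cpg_bases} + {self.noncpg_bases} != {self.L_effective})"
            )


@dataclass
class DetectionModel:
    sensitivity: float = 0.75
    precision: float = 0.87
    mean_depth: float = 60.0

    def validate(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ConfigurationError("sensitivity must be in (0, 1]")
        if not 0 < self.precision <= 1:
            raise ConfigurationError("precision must be in (0, 1] (0 leaves the false-positive intensity undefined)")


@dataclass
class BatchModel:
    """Sequencing-batch structure: software-version labels with optional
    per-version additive offsets on the false-positive intensity."""

    version_labels: tuple[str, ...] = ("2.0.2",)
    version_probs: tuple[float, ...] | None = None
    fp_offsets: dict[str, float] = field(default_factory=dict)


@dataclass
class RateModel:
    """Generative constants for the mutation-rate recovery channel."""

    rate_per_bp: float = 1.05e-8
    genome_nogap_bases: int = 2_684_000_000
    commonly_callable_bases: int = 2_210_000_000
    true_beta_father: float = 0.92
    true_beta_mother: float = 0.51


@dataclass
class CohortConfig:
    n_trios: int = 693
    age_model: AgeModel = field(default_factory=AgeModel)
    count_model: CountModel = field(default_factory=CountModel)
    origin_model: OriginModel = field(default_factory=OriginModel)
    spectrum: SpectrumModel = field(default_factory=SpectrumModel)
    genome_model: GenomeModel = field(default_factory=GenomeModel)
    detection: DetectionModel = field(default_factory=DetectionModel)
    batch: BatchModel = field(default_factory=BatchModel)
    rate_model: RateModel = field(default_factory=RateModel)
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_trios < 1:
            raise ConfigurationError("n_trios must be >= 1")
        self.age_model.validate()
        self.genome_model.validate()
        self.detection.validate()
        for name in ("art_fraction", "preterm_fraction"):
            v = getattr(self.count_model, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("paternal_fraction", "phased_fraction"):
            v = getattr(self.origin_model, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        return self

    def replace(self, **overrides) -> "CohortConfig":
        """Return a copy with top-level or nested (dotted) overrides applied."""
        new = copy.deepcopy(self)
        for key, value in overrides.items():
            if "." in key:
                head, tail = key.split(".", 1)
                setattr(getattr(new, head), tail, value)
            else:
                setattr(new, key, value)
        return new.validate()


_SECTIONS = {
    "age_model": AgeModel,
    "count_model": CountModel,
    "origin_model": OriginModel,
    "spectrum": SpectrumModel,
    "genome_model": GenomeModel,
    "detection": DetectionModel,
    "batch": BatchModel,
    "rate_model": RateModel,
}


def config_from_dict(raw: dict) -> CohortConfig:
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS and isinstance(value, dict):
            cls = _SECTIONS[key]
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - fields
            if unknown:
                raise ConfigurationError(f"unknown keys in {key}: {sorted(unknown)}")
            coerced = dict(value)
            for tup_key in ("bounds_father", "bounds_mother", "version_labels", "version_probs"):
                if tup_key in coerced and coerced[tup_key] is not None:
                    coerced[tup_key] = tuple(coerced[tup_key])
            kwargs[key] = cls(**coerced)
        else:
            kwargs[key] = value
    return CohortConfig(**kwargs).validate()


def load_config(path) -> CohortConfig:
    """Load a cohort configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def paper_cohort_config() -> CohortConfig:
    """The packaged configuration transcribed from the published cohort."""
    text = resources.files("denovotrio").joinpath("data/paper_cohort.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))
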