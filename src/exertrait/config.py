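"""Configuration objects for simulation and pipeline runs.

``SimConfig`` fixes the study conditions of the synthetic data: the grid of
tissues, traits, trait categories and genes; the human-cohort dimensions;
the planted enrichment and direction effects the downstream models are
asked to recover; and the per-gene heritability and evidence-score laws.
Defaults emulate a mid-sized endurance-exercise training study (the real
design spans 15 tissues with 47-50 animals per tissue and a four-point
training time course) at a scale where full analyses run in minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

TIMEPOINTS = ("1w", "2w", "4w", "8w")
SEXES = ("F", "M")

#: Default tissue labels (a subset of the tissues profiled in multi-tissue
#: endurance-training studies; the easily biopsied ones are BLOOD, the two
#: skeletal muscles and white adipose).
DEFAULT_TISSUES = (
    "BLOOD",
    "SKM-GN",
    "SKM-VL",
    "WAT-SC",
    "HEART",
    "LIVER",
    "LUNG",
    "KIDNEY",
    "COLON",
    "SPLEEN",
)

DEFAULT_CATEGORIES = ("Cardiometabolic", "Immune", "Anthropometric", "Psychiatric")

EASY_BIOPSY_TISSUES = ("BLOOD", "SKM-GN", "SKM-VL", "WAT-SC")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class H2Law:
    """Per-gene SNP-heritability law on [0, 1).

    ``kind='mixture'`` plants a fraction of genes with heritability drawn
    uniformly on [low, high) and the rest at exactly 0, emulating the
    empirical situation where most gene x tissue pairs have no detectably
    heritable expression.  ``kind='point'`` puts all genes at ``value``.
    ``kind='uniform'`` draws every gene from [low, high).
    """

    kind: str = "mixture"
    nonzero_fraction: float = 0.08
    low: float = 0.2
    high: float = 0.8
    value: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("mixture", "point", "uniform"):
            raise ConfigError(f"unknown h2 law kind: {self.kind!r}")
        if not 0.0 <= self.nonzero_fraction <= 1.0:
            raise ConfigError("nonzero_fraction must lie in [0, 1]")
        if not (0.0 <= self.low <= self.high < 1.0) or not 0.0 <= self.value < 1.0:
            raise ConfigError("heritability values must lie in [0, 1)")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        if self.kind == "point":
            return np.full(n, self.value)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        h2 = np.zeros(n)
        planted = rng.random(n) < self.nonzero_fraction
        h2[planted] = rng.uniform(self.low, self.high, size=int(planted.sum()))
        return h2


@dataclass
class EvidenceLaw:
    """Distribution of gene-disease evidence scores on [0, 1]."""

    kind: str = "beta"
    a: float = 0.4
    b: float = 1.6
    value: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("beta", "uniform", "point"):
            raise ConfigError(f"unknown evidence law kind: {self.kind!r}")
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ConfigError("beta parameters must be positive")
        if not 0.0 <= self.value <= 1.0:
            raise ConfigError("point value must lie in [0, 1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self.validate()
        if self.kind == "point":
            return np.full(n, self.value)
        if self.kind == "uniform":
            return rng.random(n)
        return rng.beta(self.a, self.b, size=n)


@dataclass
class PlantedEffects:
    """Logit-scale enrichment effects planted into the TWAS table.

    ``alpha`` is the overall DEG-vs-background log-odds difference in hit
    frequency; ``beta`` (per tissue), ``gamma`` (per trait) and ``epsilon``
    (per tissue x trait cell) are deviations around it.  ``None`` means a
    zero vector/grid of the appropriate shape.
    """

    alpha: float = 1.0
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    epsilon: np.ndarray | None = None

    def resolve(self, n_tissues: int, n_traits: int) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        beta = np.zeros(n_tissues) if self.beta is None else np.asarray(self.beta, float)
        gamma = np.zeros(n_traits) if self.gamma is None else np.asarray(self.gamma, float)
        eps = (
            np.zeros((n_tissues, n_traits))
            if self.epsilon is None
            else np.asarray(self.epsilon, float)
        )
        if beta.shape != (n_tissues,):
            raise ConfigError(f"beta must have shape ({n_tissues},), got {beta.shape}")
        if gamma.shape != (n_traits,):
            raise ConfigError(f"gamma must have shape ({n_traits},), got {gamma.shape}")
        if eps.shape != (n_tissues, n_traits):
            raise ConfigError(
                f"epsilon must have shape ({n_tissues}, {n_traits}), got {eps.shape}"
            )
        return float(self.alpha), beta, gamma, eps


@dataclass
class SimConfig:
    """Full specification of a synthetic study."""

    n_tissues: int = 10
    n_traits: int = 20
    n_categories: int = 4
    n_genes: int = 2000
    n_samples_human: int = 200
    n_snps: int = 500
    n_covariates: int = 5
    timepoints: Sequence[str] = TIMEPOINTS
    sexes: Sequence[str] = SEXES
    seed: int = 0

    tissues: Sequence[str] | None = None
    categories: Sequence[str] | None = None

    # differential-expression side
    de_fraction: float = 0.1
    de_up_fraction: float = 0.5  # probability a planted DE gene is up-regulated
    de_noncentrality: float = 4.0
    expressed_fraction: float = 0.9
    onset_probs: Sequence[float] = (0.15, 0.20, 0.25, 0.40)

    # TWAS side
    planted_effects: PlantedEffects = field(default_factory=PlantedEffects)
    twas_base_logit: float = -2.944  # logit(0.05): sparse background hit rate
    twas_signal: float = 4.5  # mean |z| of genuine hits
    twas_latent_rho: float = 0.3  # gene-wise latent correlation across units
    planted_direction_means: np.ndarray | None = None
    direction_scale: float = 1.0
    theta_true: float = 0.5

    # human cohort
    h2_distribution: H2Law = field(default_factory=H2Law)
    var_prior_shape: float = 3.0
    var_prior_rate: float = 2.0
    grm_mode: str = "direct"  # 'direct' (MVN genetic values) or 'snp'

    # evidence scores / trait genetic correlation
    evidence_score_law: EvidenceLaw = field(default_factory=EvidenceLaw)
    gsnp_block_r: float | None = None  # within-category block correlation

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_tissues", "n_traits", "n_categories", "n_genes",
                     "n_samples_human", "n_snps"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("de_fraction", "de_up_fraction", "expressed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.theta_true <= 1.0:
            raise ConfigError("theta_true must lie in [0, 1]")
        if self.n_samples_human < self.n_covariates + 2:
            raise ConfigError(
                "n_samples_human must exceed n_covariates + 1 for residualization"
            )
        if self.grm_mode not in ("direct", "snp"):
            raise ConfigError(f"unknown grm_mode: {self.grm_mode!r}")
        if self.tissues is not None and len(self.tissues) != self.n_tissues:
            raise ConfigError("tissues labels must match n_tissues")
        if self.categories is not None and len(self.categories) != self.n_categories:
            raise ConfigError("categories labels must match n_categories")
        if len(self.onset_probs) != len(self.timepoints):
            raise ConfigError("onset_probs must match timepoints")
        self.h2_distribution.validate()
        self.evidence_score_law.validate()
        if self.gsnp_block_r is not None and not -1.0 < self.gsnp_block_r < 1.0:
            raise ConfigError("gsnp_block_r must lie in (-1, 1)")

    # -- derived labels ---------------------------------------------------
    @property
    def tissue_labels(self) -> list[str]:
        if self.tissues is not None:
            return list(self.tissues)
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES[: self.n_tissues])
        return [f"TISSUE{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def trait_labels(self) -> list[str]:
        return [f"trait{j + 1:02d}" for j in range(self.n_traits)]

    @property
    def category_labels(self) -> list[str]:
        if self.categories is not None:
            return list(self.categories)
        if self.n_categories <= len(DEFAULT_CATEGORIES):
            return list(DEFAULT_CATEGORIES[: self.n_categories])
        return [f"Category{k + 1}" for k in range(self.n_categories)]

    @property
    def gene_labels(self) -> list[str]:
        return [f"G{g + 1:05d}" for g in range(self.n_genes)]

    def trait_category_index(self) -> np.ndarray:
        """Category index of each trait (traits cycle through categories)."""
        return np.arange(self.n_traits) % self.n_categories

    def rng(self, stage: str) -> np.random.Generator:
        """Seeded substream for one generation stage.

        Each stage gets an independent stream keyed on (seed, stage name) so
        stages can be re-run in isolation with identical results.
        """
        key = int.from_bytes(stage.encode(), "little") % (2**31)
        return np.random.default_rng([int(self.seed), key])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        pe = d["planted_effects"]
        for k, v in list(pe.items()):
            if isinstance(v, np.ndarray):
                pe[k] = v.tolist()
        d["timepoints"] = list(d["timepoints"])
        d["sexes"] = list(d["sexes"])
        d["onset_probs"] = list(d["onset_probs"])
        if d["planted_direction_means"] is not None:
            d["planted_direction_means"] = list(d["planted_direction_means"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "planted_effects" in d and isinstance(d["planted_effects"], dict):
            pe = {
                k: (np.asarray(v, float) if isinstance(v, list) else v)
                for k, v in d["planted_effects"].items()
            }
            d["planted_effects"] = PlantedEffects(**pe)
        if "h2_distribution" in d and isinstance(d["h2_distribution"], dict):
            d["h2_distribution"] = H2Law(**d["h2_distribution"])
        if "evidence_score_law" in d and isinstance(d["evidence_score_law"], dict):
            d["evidence_score_law"] = EvidenceLaw(**d["evidence_score_law"])
        if d.get("planted_direction_means") is not None:
            d["planted_direction_means"] = np.asarray(d["planted_direction_means"], float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SamplerConfig:
    """MCMC settings shared by both hierarchical models."""

    chains: int = 4
    warmup: int = 2500
    samples: int = 2500
    target_accept: float = 0.95
    max_treedepth: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    sim: SimConfig = field(default_factory=SimConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    evidence_threshold: float = 0.8
    hit_fdr: float = 0.05
    h2_filter_alpha: float = 0.10
    enrich_mass_rule: float = 0.95
    direction_mass_rule: float = 0.90
    gsea_n_perm: int = 999
    min_tissues_shared: int = 3
    exclude_tissues: Sequence[str] = EASY_BIOPSY_TISSUES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("evidence_threshold", "hit_fdr", "h2_filter_alpha",
                     "enrich_mass_rule", "direction_mass_rule"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and not (name == "evidence_threshold" and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "sampler": self.sampler.to_dict(),
            "evidence_threshold": self.evidence_threshold,
            "hit_fdr": self.hit_fdr,
            "h2_filter_alpha": self.h2_filter_alpha,
            "enrich_mass_rule": self.enrich_mass_rule,
            "direction_mass_rule": self.direction_mass_rule,
            "gsea_n_perm": self.gsea_n_perm,
            "min_tissues_shared": self.min_tissues_shared,
            "exclude_tissues": list(self.exclude_tissues),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if isinstance(d.get("sampler"), dict):
            d["sampler"] = SamplerConfig(**d["sampler"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
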