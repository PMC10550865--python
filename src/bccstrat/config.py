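"""Configuration for the synthetic EVT cohort generator.

The generator emulates the statistical structure the downstream pipeline
assumes: 71 blood cell characteristics (BCCs) arranged in correlated blocks
that collapse to 58 clusters, sex-shifted means for a subset of variables,
sex-specific cluster effects on recanalization success and stroke etiology,
cardiovascular covariates with realistic prevalences, and free-text
radiology reports carrying TICI grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    """Raised when a generator or pipeline configuration violates an invariant."""


#: Etiology class labels, in the order used for multinomial coefficients.
ETIOLOGY_CLASSES = ("CE", "LAA", "UND")

# Pooled covariate prevalences recomputed from the baseline table of an EVT
# cohort of 333 acute-ischemic-stroke patients (women and men combined).
DEFAULT_COVARIATE_PREVALENCES = {
    "hypertension": 0.57,
    "hyperlipidemia": 0.40,
    "atrial_fibrillation": 0.17,
    "diabetes_mellitus": 0.14,
    "current_smoker": 0.19,
    "prior_stroke_tia": 0.17,
    "prior_mi": 0.14,
    "antiplatelet": 0.29,
    "doac": 0.13,
}

DEFAULT_IVT_PREVALENCE = 0.34

# CE / LAA / UND marginals from the same baseline table.
DEFAULT_ETIOLOGY_MARGINALS = (0.39, 0.34, 0.27)


def _default_sex_shifts() -> dict[int, float]:
    # 21 of 71 variables carry a 0.8-SD sex shift with alternating direction
    # (some analytes run higher in women, e.g. platelet count; some lower,
    # e.g. hemoglobin).
    return {i: (0.8 if i % 2 == 0 else -0.8) for i in range(21)}


def _alternating(clusters: list[int], magnitude: float) -> dict[int, float]:
    return {c: (magnitude if i % 2 == 0 else -magnitude) for i, c in enumerate(clusters)}


def _default_informative() -> dict[str, dict[int, float]]:
    # Cluster indices are 0-based over the 58 default clusters.  The pattern
    # mirrors the stable-set structure reported for the real cohort: a shared
    # backbone plus female-specific and male-specific signal.
    return {
        "shared": _alternating(list(range(13, 26)), 0.3),
        "female_only": _alternating(list(range(26, 38)), 0.35),
        "male_only": _alternating(list(range(38, 58)), 0.3),
    }


def _default_etiology() -> dict[str, dict[int, tuple[float, float]]]:
    # Per-cluster (CE, LAA) log-odds relative to UND.  Dual-signal design:
    # 3 of the shared recanalization clusters, all 12 female-specific and 11
    # of the male-specific clusters also carry etiology signal.
    def spread(clusters: list[int], mag: float) -> dict[int, tuple[float, float]]:
        out: dict[int, tuple[float, float]] = {}
        for i, c in enumerate(clusters):
            out[c] = (mag, -mag) if i % 2 == 0 else (-mag, mag)
        return out

    return {
        "shared": spread([13, 14, 15], 0.5),
        "female_only": spread(list(range(26, 38)), 0.5),
        "male_only": spread(list(range(38, 49)), 0.5),
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 143 women and 190 men, 71 BCCs
    in 58 correlation blocks (45 singletons + 13 pairs), within-block
    correlation 0.9 and between-block correlation 0.1, 21 sex-shifted
    variables at 0.8 SD, and sex-specific cluster effects on recanalization
    and etiology.
    """

    seed: int
    n_female: int = 143
    n_male: int = 190
    n_bcc: int = 71
    n_clusters: int = 58
    rho_within: float = 0.9
    rho_between: float = 0.1
    sex_shift_vars: dict[int, float] = field(default_factory=_default_sex_shifts)
    informative_clusters: dict[str, dict[int, float]] = field(default_factory=_default_informative)
    etiology_clusters: dict[str, dict[int, tuple[float, float]]] = field(
        default_factory=_default_etiology
    )
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    ivt_prevalence: float = DEFAULT_IVT_PREVALENCE
    etiology_marginals: tuple[float, float, float] = DEFAULT_ETIOLOGY_MARGINALS
    success_intercept: float = 0.0
    missing_rate: float = 0.0
    marginal: str = "gaussian"  # or "lognormal"
    # Report-text generation: label_noise is the probability that the grade in
    # the report contradicts the recanalization label; none_rate / conflict_rate
    # are the fractions of reports with zero or two distinct TICI mentions.
    label_noise: float = 0.0
    none_rate: float = 0.0
    conflict_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0 or self.n_female + self.n_male == 0:
            raise ConfigError("cohort must contain at least one patient")
        if self.n_clusters > self.n_bcc:
            raise ConfigError(
                f"n_clusters ({self.n_clusters}) must not exceed n_bcc ({self.n_bcc})"
            )
        if not (0.0 <= self.rho_between < self.rho_within <= 1.0):
            raise ConfigError(
                "correlations must satisfy 0 <= rho_between < rho_within <= 1"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        for name, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"prevalence of {name!r} must be in [0, 1]")
        for p in (self.ivt_prevalence, self.label_noise, self.none_rate, self.conflict_rate):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("probabilities must be in [0, 1]")
        if self.none_rate + self.conflict_rate > 1.0:
            raise ConfigError("none_rate + conflict_rate must not exceed 1")
        if abs(sum(self.etiology_marginals) - 1.0) > 1e-9:
            raise ConfigError("etiology marginals must sum to 1")
        if self.marginal not in ("gaussian", "lognormal"):
            raise ConfigError(f"unknown marginal family {self.marginal!r}")
        for v in self.sex_shift_vars:
            if not (0 <= v < self.n_bcc):
                raise ConfigError(f"sex_shift variable index {v} out of range")
        sets = [set(self.informative_clusters.get(k, {})) for k in
                ("shared", "female_only", "male_only")]
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ConfigError("shared/female_only/male_only cluster sets must be disjoint")
        for s in sets:
            for c in s:
                if not (0 <= c < self.n_clusters):
                    raise ConfigError(f"informative cluster index {c} out of range")
        for group in self.etiology_clusters.values():
            for c in group:
                if not (0 <= c < self.n_clusters):
                    raise ConfigError(f"etiology cluster index {c} out of range")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigError("generator config must specify a seed")
        if "etiology_clusters" in raw:
            raw["etiology_clusters"] = {
                grp: {int(c): tuple(v) for c, v in d.items()}
                for grp, d in raw["etiology_clusters"].items()
            }
        for key in ("sex_shift_vars",):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        if "informative_clusters" in raw:
            raw["informative_clusters"] = {
                grp: {int(c): float(v) for c, v in d.items()}
                for grp, d in raw["informative_clusters"].items()
            }
        if "etiology_marginals" in raw:
            raw["etiology_marginals"] = tuple(raw["etiology_marginals"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
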