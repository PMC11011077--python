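"""Cohort-generator configuration.

:class:`CohortConfig` collects every distributional and effect-size
parameter of the synthetic glioblastoma cohort generator.  The packaged
``paper_like`` preset reproduces the demographic and outcome summaries of
a real 279-patient institutional GBM cohort (median OS 12 months, 236
deaths, median diameter 4.4 cm, core volume 28.1 cm3, whole volume
103.3 cm3, ...); the ``null`` preset keeps the same covariate structure
but removes every covariate effect on the hazard, which is what type-I
error and concordance calibration checks need.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CohortConfig",
    "SURGERY_LEVELS",
    "ONCOLOGY_LEVELS",
    "MGMT_LEVELS",
    "BETA_KEYS",
    "paper_like_config",
    "null_config",
]

#: Category labels, in reference-first order used for dummy coding.
SURGERY_LEVELS = ("biopsy", "resection_100", "resection_ge90", "resection_lt90")
ONCOLOGY_LEVELS = ("no_stupp", "full_stupp", "partial_stupp")
MGMT_LEVELS = ("unmethylated", "methylated", "unknown")

#: Covariate names accepted in ``CohortConfig.betas`` (log-hazard-ratio scale).
BETA_KEYS = frozenset(
    {
        "age",
        "female",
        "surgery_resection_100",
        "surgery_resection_ge90",
        "surgery_resection_lt90",
        "oncology_full_stupp",
        "oncology_partial_stupp",
        "mgmt_methylated",
        "diameter",
        "log_diameter",
        "cv",
        "log_cv",
        "wv",
        "log_wv",
    }
)

_Z75 = 0.6744897501960817  # standard-normal upper quartile


class ConfigError(ValueError):
    """Raised when a CohortConfig violates its invariants."""


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (3, 3):
        raise ConfigError(f"size_copula_corr must be 3x3, got shape {a.shape}")
    return a


@dataclass
class CohortConfig:
    """All parameters of the synthetic-cohort generator.

    Quartile triplets (q1 < median < q3) parameterise the marginal
    distributions; probabilities are marginal category frequencies;
    ``betas`` maps covariate names to log hazard ratios on the analysis
    scale of that covariate (e.g. ``log_wv`` is per unit of ln(cm3)).
    Times are in months throughout.
    """

    n_patients: int = 279

    # age: truncated normal quartile-matched to median/IQR, bounded by range
    age_median: float = 62.0
    age_q1: float = 55.0
    age_q3: float = 68.0
    age_min: float = 31.0
    age_max: float = 85.0

    p_female: float = 108.0 / 279.0

    # (biopsy, 100% resected, >=90% resected, <90% resected)
    surgery_probs: tuple[float, ...] = (71 / 279, 57 / 279, 86 / 279, 65 / 279)
    # (no Stupp, full Stupp, partial Stupp)
    oncology_probs: tuple[float, ...] = (150 / 279, 58 / 279, 71 / 279)

    p_mgmt_methylated_given_known: float = 103.0 / 258.0
    p_mgmt_missing: float = 21.0 / 279.0

    # tumour size marginals: diameter truncated-normal, CV/WV lognormal
    diameter_median: float = 4.4
    diameter_q1: float = 3.3
    diameter_q3: float = 5.4
    cv_median: float = 28.1
    cv_q1: float = 12.6
    cv_q3: float = 50.3
    wv_median: float = 103.3
    wv_q1: float = 45.6
    wv_q3: float = 160.1

    # latent Gaussian correlation of (diameter, CV, WV)
    size_copula_corr: tuple[tuple[float, ...], ...] = (
        (1.00, 0.90, 0.80),
        (0.90, 1.00, 0.85),
        (0.80, 0.85, 1.00),
    )

    # log-odds per SD of size shifting surgery toward less-complete resection
    surgery_size_assoc: float = 0.0

    # Weibull proportional-hazards baseline (time in months)
    baseline_shape: float = 1.0
    baseline_scale: float = 12.0 / np.log(2.0)

    # covariate-name -> log hazard ratio
    betas: dict[str, float] = field(default_factory=dict)

    # uniform potential-censoring window (months)
    censor_lo: float = 10.0
    censor_hi: float = 70.0

    # resample rows where the copula inverts core/whole volume nesting
    enforce_nesting: bool = False

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.surgery_probs = tuple(float(p) for p in self.surgery_probs)
        self.oncology_probs = tuple(float(p) for p in self.oncology_probs)
        self.size_copula_corr = tuple(
            tuple(float(v) for v in row) for row in self.size_copula_corr
        )
        self.betas = dict(self.betas)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be a positive integer")
        for name, probs, k in (
            ("surgery_probs", self.surgery_probs, 4),
            ("oncology_probs", self.oncology_probs, 3),
        ):
            if len(probs) != k:
                raise ConfigError(f"{name} must have {k} entries")
            if any(p < 0 for p in probs):
                raise ConfigError(f"{name} entries must be non-negative")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(probs)!r})")
        for name, p in (
            ("p_female", self.p_female),
            ("p_mgmt_methylated_given_known", self.p_mgmt_methylated_given_known),
            ("p_mgmt_missing", self.p_mgmt_missing),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("age", "diameter", "cv", "wv"):
            q1 = getattr(self, f"{name}_q1")
            med = getattr(self, f"{name}_median")
            q3 = getattr(self, f"{name}_q3")
            if not q1 < med < q3:
                raise ConfigError(f"{name} quartiles must satisfy q1 < median < q3")
        if self.age_min >= self.age_max:
            raise ConfigError("age_min must be below age_max")
        corr = _as_matrix(self.size_copula_corr)
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("size_copula_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("size_copula_corr must have unit diagonal")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError("size_copula_corr must be positive definite") from exc
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ConfigError("baseline_shape and baseline_scale must be positive")
        if self.censor_lo < 0 or self.censor_lo >= self.censor_hi:
            raise ConfigError("need 0 <= censor_lo < censor_hi")
        unknown = set(self.betas) - BETA_KEYS
        if unknown:
            raise ConfigError(f"unknown beta keys: {sorted(unknown)}")

    # ------------------------------------------------------------------
    @property
    def copula_matrix(self) -> np.ndarray:
        return _as_matrix(self.size_copula_corr)

    def replace(self, **changes) -> "CohortConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["surgery_probs"] = list(self.surgery_probs)
        d["oncology_probs"] = list(self.oncology_probs)
        d["size_copula_corr"] = [list(r) for r in self.size_copula_corr]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config fields: {sorted(extra)}")
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)


def paper_like_config(seed: int = 0, **overrides) -> CohortConfig:
    """The packaged calibration preset.

    Covariate distributions follow the published cohort summaries; the
    outcome model carries a log-linear whole-volume effect plus modest
    clinical-covariate effects, with the Weibull baseline scale calibrated
    so that the marginal Kaplan-Meier median OS is 12 months and ~236 of
    279 patients die before censoring.
    """
    with resources.files("gbmsize.data").joinpath("paper_like.yaml").open() as fh:
        data = yaml.safe_load(fh)
    data["seed"] = seed
    data.update(overrides)
    return CohortConfig.from_dict(data)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """paper_like covariate structure with every hazard effect removed."""
    base = {
        "betas": {},
        "surgery_size_assoc": 0.0,
        "baseline_scale": 12.0 / float(np.log(2.0)),
    }
    base.update(overrides)
    return paper_like_config(seed=seed, **base)
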