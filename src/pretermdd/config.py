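"""Simulation configuration objects.

``SimConfig`` bundles every tunable of the synthetic-cohort generator.
Defaults reproduce the composition of large developmental-disorder (DD)
clinical-sequencing cohorts: ~84% of probands born at term with WHO
moderate/very/extreme prematurity frequencies of roughly 13%, 2.2% and
0.8%, and a diagnostic yield that declines with increasing prematurity
(42%, 36%, 31%, 22% from term to extremely preterm).

Randomness is controlled by a single master ``seed``; each simulator
draws from an independently derived named substream (see
:meth:`SimConfig.rng`), so adding or re-ordering simulators never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError

#: WHO gestational-age categories, in order of decreasing gestation.
CATEGORIES = ("term", "moderate", "very", "extreme")

#: Completed-week bounds (inclusive) per category; term capped at 42.
CATEGORY_WEEK_RANGE = {
    "term": (37, 42),
    "moderate": (32, 36),
    "very": (28, 31),
    "extreme": (22, 27),
}

#: Developmental milestones tracked by the time-to-event analysis, with
#: baseline median attainment ages (months) typical of a DD cohort
#: (substantially delayed relative to population norms).
DEFAULT_MILESTONE_MEDIANS = {
    "social_smile": 3.0,
    "sitting": 9.0,
    "walking": 18.0,
    "first_words": 24.0,
}


def _check_probs(name: str, probs: Sequence[float], n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n:
        raise ConfigurationError(f"{name} must have {n} entries, got {len(probs)}")
    if any(p < 0 or p > 1 for p in probs):
        raise ConfigurationError(f"{name} entries must lie in [0, 1]: {probs}")
    return probs


@dataclass
class TrioParams:
    """Parameters of the trio (transmitted / non-transmitted) simulator.

    ``beta_direct`` is the effect of the child's standardised polygenic
    score (PGS) on the phenotype; ``beta_parental`` the effect of each
    parent's standardised PGS (capturing indirect genetic effects or
    confounding via the prenatal environment).
    """

    n_variants: int = 500
    allele_freqs: Sequence[float] | None = None
    weights: Sequence[float] | None = None
    beta_direct: float = 0.0
    beta_parental: float = 0.0
    noise_sd: float = 1.0

    def resolved_freqs(self) -> np.ndarray:
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
        else:
            # deterministic spread of common-variant frequencies
            f = np.linspace(0.05, 0.5, max(self.n_variants, 1))[: self.n_variants]
        if f.size != self.n_variants:
            raise ConfigurationError(
                f"allele_freqs length {f.size} != n_variants {self.n_variants}"
            )
        if f.size and (f.min() <= 0 or f.max() >= 1):
            raise ConfigurationError("allele_freqs must lie strictly in (0, 1)")
        return f

    def resolved_weights(self) -> np.ndarray:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
        else:
            w = np.ones(self.n_variants)
        if w.size != self.n_variants:
            raise ConfigurationError(
                f"weights length {w.size} != n_variants {self.n_variants}"
            )
        if w.size and not np.all(np.isfinite(w)):
            raise ConfigurationError("weights must be finite")
        return w

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ConfigurationError("n_variants must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        self.resolved_freqs()
        self.resolved_weights()


@dataclass
class MilestoneParams:
    """Parameters of the milestone time-to-event simulator.

    Event times are exponential with a per-milestone baseline rate
    implied by ``baseline_median_months`` (rate = ln 2 / median) and a
    proportional-hazards shift per prematurity category and diagnosis.
    """

    baseline_median_months: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MILESTONE_MEDIANS)
    )
    log_hr_by_category: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CATEGORIES}
    )
    log_hr_diagnosis: float = 0.0
    censor_prob: float = 0.1

    def validate(self) -> None:
        if not self.baseline_median_months:
            raise ConfigurationError("baseline_median_months must be non-empty")
        for m, med in self.baseline_median_months.items():
            if not med > 0:
                raise ConfigurationError(f"baseline median for {m!r} must be > 0")
        for c in self.log_hr_by_category:
            if c not in CATEGORIES:
                raise ConfigurationError(f"unknown category {c!r} in log_hr_by_category")
        if not 0 <= self.censor_prob <= 1:
            raise ConfigurationError("censor_prob must lie in [0, 1]")


@dataclass
class SimConfig:
    """Master configuration of the synthetic-cohort generator."""

    n_probands: int = 10_000
    category_probs: Sequence[float] = (0.84, 0.13, 0.022, 0.008)
    diag_prob_by_category: Sequence[float] = (0.42, 0.36, 0.31, 0.22)
    dnm_excess: Mapping[str, float] = field(default_factory=dict)
    trio_params: TrioParams = field(default_factory=TrioParams)
    milestone_params: MilestoneParams = field(default_factory=MilestoneParams)
    seed: int = 0
    cohort_label: str = "SIM"
    p_male: float = 0.56

    def validate(self) -> None:
        if self.n_probands < 0:
            raise ConfigurationError("n_probands must be >= 0")
        probs = _check_probs("category_probs", self.category_probs, 4)
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category_probs must sum to 1 within 1e-9, got {sum(probs)!r}"
            )
        _check_probs("diag_prob_by_category", self.diag_prob_by_category, 4)
        for name, rate in self.dnm_excess.items():
            if rate < 0:
                raise ConfigurationError(f"dnm_excess[{name!r}] must be >= 0")
        if not 0 <= self.p_male <= 1:
            raise ConfigurationError("p_male must lie in [0, 1]")
        if int(self.seed) < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        self.trio_params.validate()
        self.milestone_params.validate()

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named substream of the master seed."""
        tag = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), tag]))

    def to_dict(self) -> dict:
        return asdict(self)
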