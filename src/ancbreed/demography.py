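"""Studbook demography: expected lifetime offspring per breeding pair.

Converts a brood-size distribution and a survival/breeding schedule into the
expected number of offspring per pair, the Poisson mean the breeding
simulator uses.  The default values come from a wildcat studbook: brood sizes
1..5 with probabilities (0.23, 0.36, 0.30, 0.10, 0.01) (mean 2.3), and an
age-a breeding probability of ``0.5 * (1 - 0.3) * (1 - 0.1)**(a-1)`` for
ages 1..7, summing to about 1.83 expected breeding attempts.  The product is
the expected lifetime offspring, about 4.2.

The printed schedule applies the first-year factor ``(1 - 0.3)`` identically
at every age term; it is implemented literally rather than re-derived as a
life table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemographyConfig",
    "mean_brood",
    "expected_breeding_attempts",
    "expected_offspring",
]


@dataclass(frozen=True)
class DemographyConfig:
    brood_probs: tuple = (0.23, 0.36, 0.30, 0.10, 0.01)
    first_year_survival: float = 0.3
    annual_mortality: float = 0.1
    female_breeding_prob: float = 0.5
    max_age: int = 7

    def __post_init__(self) -> None:
        p = np.asarray(self.brood_probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("brood probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("brood probabilities must sum to 1")
        if self.max_age < 1:
            raise ValueError("max_age must be at least 1")


def mean_brood(config: DemographyConfig = DemographyConfig()) -> float:
    """Mean brood size: sum over k of k * P(brood = k), sizes 1..B."""
    p = np.asarray(config.brood_probs, dtype=float)
    return float(np.sum(np.arange(1, len(p) + 1) * p))


def expected_breeding_attempts(config: DemographyConfig = DemographyConfig()) -> float:
    """Expected breeding attempts over a lifetime.

    Sum over ages a = 1..max_age of the printed schedule
    ``breeding_prob * (1 - first_year_survival) * (1 - mortality)**(a-1)``.
    """
    ages = np.arange(1, config.max_age + 1)
    terms = (
        config.female_breeding_prob
        * (1.0 - config.first_year_survival)
        * (1.0 - config.annual_mortality) ** (ages - 1)
    )
    return float(terms.sum())


def expected_offspring(config: DemographyConfig = DemographyConfig()) -> float:
    """Expected lifetime offspring per pair: mean brood x breeding attempts."""
    return mean_brood(config) * expected_breeding_attempts(config)
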