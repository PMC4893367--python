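"""Latent-trait sampling designs for calibration samples with clinical enrichment.

Two stylized views of how a clinical subsample relates to the general
population are supported:

* **Scenario 1 (two distributions)** — general and clinical respondents are
  distinct populations: theta ~ N(-2, 1) for the general group and
  theta ~ N(0, 1) for the clinical group.
* **Scenario 2 (one distribution)** — everyone belongs to a single standard
  normal population; respondents above a critical value c (the (1 - prevalence)
  quantile, c = 1.28 at 10% prevalence) are "clinical".  Oversampling that
  region distorts the sampling distribution, which case weights
  (population share / sample share) undo.

Group counts are fixed by design, not binomial: a 50% clinical condition of
n = 1500 contains exactly 750 draws per group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SamplingDesign",
    "LatentSample",
    "critical_value",
    "compute_weights",
    "expected_counts",
    "sample_scenario1",
    "sample_scenario2",
]

GENERAL = "general"
CLINICAL = "clinical"


def critical_value(prevalence: float) -> float:
    """Latent-scale cutoff above which the population share is *prevalence*.

    The (1 - prevalence) quantile of the standard normal; 1.28 for a
    prevalence of 10%.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(stats.norm.isf(prevalence))


def compute_weights(prevalence: float, clinical_fraction: float) -> tuple[float, float]:
    """Case weights ``(w_general, w_clinical)`` that undo clinical oversampling.

    Each weight is the population share divided by the sample share, e.g.
    (1.8, 0.2) for 10% prevalence with a 50% clinical sample.  With exact
    group counts the weights sum to the total sample size.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if not 0.0 < clinical_fraction < 1.0:
        raise ValueError(
            f"clinical_fraction must be in (0, 1), got {clinical_fraction}"
        )
    w_general = (1.0 - prevalence) / (1.0 - clinical_fraction)
    w_clinical = prevalence / clinical_fraction
    return w_general, w_clinical


def expected_counts(prevalence: float, n_total: int) -> tuple[float, float]:
    """Expected (general, clinical) counts under random population sampling."""
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return n_total * (1.0 - prevalence), n_total * prevalence


@dataclass
class SamplingDesign:
    """Configuration of one calibration-sample draw."""

    scenario: int
    n_total: int = 1500
    clinical_fraction: float = 0.50
    # scenario 1: two distinct normal populations
    general_mean: float = -2.0
    general_sd: float = 1.0
    clinical_mean: float = 0.0
    clinical_sd: float = 1.0
    # scenario 2: single population split at the critical value
    population_mean: float = 0.0
    population_sd: float = 1.0
    prevalence: float = 0.10

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.clinical_fraction < 1.0:
            raise ValueError(
                f"clinical_fraction must be in (0, 1), got {self.clinical_fraction}"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if min(self.general_sd, self.clinical_sd, self.population_sd) <= 0:
            raise ValueError("standard deviations must be positive")

    @property
    def n_clinical(self) -> int:
        # half-up rounding; integral for all replication-mode settings
        return int(math.floor(self.n_total * self.clinical_fraction + 0.5))

    @property
    def n_general(self) -> int:
        return self.n_total - self.n_clinical


@dataclass
class LatentSample:
    """Drawn latent traits with group labels and case weights."""

    theta: np.ndarray
    group: np.ndarray
    weight: np.ndarray
    design: SamplingDesign

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.group = np.asarray(self.group)
        self.weight = np.asarray(self.weight, dtype=float)
        n = self.theta.size
        if self.group.size != n or self.weight.size != n:
            raise ValueError("theta, group and weight must be parallel vectors")
        if np.any(self.weight < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return self.theta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person": np.arange(1, len(self) + 1),
                "theta": self.theta,
                "group": self.group,
                "weight": self.weight,
            }
        )

    def save(self, path: str | Path) -> None:
        """CSV of the sample plus a JSON sidecar echoing the design."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        path.with_suffix(".design.json").write_text(
            json.dumps(asdict(self.design), indent=1)
        )


def sample_scenario1(design: SamplingDesign, seed=None) -> LatentSample:
    """Draw a two-population sample: clinical N(0,1) and general N(-2,1) by default.

    All case weights are 1; exactly ``round(n_total * clinical_fraction)``
    draws come from the clinical population.
    """
    if design.scenario != 1:
        raise ValueError("design.scenario must be 1")
    rng = np.random.default_rng(seed)
    n_c, n_g = design.n_clinical, design.n_general
    theta_g = rng.normal(design.general_mean, design.general_sd, size=n_g)
    theta_c = rng.normal(design.clinical_mean, design.clinical_sd, size=n_c)
    return LatentSample(
        theta=np.concatenate([theta_g, theta_c]),
        group=np.array([GENERAL] * n_g + [CLINICAL] * n_c),
        weight=np.ones(design.n_total),
        design=design,
    )


def sample_scenario2(design: SamplingDesign, seed=None) -> LatentSample:
    """Draw a single-population sample split at the critical value.

    General thetas come from the standard normal truncated to (-inf, c] and
    clinical thetas from (c, inf), by inverse-CDF on the corresponding
    uniform segments; case weights undo the oversampling so that the sum of
    weights equals the total sample size.
    """
    if design.scenario != 2:
        raise ValueError("design.scenario must be 2")
    rng = np.random.default_rng(seed)
    n_c, n_g = design.n_clinical, design.n_general
    c = critical_value(design.prevalence)
    # work on the standardized scale, then shift/scale by population moments
    f_c = stats.norm.cdf(c)
    u_g = rng.uniform(size=n_g)
    u_c = rng.uniform(size=n_c)
    z_g = stats.norm.ppf(u_g * f_c)
    z_c = stats.norm.ppf(f_c + u_c * (1.0 - f_c))
    theta = design.population_mean + design.population_sd * np.concatenate([z_g, z_c])
    w_g, w_c = compute_weights(design.prevalence, design.clinical_fraction)
    return LatentSample(
        theta=theta,
        group=np.array([GENERAL] * n_g + [CLINICAL] * n_c),
        weight=np.concatenate([np.full(n_g, w_g), np.full(n_c, w_c)]),
        design=design,
    )


def sample_latent(design: SamplingDesign, seed=None) -> LatentSample:
    """Dispatch to the scenario-appropriate sampler."""
    return (sample_scenario1 if design.scenario == 1 else sample_scenario2)(
        design, seed
    )
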