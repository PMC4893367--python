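"""GRM response probabilities and simulation of categorical item responses.

The graded response model for a 5-category item gives four cumulative
probabilities

    P_k(theta) = logistic(a * (theta - b_k)),   k = 1..4,

each the probability of responding in category k or above (categories are
coded 0..4).  Category probabilities are adjacent differences of the
cumulative ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .bank import ItemBank
from .sampling import LatentSample

__all__ = [
    "cumulative_prob",
    "category_probs",
    "ResponseMatrix",
    "simulate_responses",
]


def cumulative_prob(a, b_k, theta):
    """P(response >= k) = logistic(a * (theta - b_k)); broadcasts over inputs."""
    a = np.asarray(a, dtype=float)
    if not np.all(a > 0):
        raise ValueError("discrimination must be positive")
    z = a * (np.asarray(theta, dtype=float) - np.asarray(b_k, dtype=float))
    return expit(z)


def category_probs(item, theta) -> np.ndarray:
    """Probabilities of the five response categories at *theta*.

    *item* is anything with attributes ``a`` and ``b`` (4 ordered thresholds);
    *theta* may be a scalar or an array, and the category axis is last.
    """
    a = float(item.a)
    b = np.asarray(item.b, dtype=float)
    if b.shape != (4,) or np.any(np.diff(b) <= 0):
        raise ValueError(f"thresholds must be 4 strictly increasing values, got {b}")
    theta = np.asarray(theta, dtype=float)
    s = expit(a * (theta[..., None] - b))  # (..., 4) cumulative probs
    p = np.empty(theta.shape + (5,))
    p[..., 0] = 1.0 - s[..., 0]
    p[..., 1:4] = s[..., :3] - s[..., 1:]
    p[..., 4] = s[..., 3]
    return p


@dataclass
class ResponseMatrix:
    """Complete persons x items matrix of integer category codes 0..4."""

    data: np.ndarray
    n_categories: int = 5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("response data must be 2-D (persons x items)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("response codes must be integers")
        if self.data.size and (
            self.data.min() < 0 or self.data.max() >= self.n_categories
        ):
            raise ValueError(
                f"response codes must lie in 0..{self.n_categories - 1}"
            )

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.data, columns=[f"item{j + 1}" for j in range(self.n_items)]
        )
        df.insert(0, "person", np.arange(1, self.n_persons + 1))
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ResponseMatrix":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c.startswith("item")]
        return cls(data=df[cols].to_numpy(int))


def simulate_responses(bank: ItemBank, sample, seed=None) -> ResponseMatrix:
    """Draw one GRM response per person-item cell.

    *sample* is a :class:`~grmcalib.sampling.LatentSample` or a plain array of
    latent traits.  Each cell compares a single uniform draw against the
    item's cumulative probabilities at the person's theta, which draws the
    category from the implied multinomial; reproducible given *seed*.
    """
    theta = np.asarray(
        sample.theta if isinstance(sample, LatentSample) else sample, dtype=float
    )
    if len(bank) == 0 or theta.size == 0:
        raise ValueError("bank and sample must be non-empty")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(theta.size, len(bank)))
    # cumulative P(X >= k): shape (persons, items, 4)
    s = expit(bank.a[None, :, None] * (theta[:, None, None] - bank.b[None, :, :]))
    x = (u[:, :, None] <= s).sum(axis=2)
    return ResponseMatrix(data=x.astype(np.int8))
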