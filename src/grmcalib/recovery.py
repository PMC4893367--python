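"""Outcome measures of the recovery experiment.

Item-parameter recovery contrasts an estimated bank with the generating one
via per-parameter Pearson correlations and mean differences
(true - estimate; a *negative* mean difference means overestimation).
Person-parameter recovery simulates fresh respondents from the *true* bank
at fixed latent values (500 per point on a 17-point grid from -4 to 4),
MAP-scores them under the *estimated* bank, and summarizes bias, correlation
and the mean reported standard error.  T = 50 + 10 * theta converts the
latent scale to the familiar T-score norm scale (theta = 2 <-> T = 70).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bank import ItemBank, PARAM_NAMES
from .responses import simulate_responses
from .scoring import map_score_matrix

__all__ = [
    "ParamRecovery",
    "ThetaRecovery",
    "param_recovery",
    "theta_recovery",
    "make_grid_dataset",
    "t_score",
    "DEFAULT_THETA_GRID",
]

#: 17 evenly spaced true latent values from -4 to 4 (step 0.5).
DEFAULT_THETA_GRID = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.5), 10)


@dataclass(frozen=True)
class ParamRecovery:
    """Per-parameter correlation and mean(true - estimate) across items."""

    table: pd.DataFrame  # index a,b1..b4; columns correlation, mean_diff

    def correlation(self, name: str) -> float:
        return float(self.table.loc[name, "correlation"])

    def mean_diff(self, name: str) -> float:
        return float(self.table.loc[name, "mean_diff"])


@dataclass(frozen=True)
class ThetaRecovery:
    """Latent-trait recovery on a fixed grid of true values."""

    by_theta: pd.DataFrame  # columns theta, mean_theta_hat, mean_se, n
    correlation: float
    mean_diff: float  # mean(theta - theta_hat) pooled over all simulees
    mean_se: float

    def mean_estimate_at(self, theta: float) -> float:
        row = self.by_theta[np.isclose(self.by_theta["theta"], theta)]
        if row.empty:
            raise KeyError(f"true theta {theta} is not on the grid")
        return float(row["mean_theta_hat"].iloc[0])


def param_recovery(true_bank: ItemBank, est_bank: ItemBank) -> ParamRecovery:
    """Correlate and difference the parameter columns of two aligned banks."""
    if len(true_bank) != len(est_bank):
        raise ValueError(
            f"bank sizes differ: {len(true_bank)} vs {len(est_bank)} items"
        )
    if true_bank.n_categories != est_bank.n_categories:
        raise ValueError("banks must have the same number of categories")
    cols = {}
    for name in PARAM_NAMES:
        if name == "a":
            t, e = true_bank.a, est_bank.a
        else:
            k = int(name[1]) - 1
            t, e = true_bank.b[:, k], est_bank.b[:, k]
        cols[name] = (float(np.corrcoef(t, e)[0, 1]), float(np.mean(t - e)))
    table = pd.DataFrame(cols, index=["correlation", "mean_diff"]).T
    return ParamRecovery(table=table)


def make_grid_dataset(
    true_bank: ItemBank,
    seed=None,
    grid=DEFAULT_THETA_GRID,
    n_per_point: int = 500,
):
    """Simulate the person-recovery dataset from the true bank.

    Returns ``(theta_true, responses)`` with ``n_per_point`` simulees at each
    grid value.  Generated once per study replication and scored under every
    calibration, so differences between calibrations are attributable to the
    estimated banks alone.
    """
    grid = np.asarray(grid, dtype=float)
    theta_true = np.repeat(grid, n_per_point)
    responses = simulate_responses(true_bank, theta_true, seed=seed)
    return theta_true, responses


def theta_recovery(
    true_bank: ItemBank,
    est_bank: ItemBank,
    seed=None,
    *,
    grid=DEFAULT_THETA_GRID,
    n_per_point: int = 500,
    dataset=None,
) -> ThetaRecovery:
    """MAP recovery of the latent trait scored under *est_bank*.

    Pass ``dataset=(theta_true, responses)`` to reuse a shared simulated
    dataset; otherwise one is generated from *true_bank* with *seed*.
    """
    if dataset is None:
        theta_true, responses = make_grid_dataset(true_bank, seed, grid, n_per_point)
    else:
        theta_true, responses = dataset
        theta_true = np.asarray(theta_true, dtype=float)
    theta_hat, se, _ = map_score_matrix(
        np.asarray(getattr(responses, "data", responses)), est_bank
    )
    df = pd.DataFrame({"theta": theta_true, "theta_hat": theta_hat, "se": se})
    by = (
        df.groupby("theta", sort=True)
        .agg(mean_theta_hat=("theta_hat", "mean"), mean_se=("se", "mean"), n=("se", "size"))
        .reset_index()
    )
    if len(df) > 1 and df["theta"].nunique() > 1:
        corr = float(np.corrcoef(df["theta"], df["theta_hat"])[0, 1])
    else:
        corr = float("nan")
    return ThetaRecovery(
        by_theta=by,
        correlation=corr,
        mean_diff=float(np.mean(df["theta"] - df["theta_hat"])),
        mean_se=float(df["se"].mean()),
    )


def t_score(theta):
    """Convert latent-trait values to the T-score norm scale (mean 50, SD 10)."""
    return 50.0 + 10.0 * np.asarray(theta, dtype=float)
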