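"""Quasi-trait GRM item banks: generation, summaries, and serialization.

A graded response model (GRM) item for a 5-point Likert scale is described
by a discrimination (slope) parameter ``a > 0`` and four strictly ordered
location (threshold) parameters ``b1 < b2 < b3 < b4`` on the latent-trait
scale.  A *quasi-trait* bank places most thresholds on the upper half of
the scale, so that general-population respondents (who sit low on the
trait) rarely endorse higher categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ItemBank",
    "BankSummary",
    "QUASI_TRAIT_TARGETS",
    "generate_bank",
    "bank_summary",
    "save_bank",
    "load_bank",
]

PARAM_NAMES = ("a", "b1", "b2", "b3", "b4")

#: Default per-parameter (min, mean, max) profile of the 40-item quasi-trait
#: bank used throughout the replication study.  Thresholds sit mostly on the
#: upper side of the scale, so the bank carries little information below
#: theta ~ -1.
QUASI_TRAIT_TARGETS: dict[str, tuple[float, float, float]] = {
    "a": (1.04, 1.89, 2.66),
    "b1": (-0.97, -0.11, 0.89),
    "b2": (0.27, 0.90, 1.52),
    "b3": (1.20, 1.93, 2.72),
    "b4": (2.20, 2.94, 3.57),
}


@dataclass(frozen=True)
class ItemParameters:
    """GRM parameters of a single 5-category item."""

    a: float
    b: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"discrimination must be positive, got a={self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) != 4:
            raise ValueError("expected exactly 4 thresholds")
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError(f"thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "b", b)


@dataclass
class ItemBank:
    """Ordered collection of GRM item parameters.

    Parameters are stored columnwise: ``a`` with shape (n_items,) and
    ``b`` with shape (n_items, 4), rows strictly increasing.
    """

    a: np.ndarray
    b: np.ndarray
    label: str = ""
    n_categories: int = 5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.ndim != 1 or self.b.shape != (self.a.size, 4):
            raise ValueError(
                f"shape mismatch: a has {self.a.shape}, b has {self.b.shape}"
            )
        if self.n_categories != 5:
            raise ValueError("only 5-category banks are supported")
        if np.any(self.a <= 0):
            bad = int(np.flatnonzero(self.a <= 0)[0])
            raise ValueError(f"item {bad}: discrimination must be positive")
        diffs = np.diff(self.b, axis=1)
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(np.any(diffs <= 0, axis=1))[0])
            raise ValueError(
                f"item {bad}: thresholds must be strictly increasing, got {self.b[bad]}"
            )

    def __len__(self) -> int:
        return self.a.size

    @property
    def n_items(self) -> int:
        return self.a.size

    def __getitem__(self, i: int) -> ItemParameters:
        return ItemParameters(a=float(self.a[i]), b=tuple(self.b[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.b, columns=["b1", "b2", "b3", "b4"])
        df.insert(0, "a", self.a)
        df.insert(0, "item", np.arange(1, self.n_items + 1))
        return df

    @classmethod
    def from_items(cls, items: Sequence[ItemParameters], **kw) -> "ItemBank":
        return cls(
            a=np.array([it.a for it in items]),
            b=np.array([it.b for it in items]),
            **kw,
        )


@dataclass(frozen=True)
class BankSummary:
    """Per-parameter (min, mean, max) of a bank, in latent-scale units."""

    stats: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (lo, mean, hi) in self.stats.items():
            if not (lo <= mean <= hi):
                raise ValueError(
                    f"inconsistent summary for {name}: need min <= mean <= max, "
                    f"got ({lo}, {mean}, {hi})"
                )

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.stats[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: list(v) for k, v in self.stats.items()}, index=["min", "mean", "max"]
        )


def bank_summary(bank: ItemBank) -> BankSummary:
    """Exact columnwise min/mean/max of each parameter of *bank*."""
    if len(bank) == 0:
        raise ValueError("cannot summarize an empty bank")
    cols = {"a": bank.a}
    for k in range(4):
        cols[f"b{k + 1}"] = bank.b[:, k]
    return BankSummary(
        stats={
            name: (float(v.min()), float(v.mean()), float(v.max()))
            for name, v in cols.items()
        }
    )


def _as_summary(targets) -> BankSummary:
    if isinstance(targets, BankSummary):
        return targets
    return BankSummary(stats={k: tuple(map(float, v)) for k, v in targets.items()})


def _sample_column(
    rng: np.random.Generator,
    n: int,
    lo: float,
    mean: float,
    hi: float,
    concentration: float,
) -> np.ndarray:
    """Draw n values on [lo, hi] from a scaled Beta with the requested mean."""
    span = hi - lo
    if span < 1e-12:
        return np.full(n, mean)
    frac = (mean - lo) / span
    if not (0.0 < frac < 1.0):
        raise ValueError(
            f"infeasible targets: mean {mean} not strictly inside ({lo}, {hi})"
        )
    alpha = frac * concentration
    beta = (1.0 - frac) * concentration
    return lo + span * rng.beta(alpha, beta, size=n)


def generate_bank(
    n_items: int = 40,
    seed: int | np.random.Generator | None = None,
    summary_targets: Mapping[str, tuple[float, float, float]] | BankSummary = None,
    *,
    tol: float = 0.15,
    concentration: float = 4.0,
    min_gap: float = 0.05,
    max_tries: int = 500,
    label: str = "quasi-trait",
) -> ItemBank:
    """Generate an item bank whose parameter summary matches a target profile.

    Each parameter column is drawn independently from a Beta distribution
    rescaled to [min, max] with the target mean; per-item threshold draws are
    rejection-resampled until ``b1 < b2 < b3 < b4`` with gaps of at least
    *min_gap*, and whole draws are rejected until every column's min, mean
    and max lie within *tol* of the targets.  Deterministic given *seed*.

    Raises ``ValueError`` for internally inconsistent or unreachable targets.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    targets = _as_summary(
        QUASI_TRAIT_TARGETS if summary_targets is None else summary_targets
    )
    for name in PARAM_NAMES:
        if name not in targets.stats:
            raise ValueError(f"summary_targets missing parameter {name!r}")
    rng = np.random.default_rng(seed)
    seed_echo = seed if isinstance(seed, (int, np.integer)) else None

    def draw_column(name: str) -> np.ndarray:
        """Rejection-resample one parameter column until its own summary fits."""
        lo, mean, hi = targets[name]
        for _ in range(max_tries):
            v = _sample_column(rng, n_items, lo, mean, hi, concentration)
            got = (v.min(), v.mean(), v.max())
            if all(abs(g - t) <= tol for g, t in zip(got, (lo, mean, hi))):
                return v
        raise ValueError(
            f"failed to match the summary targets for {name!r} within tol={tol} "
            f"after {max_tries} attempts"
        )

    for _ in range(max_tries):
        cols = {name: draw_column(name) for name in PARAM_NAMES}
        b = np.column_stack([cols[f"b{k}"] for k in range(1, 5)])
        # columns come from mostly disjoint ranges; sort within item and push
        # adjacent thresholds apart to guarantee ordering with a minimum gap
        b.sort(axis=1)
        for k in range(1, 4):
            b[:, k] = np.maximum(b[:, k], b[:, k - 1] + min_gap)
        candidate = ItemBank(a=cols["a"], b=b, label=label, meta={"seed": seed_echo})
        got = bank_summary(candidate)
        ok = all(
            abs(got[name][j] - targets[name][j]) <= tol
            for name in PARAM_NAMES
            for j in range(3)
        )
        if ok:
            candidate.meta["summary_targets"] = {
                k: list(v) for k, v in targets.stats.items()
            }
            return candidate
    raise ValueError(
        f"failed to match the summary targets within tol={tol} "
        f"after {max_tries} attempts"
    )


def save_bank(bank: ItemBank, path: str | Path) -> None:
    """Write *bank* to CSV (columns item,a,b1..b4) or JSON (with metadata).

    The format is chosen from the file extension; round trips are lossless
    to full floating precision.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "label": bank.label,
            "n_categories": bank.n_categories,
            "meta": bank.meta,
            "items": [
                {"item": i + 1, "a": float(bank.a[i]), "b": [float(x) for x in bank.b[i]]}
                for i in range(len(bank))
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        bank.to_frame().to_csv(path, index=False, float_format="%.17g")


def load_bank(path: str | Path) -> ItemBank:
    """Read a bank written by :func:`save_bank`; validates threshold order."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            payload = json.loads(path.read_text())
            a = np.array([it["a"] for it in payload["items"]], dtype=float)
            b = np.array([it["b"] for it in payload["items"]], dtype=float)
            label = payload.get("label", "")
            meta = payload.get("meta", {})
        else:
            df = pd.read_csv(path, float_precision="round_trip")
            need = {"a", "b1", "b2", "b3", "b4"}
            if not need.issubset(df.columns):
                raise ValueError(f"missing columns {sorted(need - set(df.columns))}")
            a = df["a"].to_numpy(float)
            b = df[["b1", "b2", "b3", "b4"]].to_numpy(float)
            label, meta = "", {}
    except (KeyError, json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed bank file {path}: {exc}") from exc
    return ItemBank(a=a, b=b, label=label, meta=meta)
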