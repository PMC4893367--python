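"""Orchestration of the 12-condition calibration experiment.

For each scenario (two-distribution vs one-distribution) and each clinical
fraction (25/50/75%) a calibration sample of n = 1500 is simulated from a
40-item quasi-trait bank, then calibrated twice:

* **improper** — single-group MML assuming a standard normal latent trait,
  ignoring the oversampling of clinical respondents;
* **proper** — scenario 1: a multi-group model with the clinical mean fixed
  at 0 and the general mean free; scenario 2: case-weighted MML with
  weights that restore the population distribution.

Each of the 12 fits is summarized by item-parameter recovery and by MAP
recovery of the latent trait on a shared 17 x 500 simulee grid.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import ItemBank, generate_bank, load_bank, bank_summary
from .mml import GRMFit, LatentSpec, fit_grm
from .recovery import (
    DEFAULT_THETA_GRID,
    ParamRecovery,
    ThetaRecovery,
    make_grid_dataset,
    param_recovery,
    theta_recovery,
)
from .responses import simulate_responses
from .sampling import SamplingDesign, sample_latent

__all__ = [
    "StudyConfig",
    "ConditionResult",
    "StudyResult",
    "enumerate_conditions",
    "run_study",
    "run_replications",
    "render_tables",
    "bias_curve_table",
    "render_bias_curves",
]

IMPROPER = "improper"
PROPER = "proper"


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    n_items: int = 40
    bank_path: str | None = None  # load instead of generate when given
    bank_targets: dict | None = None  # None -> quasi-trait defaults
    n_total: int = 1500
    clinical_fractions: tuple[float, ...] = (0.25, 0.50, 0.75)
    scenarios: tuple[int, ...] = (1, 2)
    prevalence: float = 0.10
    general_mean: float = -2.0
    general_sd: float = 1.0
    clinical_mean: float = 0.0
    clinical_sd: float = 1.0
    theta_grid: tuple[float, ...] = tuple(DEFAULT_THETA_GRID)
    n_per_grid_point: int = 500
    estimation: dict = field(default_factory=dict)  # GradedResponseModelMML kwargs
    master_seed: int = 1234
    n_replications: int = 1

    def __post_init__(self) -> None:
        for f in self.clinical_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"clinical fraction must be in (0, 1), got {f}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if any(s not in (1, 2) for s in self.scenarios):
            raise ValueError("scenarios must be a subset of (1, 2)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        for key in ("clinical_fractions", "scenarios", "theta_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=list)


@dataclass
class ConditionResult:
    scenario: int
    clinical_fraction: float
    approach: str  # "improper" | "proper"
    fit: GRMFit
    params: ParamRecovery
    thetas: ThetaRecovery
    runtime_s: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class StudyResult:
    bank: ItemBank
    conditions: list[ConditionResult]
    provenance: dict

    def condition(
        self, scenario: int, clinical_fraction: float, approach: str
    ) -> ConditionResult:
        for c in self.conditions:
            if (
                c.scenario == scenario
                and np.isclose(c.clinical_fraction, clinical_fraction)
                and c.approach == approach
            ):
                return c
        raise KeyError(f"no condition ({scenario}, {clinical_fraction}, {approach})")


def enumerate_conditions(config: StudyConfig) -> list[tuple[int, float, str]]:
    """Scenario x clinical fraction x approach; 12 in the default design."""
    return [
        (s, f, approach)
        for s in config.scenarios
        for f in config.clinical_fractions
        for approach in (IMPROPER, PROPER)
    ]


def _design(config: StudyConfig, scenario: int, fraction: float) -> SamplingDesign:
    return SamplingDesign(
        scenario=scenario,
        n_total=config.n_total,
        clinical_fraction=fraction,
        general_mean=config.general_mean,
        general_sd=config.general_sd,
        clinical_mean=config.clinical_mean,
        clinical_sd=config.clinical_sd,
        prevalence=config.prevalence,
    )


def _get_bank(config: StudyConfig, seed_seq: np.random.SeedSequence) -> ItemBank:
    if config.bank_path:
        return load_bank(config.bank_path)
    return generate_bank(
        n_items=config.n_items,
        seed=np.random.default_rng(seed_seq),
        summary_targets=config.bank_targets,
    )


def run_study(config: StudyConfig, replication: int = 0) -> StudyResult:
    """Run one full replication of the experiment; deterministic given seeds.

    The item bank is drawn once from the master seed (shared across
    replications); sampling, response simulation and the person-recovery
    grid dataset use per-replication seed branches.  Non-converged fits do
    not abort the run: they are flagged in the condition's record.
    """
    root = np.random.SeedSequence(config.master_seed)
    bank_ss, rep_root = root.spawn(2)
    bank = _get_bank(config, bank_ss)
    rep_ss = rep_root.spawn(config.n_replications)[replication]
    conds = enumerate_conditions(config)
    pairs = sorted({(s, f) for s, f, _ in conds})
    subs = rep_ss.spawn(1 + len(pairs))
    grid_ss, pair_ss = subs[0], dict(zip(pairs, subs[1:]))

    grid_dataset = make_grid_dataset(
        bank,
        seed=np.random.default_rng(grid_ss),
        grid=np.asarray(config.theta_grid),
        n_per_point=config.n_per_grid_point,
    )

    results: list[ConditionResult] = []
    for scenario, fraction in pairs:
        sample_ss, resp_ss = pair_ss[(scenario, fraction)].spawn(2)
        design = _design(config, scenario, fraction)
        sample = sample_latent(design, seed=np.random.default_rng(sample_ss))
        responses = simulate_responses(bank, sample, seed=np.random.default_rng(resp_ss))
        for approach in (IMPROPER, PROPER):
            if (scenario, fraction, approach) not in conds:
                continue
            kwargs: dict = {}
            if approach == PROPER:
                if scenario == 1:
                    kwargs = {
                        "latent_spec": LatentSpec.two_group(),
                        "group": sample.group,
                    }
                else:
                    kwargs = {"case_weights": sample.weight}
            t0 = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = fit_grm(responses, **kwargs, **config.estimation)
            runtime = time.perf_counter() - t0
            results.append(
                ConditionResult(
                    scenario=scenario,
                    clinical_fraction=fraction,
                    approach=approach,
                    fit=fit,
                    params=param_recovery(bank, fit.bank),
                    thetas=theta_recovery(bank, fit.bank, dataset=grid_dataset),
                    runtime_s=runtime,
                    warnings=[str(w.message) for w in caught],
                )
            )

    provenance = {
        "config": json.loads(config.to_json()),
        "replication": replication,
        "bank_summary": {
            k: list(v) for k, v in bank_summary(bank).stats.items()
        },
        "conditions": [
            {
                "scenario": c.scenario,
                "clinical_fraction": c.clinical_fraction,
                "approach": c.approach,
                "converged": c.fit.converged,
                "n_iter": c.fit.n_iter,
                "loglik": c.fit.loglik,
                "group_means": c.fit.group_means,
                "runtime_s": round(c.runtime_s, 3),
                "warnings": c.warnings,
            }
            for c in results
        ],
    }
    return StudyResult(bank=bank, conditions=results, provenance=provenance)


def run_replications(config: StudyConfig) -> list[StudyResult]:
    """All replications of the study (the replication design uses a single one)."""
    return [run_study(config, r) for r in range(config.n_replications)]


# ----------------------------------------------------------------------
# rendering


def _item_table(result: StudyResult, scenario: int) -> pd.DataFrame:
    rows = []
    fractions = sorted({c.clinical_fraction for c in result.conditions if c.scenario == scenario})
    for fraction in fractions:
        improper = result.condition(scenario, fraction, IMPROPER)
        proper = result.condition(scenario, fraction, PROPER)
        for name in ("a", "b1", "b2", "b3", "b4"):
            rows.append(
                {
                    "clinical_pct": int(round(100 * fraction)),
                    "parameter": name,
                    "cor_improper": improper.params.correlation(name),
                    "meandiff_improper": improper.params.mean_diff(name),
                    "cor_proper": proper.params.correlation(name),
                    "meandiff_proper": proper.params.mean_diff(name),
                }
            )
    return pd.DataFrame(rows)


def _person_table(result: StudyResult) -> pd.DataFrame:
    rows = []
    for c in sorted(
        result.conditions, key=lambda c: (c.scenario, c.clinical_fraction, c.approach)
    ):
        rows.append(
            {
                "scenario": c.scenario,
                "clinical_pct": int(round(100 * c.clinical_fraction)),
                "approach": c.approach,
                "cor": c.thetas.correlation,
                "mean_diff": c.thetas.mean_diff,
                "mean_se": c.thetas.mean_se,
            }
        )
    return pd.DataFrame(rows)


def bias_curve_table(result: StudyResult) -> pd.DataFrame:
    """Tidy mean estimated theta per true theta, condition by condition."""
    frames = []
    for c in result.conditions:
        df = c.thetas.by_theta.copy()
        df.insert(0, "approach", c.approach)
        df.insert(0, "clinical_pct", int(round(100 * c.clinical_fraction)))
        df.insert(0, "scenario", c.scenario)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def render_tables(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write the recovery tables and provenance log as CSV/JSON files.

    Emits per-scenario item-recovery tables (one row per parameter and
    clinical percentage, four statistic columns), the person-recovery
    summary, the bias-curve table behind the figures, and provenance.json.
    Deterministic: rendering the same result twice gives identical bytes.
    """
    if not result.conditions:
        raise ValueError("cannot render an empty study result")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fmt = "%.10g"
    for scenario in sorted({c.scenario for c in result.conditions}):
        p = outdir / f"item_recovery_scenario{scenario}.csv"
        _item_table(result, scenario).to_csv(p, index=False, float_format=fmt)
        paths[f"item_recovery_scenario{scenario}"] = p
    p = outdir / "person_recovery.csv"
    _person_table(result).to_csv(p, index=False, float_format=fmt)
    paths["person_recovery"] = p
    p = outdir / "bias_curves.csv"
    bias_curve_table(result).to_csv(p, index=False, float_format=fmt)
    paths["bias_curves"] = p
    p = outdir / "provenance.json"
    p.write_text(json.dumps(result.provenance, indent=1, sort_keys=True))
    paths["provenance"] = p
    return paths


def render_bias_curves(curves, outdir: str | Path) -> Path:
    """Plot mean estimated vs true theta per scenario and approach.

    *curves* is the emitted bias-curve table (DataFrame or CSV path); the
    figure is drawn from that table alone, one panel per scenario x
    approach, one line per clinical percentage, with the identity line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(curves, (str, Path)):
        curves = pd.read_csv(curves)
    elif isinstance(curves, StudyResult):
        curves = bias_curve_table(curves)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenarios = sorted(curves["scenario"].unique())
    approaches = [a for a in (IMPROPER, PROPER) if a in set(curves["approach"])]
    fig, axes = plt.subplots(
        len(scenarios),
        len(approaches),
        figsize=(5 * len(approaches), 4 * len(scenarios)),
        squeeze=False,
    )
    for i, s in enumerate(scenarios):
        for j, appr in enumerate(approaches):
            ax = axes[i][j]
            sub = curves[(curves["scenario"] == s) & (curves["approach"] == appr)]
            for pct, grp in sub.groupby("clinical_pct"):
                ax.plot(grp["theta"], grp["mean_theta_hat"], marker="o", ms=3,
                        label=f"{pct}% clinical")
            lims = [curves["theta"].min(), curves["theta"].max()]
            ax.plot(lims, lims, "k-", lw=0.8)
            ax.set_title(f"Scenario {s}, {appr} calibration")
            ax.set_xlabel(r"true $\theta$")
            ax.set_ylabel(r"mean estimated $\theta$")
            ax.legend(fontsize=8)
    fig.tight_layout()
    path = outdir / "bias_curves.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
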