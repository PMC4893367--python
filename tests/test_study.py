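import dataclasses
import json

import numpy as np
import pytest

from grmcalib import (
    StudyConfig,
    bias_curve_table,
    enumerate_conditions,
    render_bias_curves,
    render_tables,
    run_study,
)
from grmcalib.study import StudyResult


@pytest.fixture(scope="module")
def tiny_config():
    """Desk-scale study: 10 items, n=300, one fraction -> 4 conditions."""
    return StudyConfig(
        n_items=10,
        n_total=300,
        clinical_fractions=(0.5,),
        theta_grid=(-2.0, 0.0, 2.0),
        n_per_grid_point=40,
        estimation={"max_iter": 200},
        master_seed=77,
    )


@pytest.fixture(scope="module")
def tiny_result(tiny_config):
    return run_study(tiny_config)


def test_enumerate_conditions_counts(tiny_config):
    assert len(enumerate_conditions(StudyConfig())) == 12
    assert len(enumerate_conditions(tiny_config)) == 4


def test_config_validation():
    with pytest.raises(ValueError):
        StudyConfig(clinical_fractions=(0.5, 1.0))
    with pytest.raises(ValueError):
        StudyConfig(prevalence=0.0)
    with pytest.raises(ValueError):
        StudyConfig(scenarios=(3,))
    with pytest.raises(ValueError):
        StudyConfig(n_replications=0)


def test_config_file_round_trip(tmp_path, tiny_config):
    path = tmp_path / "config.json"
    path.write_text(tiny_config.to_json())
    loaded = StudyConfig.from_file(path)
    assert loaded == tiny_config
    ypath = tmp_path / "config.yaml"
    import yaml

    ypath.write_text(yaml.safe_dump(json.loads(tiny_config.to_json())))
    assert StudyConfig.from_file(ypath) == tiny_config


def test_tiny_study_structure(tiny_result, tiny_config):
    assert len(tiny_result.conditions) == 4
    for c in tiny_result.conditions:
        assert c.fit.bank.n_items == tiny_config.n_items
        assert np.all(np.diff(c.fit.loglik_trace) >= -1e-8)
    prov = tiny_result.provenance
    assert prov["config"]["master_seed"] == 77
    assert len(prov["conditions"]) == 4
    assert all("runtime_s" in c for c in prov["conditions"])
    # proper scenario-1 condition reports an estimated general mean
    c = tiny_result.condition(1, 0.5, "proper")
    assert c.fit.group_means["clinical"] == 0.0
    assert c.fit.group_means["general"] < -0.5


def test_condition_lookup(tiny_result):
    with pytest.raises(KeyError):
        tiny_result.condition(1, 0.25, "proper")


def test_study_deterministic_and_seed_branching(tiny_config):
    res2 = run_study(tiny_config)
    ref = run_study(dataclasses.replace(tiny_config, master_seed=78))
    for c, c2 in zip(run_study(tiny_config).conditions, res2.conditions):
        assert np.array_equal(c.fit.bank.a, c2.fit.bank.a)
    assert not np.array_equal(
        ref.conditions[0].fit.bank.a, res2.conditions[0].fit.bank.a
    )


def test_render_tables(tmp_path, tiny_result):
    paths = render_tables(tiny_result, tmp_path / "out")
    import pandas as pd

    item = pd.read_csv(paths["item_recovery_scenario1"])
    # one fraction x 5 parameters, with 4 statistic columns
    assert item.shape[0] == 5
    assert list(item.columns) == [
        "clinical_pct", "parameter",
        "cor_improper", "meandiff_improper", "cor_proper", "meandiff_proper",
    ]
    person = pd.read_csv(paths["person_recovery"])
    assert person.shape[0] == 4
    curves = pd.read_csv(paths["bias_curves"])
    assert curves.shape[0] == 4 * 3  # conditions x grid points
    prov = json.loads(paths["provenance"].read_text())
    assert prov["config"]["n_total"] == 300
    # two renders of the same result are byte-identical
    first = {k: p.read_bytes() for k, p in paths.items()}
    paths2 = render_tables(tiny_result, tmp_path / "out2")
    assert all(paths2[k].read_bytes() == first[k] for k in first)


def test_render_empty_result_fails(tiny_result):
    empty = StudyResult(bank=tiny_result.bank, conditions=[], provenance={})
    with pytest.raises(ValueError):
        render_tables(empty, "unused")


def test_render_bias_curves_from_table_only(tmp_path, tiny_result):
    table = bias_curve_table(tiny_result)
    out = render_bias_curves(table, tmp_path)
    assert out.exists() and out.stat().st_size > 0
    # also accepts the emitted CSV
    paths = render_tables(tiny_result, tmp_path / "t")
    out2 = render_bias_curves(paths["bias_curves"], tmp_path / "t")
    assert out2.exists()
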