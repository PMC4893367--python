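import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from grmcalib import (
    SamplingDesign,
    compute_weights,
    critical_value,
    expected_counts,
    sample_scenario1,
    sample_scenario2,
)

fractions = st.floats(0.01, 0.99)


def test_critical_value():
    assert critical_value(0.10) == pytest.approx(1.28, abs=0.005)
    assert critical_value(0.50) == pytest.approx(0.0, abs=1e-12)
    # independent inverse-CDF evaluation for a quarter prevalence
    assert critical_value(0.25) == pytest.approx(stats.norm.ppf(0.75), abs=1e-12)
    with pytest.raises(ValueError):
        critical_value(1.2)


def test_compute_weights_replication_values():
    w_g, w_c = compute_weights(0.10, 0.50)
    assert (w_g, w_c) == (1.8, 0.2)
    # oversampling ratio: clinical persons are 5x as likely to be sampled
    assert 1.0 / w_c == pytest.approx(5.0)
    assert compute_weights(0.3, 0.3) == (1.0, 1.0)
    with pytest.raises(ValueError):
        compute_weights(0.0, 0.5)
    with pytest.raises(ValueError):
        compute_weights(0.1, 1.0)


@given(prevalence=fractions, fraction=fractions)
@settings(max_examples=50, deadline=None)
def test_weights_average_to_one(prevalence, fraction):
    """Sample-share-weighted average of the case weights is always 1, so the
    weight total equals the sample size whenever group counts are exact."""
    w_g, w_c = compute_weights(prevalence, fraction)
    assert w_c * fraction + w_g * (1 - fraction) == pytest.approx(1.0)


def test_expected_counts():
    assert expected_counts(0.10, 1500) == (1350.0, 150.0)
    assert expected_counts(0.5, 100) == (50.0, 50.0)
    n_g, n_c = expected_counts(1e-9, 1000)
    assert n_c == pytest.approx(0.0, abs=1e-5) and n_g == pytest.approx(1000.0)


def test_scenario1_counts_weights_and_determinism():
    design = SamplingDesign(scenario=1, n_total=1500, clinical_fraction=0.50)
    s = sample_scenario1(design, seed=5)
    assert np.sum(s.group == "clinical") == 750
    assert np.sum(s.group == "general") == 750
    assert np.all(s.weight == 1.0)
    s2 = sample_scenario1(design, seed=5)
    assert np.array_equal(s.theta, s2.theta)


def test_scenario1_nearly_all_clinical():
    design = SamplingDesign(scenario=1, n_total=10, clinical_fraction=0.9999)
    s = sample_scenario1(design, seed=0)
    assert np.all(s.group == "clinical")


def test_scenario1_clinical_mean_clt():
    design = SamplingDesign(scenario=1, n_total=100_000, clinical_fraction=0.9999)
    s = sample_scenario1(design, seed=21)
    clin = s.theta[s.group == "clinical"]
    assert abs(clin.mean()) < 3.0 / np.sqrt(clin.size)


def test_scenario2_truncation_weights_and_sum():
    design = SamplingDesign(scenario=2, n_total=1500, clinical_fraction=0.50)
    s = sample_scenario2(design, seed=9)
    c = critical_value(0.10)
    clin = s.group == "clinical"
    assert clin.sum() == 750
    assert np.all(s.theta[clin] > c)
    assert np.all(s.theta[~clin] <= c)
    assert set(np.round(s.weight[clin], 12)) == {0.2}
    assert set(np.round(s.weight[~clin], 12)) == {1.8}
    assert s.weight.sum() == pytest.approx(1500.0)


def test_scenario2_weighted_distribution_is_standard_normal():
    """Weighted ECDF of an oversampled draw matches the untruncated normal."""
    design = SamplingDesign(
        scenario=2, n_total=100_000, clinical_fraction=0.50, prevalence=0.10
    )
    s = sample_scenario2(design, seed=3)
    order = np.argsort(s.theta)
    ecdf = np.cumsum(s.weight[order]) / s.weight.sum()
    ks = np.max(np.abs(ecdf - stats.norm.cdf(s.theta[order])))
    assert ks < 0.01
    # at clinical_fraction == prevalence the raw draw is already unweighted-normal
    design_eq = SamplingDesign(
        scenario=2, n_total=100_000, clinical_fraction=0.10, prevalence=0.10
    )
    s_eq = sample_scenario2(design_eq, seed=4)
    assert np.allclose(s_eq.weight, 1.0)
    ks_raw = np.max(
        np.abs(
            np.arange(1, s_eq.theta.size + 1) / s_eq.theta.size
            - stats.norm.cdf(np.sort(s_eq.theta))
        )
    )
    assert ks_raw < 0.01


def test_design_validation():
    with pytest.raises(ValueError):
        SamplingDesign(scenario=3)
    with pytest.raises(ValueError):
        SamplingDesign(scenario=1, clinical_fraction=0.0)
    with pytest.raises(ValueError):
        SamplingDesign(scenario=2, prevalence=1.5)
    with pytest.raises(ValueError):
        sample_scenario2(SamplingDesign(scenario=1), seed=0)


def test_sample_round_trip(tmp_path):
    design = SamplingDesign(scenario=2, n_total=40, clinical_fraction=0.25)
    s = sample_scenario2(design, seed=0)
    s.save(tmp_path / "sample.csv")
    assert (tmp_path / "sample.design.json").exists()
    import pandas as pd

    df = pd.read_csv(tmp_path / "sample.csv")
    assert list(df.columns) == ["person", "theta", "group", "weight"]
    np.testing.assert_allclose(df["theta"].to_numpy(), s.theta)
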