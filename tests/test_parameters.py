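"""Distribution moment matching and the packaged parameter table."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transoral_cua import (
    beta_moments,
    fit_beta_from_moments,
    fit_gamma_from_moments,
    gamma_moments,
    load_default_parameters,
    load_parameter_table,
    validate_moments,
)
from transoral_cua.exceptions import InfeasibleMomentsError, InvalidParameterError, SchemaError
from transoral_cua.parameters import REQUIRED_SYMBOLS, Scalars


@pytest.mark.parametrize(
    "alpha,beta,mean,var",
    [
        (4, 80, 0.0476, None),  # esophageal-stenosis probability row
        (1, 1, 0.5, 1 / 12),  # uniform
        (824, 1379, 0.3740, None),  # probability of TORS alone
    ],
)
def test_beta_moments(alpha, beta, mean, var):
    m, v = beta_moments(alpha, beta)
    assert m == pytest.approx(mean, abs=5e-4)
    if var is not None:
        assert v == pytest.approx(var, rel=1e-12)


@pytest.mark.parametrize(
    "shape,rate,mean,sd",
    [
        (602.4698, 0.0475, None, 516.8),  # cost of TLM
        (1, 1, 1.0, 1.0),  # unit exponential
        (61609.3654, 0.7432, 82897.0, None),  # cost of pharyngocutaneous fistula
    ],
)
def test_gamma_moments(shape, rate, mean, sd):
    m, s = gamma_moments(shape, rate)
    if mean is not None:
        assert m == pytest.approx(mean, rel=1e-3)
    if sd is not None:
        assert s == pytest.approx(sd, rel=1e-3)


@pytest.mark.parametrize("bad", [(0, 1), (1, 0), (-2, 3)])
def test_non_positive_shapes_rejected(bad):
    with pytest.raises(InvalidParameterError):
        beta_moments(*bad)
    with pytest.raises(InvalidParameterError):
        gamma_moments(*bad)


@pytest.mark.parametrize(
    "mean,sd,alpha",
    [
        (0.902, 0.203, 1.0328),  # utility of surgery row, shape column
        (0.5, math.sqrt(1 / 12), 1.0),
        (0.794, 0.317, 0.4984),  # utility of adjuvant CRT
    ],
)
def test_fit_beta_recovers_shape_columns(mean, sd, alpha):
    a, b = fit_beta_from_moments(mean, sd)
    assert a == pytest.approx(alpha, rel=2e-3)
    m, v = beta_moments(a, b)
    assert m == pytest.approx(mean, abs=1e-9)
    assert math.sqrt(v) == pytest.approx(sd, abs=1e-9)


@pytest.mark.parametrize(
    "mean,sd,shape",
    [
        (14739, 869.31, 287.46),  # cost of TORS
        (1, 1, 1.0),
        (4332, 410.65, 111.3),  # cost of gastrostomy
    ],
)
def test_fit_gamma_recovers_shape_columns(mean, sd, shape):
    k, rate = fit_gamma_from_moments(mean, sd)
    assert k == pytest.approx(shape, rel=2e-3)
    m, s = gamma_moments(k, rate)
    assert (m, s) == (pytest.approx(mean, abs=1e-9), pytest.approx(sd, abs=1e-9))


def test_beta_variance_infeasible():
    with pytest.raises(InfeasibleMomentsError):
        fit_beta_from_moments(0.5, 0.6)


@settings(derandomize=True, max_examples=100)
@given(
    mean=st.floats(0.01, 0.99),
    frac=st.floats(0.05, 0.95),
)
def test_beta_fit_roundtrip(mean, frac):
    """fit_beta_from_moments and beta_moments are mutual inverses."""
    sd = frac * math.sqrt(mean * (1 - mean))
    a, b = fit_beta_from_moments(mean, sd)
    m, v = beta_moments(a, b)
    assert m == pytest.approx(mean, abs=1e-9)
    assert v == pytest.approx(sd * sd, rel=1e-9)


@settings(derandomize=True, max_examples=100)
@given(mean=st.floats(0.1, 1e5), cv=st.floats(0.01, 2.0))
def test_gamma_fit_roundtrip(mean, cv):
    k, rate = fit_gamma_from_moments(mean, cv * mean)
    m, s = gamma_moments(k, rate)
    assert m == pytest.approx(mean, rel=1e-9)
    assert s == pytest.approx(cv * mean, rel=1e-9)


# ---------------------------------------------------------------------------
# packaged table


def test_default_table_complete(params):
    assert len(params) == 56
    assert all(name in params.values for name in REQUIRED_SYMBOLS)


def test_complement_groups_sum_to_one(params):
    for free, derived in params.complement_groups:
        assert params[free] + params[derived] == pytest.approx(1.0, abs=1e-9)


def test_all_rows_consistent(params):
    report = validate_moments(params)
    bad = report[~report["consistent"]]
    assert bad.empty, f"inconsistent rows: {list(bad.index)}"


def test_dispersion_interpretation_split(params):
    """Event-probability rows carry a variance, cost/utility rows an SD."""
    report = validate_moments(params)
    assert report.loc["pes", "interpretation"] == "variance"
    assert report.loc["pes", "sd_analytic"] ** 2 == pytest.approx(0.000534, abs=2e-6)
    assert report.loc["uSURG", "interpretation"] == "sd"
    assert report.loc["uSURG", "sd_analytic"] == pytest.approx(0.203, abs=5e-4)


def test_beta_row_means_match_printed(params):
    for name, spec in params.specs.items():
        if spec.family == "beta":
            mean, _ = beta_moments(spec.shape1, spec.shape2)
            assert mean == pytest.approx(spec.mean, abs=5e-3), name


def test_gamma_row_moments_match_printed(params):
    for name, spec in params.specs.items():
        if spec.family == "gamma":
            mean, sd = gamma_moments(spec.shape1, spec.shape2)
            assert mean == pytest.approx(spec.mean, rel=1e-2), name
            assert sd == pytest.approx(spec.dispersion, rel=1e-2), name


def test_missing_symbol_rejected(tmp_path, params):
    df = params.to_frame().reset_index().rename(columns={"value": "mean"})
    df["dispersion"] = 0.1
    df = df[df["name"] != "pTorsAlone"]
    path = tmp_path / "table.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="pTorsAlone"):
        load_parameter_table(path)


def test_duplicate_name_rejected(tmp_path, params):
    df = params.to_frame().reset_index().rename(columns={"value": "mean"})
    df["dispersion"] = 0.1
    import pandas as pd

    df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    path = tmp_path / "table.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="duplicate"):
        load_parameter_table(path)


def test_set_rebalances_complement(params):
    p = params.with_value("pCRT_tors", 0.6)
    assert p["pRT_tors"] == pytest.approx(0.4)
    # setting the derived member rebalances the free one
    p = params.with_value("pRT_TLM", 0.3)
    assert p["pCRT_TLM"] == pytest.approx(0.7)


def test_scalars_accessible_and_validated(params):
    assert params["krepeatTLM"] == 1.0
    assert params["wtp_per_qalm"] == 4000.0
    with pytest.raises(InvalidParameterError):
        Scalars(krepeatTLM=0.5).validate()


def test_probability_value_outside_unit_interval_rejected(params):
    with pytest.raises(InvalidParameterError):
        params.with_value("pes", 1.2)
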