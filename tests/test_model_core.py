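"""Scoring engine: FP transforms, indices, baselines, competing risks.

Expected values are recomputed inline from the published term definitions
(spreadsheet-style arithmetic independent of the package code paths).
"""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import predictbc as pb
from predictbc import ER_NEG, ER_POS, OTHER
from predictbc.errors import ConfigurationError, HorizonError, InvalidInputError


# ---------------------------------------------------------------------------
# FP transforms
# ---------------------------------------------------------------------------


def test_fp_transform_er_negative_hand_values(er_neg_patient, model):
    terms = pb.fp_transform(er_neg_patient, ER_NEG, model).iloc[0]
    assert terms["age"] == pytest.approx(50 - 56.325, abs=1e-12)
    assert terms["size"] == pytest.approx(math.sqrt(20 / 100) - 0.5090, abs=1e-12)
    assert terms["nodes"] == pytest.approx(1.0 / math.sqrt((0 + 1) / 10) - 1.72, abs=1e-12)
    assert terms["grade"] == 3  # uncentered ordinal, returned raw


def test_fp_transform_er_positive_hand_values(er_pos_patient, model):
    terms = pb.fp_transform(er_pos_patient, ER_POS, model).iloc[0]
    assert terms["age_1"] == pytest.approx((40 / 10) ** -2 - 0.0287, abs=1e-12)
    assert terms["age_2"] == pytest.approx((40 / 10) ** -2 * math.log(40 / 10) - 0.0510, abs=1e-12)
    assert terms["size"] == pytest.approx(math.log(15 / 100) + 1.5452, abs=1e-12)
    assert terms["nodes"] == pytest.approx(math.log((2 + 1) / 10) + 1.3876, abs=1e-12)
    assert terms["screen"] == 0.0


def test_centering_point_scores_zero(model):
    patient = pb.PatientRecord(age=56.325, size_mm=10, nodes=1, grade=2, er="neg")
    terms = pb.fp_transform(patient, ER_NEG, model)
    assert terms.iloc[0]["age"] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs, bad_field",
    [
        (dict(age=50, size_mm=0.5, nodes=0, grade=2), "size_mm"),
        (dict(age=50, size_mm=20, nodes=-1, grade=2), "nodes"),
        (dict(age=50, size_mm=20, nodes=2.5, grade=2), "nodes"),
        (dict(age=50, size_mm=20, nodes=0, grade=4), "grade"),
        (dict(age=-3, size_mm=20, nodes=0, grade=2), "age"),
    ],
)
def test_invalid_covariates_name_the_field(kwargs, bad_field, model):
    patient = pb.PatientRecord(er="neg", **kwargs)
    with pytest.raises(InvalidInputError) as err:
        pb.fp_transform(patient, ER_NEG, model)
    assert err.value.field == bad_field


def test_endpoint_must_match_er_status(er_pos_patient, model):
    with pytest.raises(InvalidInputError):
        pb.fp_transform(er_pos_patient, ER_NEG, model)


# ---------------------------------------------------------------------------
# Prognostic and mortality indices
# ---------------------------------------------------------------------------


def test_prognostic_index_er_negative(er_neg_patient, model):
    expected = (
        (50 - 56.325) * 0.00894
        + (math.sqrt(0.2) - 0.5090) * 2.109
        + (1 / math.sqrt(0.1) - 1.72) * -0.705
        + 3 * 0.259
    )
    pi = pb.linear_predictor(er_neg_patient, ER_NEG, model)
    assert pi == pytest.approx(expected, abs=1e-12)
    assert pi == pytest.approx(-0.4267, abs=5e-5)


def test_prognostic_index_er_positive(er_pos_patient, model):
    expected = (
        (0.0625 - 0.0287) * 34.53
        + (0.0625 * math.log(4.0) - 0.0510) * -34.20
        + (math.log(0.15) + 1.5452) * 0.7531
        + (math.log(0.3) + 1.3876) * 0.7069
        + 2 * 0.7467
    )
    pi = pb.linear_predictor(er_pos_patient, ER_POS, model)
    assert pi == pytest.approx(expected, abs=1e-12)
    assert pi == pytest.approx(1.3063, abs=5e-5)


def test_zero_terms_give_zero_pi(model):
    terms = np.zeros(len(model.er_negative))
    assert pb.prognostic_index(terms, ER_NEG, model) == 0.0


def test_treatment_log_hrs_add_and_hormone_is_er_positive_only(er_pos_patient, model):
    pi0 = pb.linear_predictor(er_pos_patient, ER_POS, model)
    pi1 = pb.linear_predictor(er_pos_patient, ER_POS, model, treatments=("hormone", "chemotherapy"))
    assert pi1 - pi0 == pytest.approx(
        model.treatments["hormone"].log_hr + model.treatments["chemotherapy"].log_hr, abs=1e-12
    )
    with pytest.raises(ConfigurationError):
        pb.linear_predictor(
            pb.PatientRecord(age=50, size_mm=20, nodes=0, grade=3, er="neg"),
            ER_NEG, model, treatments=("hormone",),
        )
    with pytest.raises(ConfigurationError):
        pb.linear_predictor(er_pos_patient, ER_POS, model, treatments=("voodoo",))


@pytest.mark.parametrize(
    "age, expected",
    [
        (65.0, (6.5**2 - 34.234) * 0.0698),
        (40.0, (4.0**2 - 34.234) * 0.0698),
        (10 * math.sqrt(34.234), 0.0),
    ],
)
def test_mortality_index(age, expected, model):
    assert pb.mortality_index(age, model) == pytest.approx(expected, abs=1e-12)


def test_mortality_index_rejects_nonpositive_age(model):
    with pytest.raises(InvalidInputError):
        pb.mortality_index(0.0, model)


# ---------------------------------------------------------------------------
# Baselines and absolute mortality
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "endpoint, t, expected",
    [
        (ER_NEG, 10.0, -1.156 + 0.4707 / 100 - 3.514 / 10),
        (ER_POS, 10.0, 0.7424 - 7.530 / math.sqrt(10) - 1.813 * math.log(10) / math.sqrt(10)),
        (OTHER, 10.0, -6.053 + 1.080 * math.log(10) + 0.3255 * math.sqrt(10)),
        (ER_NEG, 5.0, -1.156 + 0.4707 / 25 - 3.514 / 5),
    ],
)
def test_baseline_log_cumhaz_matches_printed_polynomials(endpoint, t, expected, model):
    assert pb.baseline_log_cumhaz(t, endpoint, model) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("t", [0.5, 0.0, 10.5, float("nan")])
def test_baseline_rejects_out_of_horizon_times(t, model):
    with pytest.raises(HorizonError):
        pb.baseline_log_cumhaz(t, ER_NEG, model)


def test_absolute_mortality_hand_chain(model):
    """Full worked chain: PI=1.3063, MI(65), t=10, ER-positive."""
    mi = (6.5**2 - 34.234) * 0.0698
    lam_b = math.exp(0.7424 - 7.530 / math.sqrt(10) - 1.813 * math.log(10) / math.sqrt(10))
    lam_o = math.exp(-6.053 + 1.080 * math.log(10) + 0.3255 * math.sqrt(10))
    h_b = 1 - math.exp(-math.exp(1.3063) * lam_b)
    h_o = 1 - math.exp(-math.exp(mi) * lam_o)
    r = pb.absolute_mortality(1.3063, mi, 10.0, ER_POS, model)
    assert r.h_breast == pytest.approx(h_b, abs=1e-12)
    assert r.h_other == pytest.approx(h_o, abs=1e-12)
    assert r.risk_breast == pytest.approx(h_b * (1 - h_o), abs=1e-12)
    # sanity echo of the rounded worked figures (intermediate rounding there)
    assert r.h_breast == pytest.approx(0.1744, abs=2e-4)
    assert r.h_other == pytest.approx(0.1293, abs=2e-4)
    assert r.risk_breast == pytest.approx(0.1519, abs=2e-4)


def test_absolute_mortality_degenerate_other_mortality(model):
    """With MI -> -inf the other-cause risk vanishes and Rb = H_B."""
    r = pb.absolute_mortality(0.0, -np.inf, 10.0, ER_NEG, model)
    expected_hb = 1 - math.exp(-math.exp(-1.156 + 0.4707 / 100 - 3.514 / 10))
    assert r.h_other == 0.0
    assert r.h_breast == pytest.approx(expected_hb, abs=1e-12)
    assert r.risk_breast == pytest.approx(expected_hb, abs=1e-12)
    assert r.h_breast == pytest.approx(0.1995, abs=5e-5)


@given(
    pi=st.floats(-4, 3),
    mi=st.floats(-4, 2),
    t=st.floats(1.0, 10.0),
)
def test_competing_risk_identities(pi, mi, t, model):
    """Rb = H_B(1-H_O) and Ro = H_O(1-H_B) hold to machine precision."""
    r = pb.absolute_mortality(pi, mi, t, ER_POS, model)
    assert 0.0 <= r.h_breast <= 1.0 and 0.0 <= r.h_other <= 1.0
    assert r.risk_breast == pytest.approx(r.h_breast * (1 - r.h_other), abs=0, rel=1e-15)
    assert r.risk_other == pytest.approx(r.h_other * (1 - r.h_breast), abs=0, rel=1e-15)
    assert r.risk_breast <= r.h_breast
    assert r.risk_breast + r.risk_other <= 1.0


def test_h_breast_monotone_in_pi_and_t(model):
    """H_B strictly increases in PI and is non-decreasing in t on [1, 10]."""
    ts = np.linspace(1.0, 10.0, 181)
    for endpoint in (ER_NEG, ER_POS):
        lam = np.exp([pb.baseline_log_cumhaz(t, endpoint, model) for t in ts])
        assert np.all(np.diff(lam) > 0)  # all printed baselines rise on [1,10]
        pis = np.linspace(-3, 3, 61)
        h = 1 - np.exp(-np.exp(pis) * lam[-1])
        assert np.all(np.diff(h) > 0)


def test_pi_linear_in_coefficient_scaling(er_pos_patient, model):
    """Scaling every log HR by c scales PI by c (linearity in coefficients)."""
    c = 2.5
    scaled = dataclasses.replace(
        model,
        er_positive=tuple(
            dataclasses.replace(t, coefficient=c * t.coefficient) for t in model.er_positive
        ),
    )
    pi = pb.linear_predictor(er_pos_patient, ER_POS, model)
    pi_scaled = pb.linear_predictor(er_pos_patient, ER_POS, scaled)
    assert pi_scaled == pytest.approx(c * pi, rel=1e-12)


def test_baseline_reproduced_at_centering_point(model):
    """All covariates at their centering points + zero grade effect => PI=0,
    so H_B equals the baseline risk exactly."""
    zeroed = dataclasses.replace(
        model,
        er_negative=tuple(
            dataclasses.replace(t, coefficient=0.0) if t.variable == "grade" else t
            for t in model.er_negative
        ),
    )
    nodes_center = 10.0 / 1.72**2 - 1.0  # solves 1/sqrt((n+1)/10) = 1.72
    patient_df = pd.DataFrame(
        [{"age": 56.325, "size_mm": 100 * 0.5090**2, "nodes": nodes_center, "grade": 2, "er": "neg"}]
    )
    # nodes_center is not an integer; bypass the integer check by scoring terms
    terms = [t.basis(patient_df[t.variable]) for t in zeroed.er_negative]
    pi = sum(
        float(v[0]) * t.coefficient for v, t in zip(terms, zeroed.er_negative)
    )
    assert pi == pytest.approx(0.0, abs=1e-10)
    r = pb.absolute_mortality(pi, -np.inf, 10.0, ER_NEG, zeroed)
    assert r.h_breast == pytest.approx(
        1 - math.exp(-math.exp(pb.baseline_log_cumhaz(10.0, ER_NEG, model))), abs=1e-10
    )


# ---------------------------------------------------------------------------
# Treatment benefit
# ---------------------------------------------------------------------------


def test_treatment_benefit_empty_and_null_hr(er_pos_patient, model):
    assert pb.treatment_benefit(er_pos_patient, (), 10.0, model) == []
    null = dataclasses.replace(
        model,
        treatments={
            "hormone": dataclasses.replace(model.treatments["hormone"], log_hr=0.0),
            "chemotherapy": model.treatments["chemotherapy"],
        },
    )
    steps = pb.treatment_benefit(er_pos_patient, ("hormone",), 10.0, null)
    assert steps[0].benefit_over_untreated == pytest.approx(0.0, abs=1e-15)


def test_treatment_benefit_matches_direct_recomputation(er_pos_patient, model):
    """Hormone benefit equals Rb(PI) - Rb(PI + logHR) at the patient's MI."""
    pi = pb.linear_predictor(er_pos_patient, ER_POS, model)
    mi = pb.mortality_index(40.0, model)
    rb0 = pb.absolute_mortality(pi, mi, 10.0, ER_POS, model).risk_breast
    rb1 = pb.absolute_mortality(pi - 0.386, mi, 10.0, ER_POS, model).risk_breast
    steps = pb.treatment_benefit(er_pos_patient, ("hormone",), 10.0, model)
    assert steps[0].log_hr == -0.386
    assert steps[0].benefit_over_untreated == pytest.approx(rb0 - rb1, abs=1e-12)
    assert steps[0].benefit_over_untreated > 0


def test_treatment_benefit_order_and_decomposition(er_pos_patient, model):
    """Hormone is decomposed first; increments sum to the combined benefit."""
    steps = pb.treatment_benefit(er_pos_patient, ("chemotherapy", "hormone"), 10.0, model)
    assert [s.treatment for s in steps] == ["hormone", "chemotherapy"]
    total = steps[-1].benefit_over_untreated
    assert sum(s.benefit_over_previous for s in steps) == pytest.approx(total, abs=1e-12)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def test_model_round_trip_is_lossless(model, patient_panel):
    clone = pb.ModelCoefficients.from_json(model.to_json())
    a = pb.score_cohort(patient_panel, t=10.0, model=model)
    b = pb.score_cohort(patient_panel, t=10.0, model=clone)
    pd.testing.assert_frame_equal(a, b)


def test_model_schema_errors():
    with pytest.raises(pb.SchemaError):
        pb.ModelCoefficients.from_dict({"schema_version": 99})
    with pytest.raises(pb.SchemaError):
        pb.ModelCoefficients.from_json("{not json")
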