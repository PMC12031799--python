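"""Variable selection, OR-ratio weights, and per-patient scoring."""

import pytest
from hypothesis import given, settings, strategies as st

import vurscore as vs
from vurscore.association import ContingencyTable2x2, assess_table
from vurscore.scoring import (
    CollinearityGroups,
    ScoreDistribution,
    assign_weights,
    compute_score,
    score_cohort,
    select_variables,
)


def _result(variable, or_point, p_value=0.001):
    """A minimal AssociationResult stand-in built through the real dataclass."""
    return vs.AssociationResult(
        variable=variable,
        table=ContingencyTable2x2(1, 1, 1, 1),
        chi2=0.0,
        p_value=p_value,
        or_point=or_point,
        ci_low=or_point / 2,
        ci_high=or_point * 2,
        haldane_applied=False,
        significant=p_value < 0.05,
    )


# -- selection ---------------------------------------------------------------


def test_reference_screen_selects_the_five_model_variables(reference_screen):
    selected = select_variables(reference_screen)
    assert [r.variable for r in selected] == [
        "age_lt2", "male", "non_ecoli", "utd_p3", "multiple_scars",
    ]


def test_highest_or_wins_within_group():
    groups = CollinearityGroups({"ultrasound": ("usg_abnormal", "hydronephrosis", "utd_p3")})
    results = [
        _result("usg_abnormal", 2.7),
        _result("hydronephrosis", 4.5),
        _result("utd_p3", 5.9),
    ]
    assert [r.variable for r in select_variables(results, groups)] == ["utd_p3"]


def test_non_significant_singleton_excluded():
    results = [_result("male", 2.0), _result("uti", 1.5, p_value=0.30)]
    groups = CollinearityGroups({})
    assert [r.variable for r in select_variables(results, groups)] == ["male"]


def test_empty_selection_is_degenerate():
    with pytest.raises(vs.ModelDegenerateError):
        select_variables([_result("male", 2.0, p_value=0.9)], CollinearityGroups({}))


def test_group_tie_keeps_first_listed():
    groups = CollinearityGroups({"g": ("x1", "x2")})
    results = [_result("x1", 3.0), _result("x2", 3.0)]
    assert [r.variable for r in select_variables(results, groups)] == ["x1"]


def test_overlapping_groups_rejected():
    with pytest.raises(vs.ParameterError):
        CollinearityGroups({"g1": ("a", "b"), "g2": ("b",)})


# -- weights -----------------------------------------------------------------


def test_reference_ors_give_1_1_1_2_2():
    spec = assign_weights(
        {"age_lt2": 1.8, "male": 2.2, "non_ecoli": 2.6, "utd_p3": 5.9,
         "multiple_scars": 5.5}
    )
    assert dict(spec.entries) == {
        "age_lt2": 1, "male": 1, "non_ecoli": 1, "utd_p3": 2, "multiple_scars": 2,
    }
    assert spec.max_score == 7
    assert spec.min_or_anchor == pytest.approx(1.8)


def test_equal_ors_all_weight_one():
    spec = assign_weights({"a": 3.3, "b": 3.3, "c": 3.3})
    assert set(spec.entries.values()) == {1}


@pytest.mark.parametrize(
    "ors, expected",
    [({"a": 2.0, "b": 2.9}, {"a": 1, "b": 1}), ({"a": 2.0, "b": 3.1}, {"a": 1, "b": 2})],
)
def test_round_half_up_boundary(ors, expected):
    # ratio 1.45 rounds down, 1.55 rounds up
    assert dict(assign_weights(ors).entries) == expected


def test_ratio_exactly_half_rounds_up():
    assert dict(assign_weights({"a": 2.0, "b": 3.0}).entries) == {"a": 1, "b": 2}


@given(
    ors=st.lists(st.floats(min_value=0.2, max_value=50), min_size=1, max_size=6),
    scale=st.floats(min_value=0.01, max_value=100),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_weights_scale_invariant_and_monotone(ors, scale):
    named = {f"v{i}": o for i, o in enumerate(ors)}
    spec = assign_weights(named)
    rescaled = assign_weights({k: v * scale for k, v in named.items()})
    assert dict(spec.entries) == dict(rescaled.entries)
    ordered = sorted(named, key=named.get)
    weights = [spec.entries[v] for v in ordered]
    assert weights == sorted(weights)  # OR_i >= OR_j => w_i >= w_j


def test_nonpositive_or_rejected():
    with pytest.raises(vs.ParameterError):
        assign_weights({"a": 0.0})


def test_weight_ceiling_configurable():
    spec = assign_weights({"a": 1.0, "b": 10.0}, ceiling=5)
    assert spec.entries["b"] == 5


def test_weightspec_json_round_trip(reference_weights, tmp_path):
    path = tmp_path / "w.json"
    reference_weights.to_json(path)
    back = vs.WeightSpec.from_json(path)
    assert dict(back.entries) == dict(reference_weights.entries)
    assert back.min_or_anchor == pytest.approx(reference_weights.min_or_anchor)


# -- scoring -----------------------------------------------------------------


def test_all_positive_scores_seven(tiny_cohort, reference_weights):
    assert compute_score(tiny_cohort.records[0], reference_weights) == 7


def test_all_negative_scores_zero(tiny_cohort, reference_weights):
    assert compute_score(tiny_cohort.records[1], reference_weights) == 0


def test_missing_modality_caps_score(reference_weights):
    rec = vs.PatientRecord(
        patient_id="x", age_lt2=0, male=1, uti=0, recurrent_uti=0, non_ecoli=0,
        usg_abnormal=1, hydronephrosis=1, utd_p3=1, dmsa_done=0,
        any_scar=None, multiple_scars=None, severe_vur=0,
    )
    assert compute_score(rec, reference_weights) == 3  # 1 (male) + 2 (UTD-P3)
    assert reference_weights.capped_max_score("dmsa_done") == 5


def test_score_additivity_single_flip(reference_weights):
    base = dict(
        patient_id="x", age_lt2=0, male=0, uti=1, recurrent_uti=0, non_ecoli=1,
        usg_abnormal=0, hydronephrosis=0, utd_p3=0, dmsa_done=1,
        any_scar=0, multiple_scars=0, severe_vur=0,
    )
    s0 = compute_score(vs.PatientRecord(**base), reference_weights)
    flipped = dict(base, age_lt2=1)
    s1 = compute_score(vs.PatientRecord(**flipped), reference_weights)
    assert s1 - s0 == reference_weights.entries["age_lt2"]


def test_reference_cohort_scores_reproduce_score_table(
    reference_cohort, reference_weights, fixture_set
):
    _, dist = score_cohort(reference_cohort, reference_weights)
    assert dist.n0 == fixture_set.table2.n0
    assert dist.n1 == fixture_set.table2.n1


def test_reference_cohort_981_63_split(reference_cohort, reference_weights):
    scores, _ = score_cohort(reference_cohort, reference_weights)
    assert (scores <= 4).sum() == 981
    assert (scores >= 5).sum() == 63


def test_single_patient_distribution(tiny_cohort, reference_weights):
    single = vs.Cohort((tiny_cohort.records[0],))
    _, dist = score_cohort(single, reference_weights)
    assert dist.total == 1
    assert dist.n1[7] == 1


def test_score_distribution_counts_conserved(reference_cohort, reference_weights):
    _, dist = score_cohort(reference_cohort, reference_weights)
    assert dist.total == len(reference_cohort)


def test_unknown_spec_variable_is_lookup_error(tiny_cohort):
    bogus = vs.WeightSpec(entries={"creatinine": 1}, ors={"creatinine": 2.0},
                          min_or_anchor=2.0)
    with pytest.raises(vs.SchemaError):
        compute_score(tiny_cohort.records[0], bogus)


def test_score_distribution_rejects_negative_counts():
    with pytest.raises(vs.ParameterError):
        ScoreDistribution((1, -1), (0, 0))
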