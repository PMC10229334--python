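"""The NDS rubric: category ratings, totals, the SE convention, and the
structural properties of the scale (completeness, monotonicity, range,
determinism)."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nds.records import (
    CerebellarFindings,
    NeuroExamRecord,
    RecordValidationError,
    VisionFindings,
    maximal_record,
    normal_record,
    validate_record,
)
from nds.scale import (
    BINARY_ITEMS,
    CATEGORIES,
    MAX_TOTAL,
    SE_CONVENTION_TOTAL,
    apply_se_convention,
    rate_category,
    score_record,
)

CEREBRAL_SIGNS = (
    "disorientation",
    "obtundation",
    "behavior_change",
    "stupor",
    "coma",
    "compulsive_circling",
    "head_pressing",
)
BRAINSTEM_SIGNS = (
    "facial_nerve_dysfunction",
    "positional_pathological_nystagmus",
    "trigeminal_dysfunction",
    "hypoglossal_dysfunction",
    "persistent_pathological_nystagmus",
    "dysphagia",
    "laryngeal_dysfunction",
)
POSTURAL_SIGNS = (
    "head_tilt",
    "head_turn",
    "pleurothotonus",
    "decerebellate_rigidity",
    "decerebrate_rigidity",
)
MENACE = ("normal", "reduced_with_impaired_vision", "absent_with_impaired_vision")


def subsets(items):
    for r in range(len(items) + 1):
        yield from (set(c) for c in itertools.combinations(items, r))


# ---------------------------------------------------------------- rubric rows


@pytest.mark.parametrize(
    "history, expected",
    [("none", 0), ("controlled", 1), ("cluster_or_refractory", 2),
     ("status_epilepticus", 3)],
)
def test_seizure_rows(history, expected):
    record = NeuroExamRecord(subject_id="d", seizure_history_7d=history)
    assert rate_category("seizure", record) == expected


@pytest.mark.parametrize(
    "status, expected",
    [("normal", 0), ("ambulatory_mild_deficit", 1),
     ("ambulatory_frequent_falling", 2), ("nonambulatory", 3)],
)
def test_ambulatory_rows(status, expected):
    record = NeuroExamRecord(subject_id="d", ambulatory=status)
    assert rate_category("ambulatory", record) == expected


@pytest.mark.parametrize(
    "signs, expected",
    [
        (set(), 0),
        ({"obtundation"}, 1),
        ({"disorientation"}, 1),
        ({"disorientation", "obtundation"}, 2),
        ({"disorientation", "obtundation", "behavior_change"}, 2),
        ({"compulsive_circling"}, 3),
        ({"head_pressing"}, 3),
        ({"stupor"}, 3),
        ({"coma", "disorientation", "behavior_change"}, 3),  # capped at 3
    ],
)
def test_cerebral_rows(signs, expected):
    record = NeuroExamRecord(subject_id="d", cerebral_signs=signs)
    assert rate_category("cerebral", record) == expected


@pytest.mark.parametrize(
    "severity, tremors, expected",
    [
        ("none", False, 0),
        ("mild", False, 1),
        ("moderate", False, 1),  # no rubric row of its own; graded with mild
        ("mild", True, 2),
        ("moderate", True, 2),
        ("severe", False, 3),
        ("severe", True, 3),
    ],
)
def test_cerebellar_rows(severity, tremors, expected):
    record = NeuroExamRecord(
        subject_id="d",
        cerebellar=CerebellarFindings(
            severity=severity, truncal_sway=True, tremors=tremors
        ),
    )
    assert rate_category("cerebellar", record) == expected


def test_cerebellar_flags_without_ataxia_rate_zero():
    record = NeuroExamRecord(
        subject_id="d",
        cerebellar=CerebellarFindings(severity="none", tremors=True, hypermetria=True),
    )
    assert rate_category("cerebellar", record) == 0


@pytest.mark.parametrize(
    "signs, expected",
    [
        (set(), 0),
        ({"facial_nerve_dysfunction"}, 1),
        ({"positional_pathological_nystagmus"}, 1),
        ({"trigeminal_dysfunction"}, 2),
        ({"persistent_pathological_nystagmus", "facial_nerve_dysfunction"}, 2),
        ({"dysphagia"}, 3),
        ({"laryngeal_dysfunction", "hypoglossal_dysfunction"}, 3),
    ],
)
def test_brainstem_rows(signs, expected):
    record = NeuroExamRecord(subject_id="d", brainstem_signs=signs)
    assert rate_category("brainstem", record) == expected


@pytest.mark.parametrize(
    "left, right, expected",
    [
        ("normal", "normal", 0),
        ("reduced_with_impaired_vision", "normal", 1),
        ("normal", "reduced_with_impaired_vision", 1),
        ("reduced_with_impaired_vision", "reduced_with_impaired_vision", 2),
        ("absent_with_impaired_vision", "normal", 2),
        ("absent_with_impaired_vision", "reduced_with_impaired_vision", 2),
        ("absent_with_impaired_vision", "absent_with_impaired_vision", 3),
    ],
)
def test_visual_rows(left, right, expected):
    record = NeuroExamRecord(
        subject_id="d", vision=VisionFindings(left=left, right=right)
    )
    assert rate_category("visual", record) == expected


@pytest.mark.parametrize(
    "signs, expected",
    [
        (set(), 0),
        ({"head_tilt"}, 1),
        ({"head_turn"}, 1),
        ({"head_tilt", "head_turn"}, 2),
        ({"pleurothotonus"}, 2),
        ({"decerebellate_rigidity"}, 3),
        ({"decerebrate_rigidity", "head_tilt"}, 3),
    ],
)
def test_postural_rows(signs, expected):
    record = NeuroExamRecord(subject_id="d", posture=signs)
    assert rate_category("postural", record) == expected


# ------------------------------------------------------------------- scoring


def test_maximal_record_totals_21_on_final_scale(maximal):
    sheet = score_record(maximal, "final7")
    assert sheet.total == 21 == MAX_TOTAL["final7"]
    assert all(r == 3 for r in sheet.category_ratings.values())
    assert sheet.binary_items is None


def test_normal_record_totals_zero(normal):
    sheet = score_record(normal, "final7")
    assert sheet.total == 0
    assert all(r == 0 for r in sheet.category_ratings.values())


def test_pilot_scale_adds_binary_points(normal, maximal):
    hyper = normal.model_copy(update={"hyperesthesia": True})
    sheet = score_record(hyper, "pilot9")
    assert sheet.total == 1
    assert sheet.binary_items == {"hyperesthesia": 1, "proprioceptive_deficits": 0}
    assert score_record(maximal, "pilot9").total == 23 == MAX_TOTAL["pilot9"]
    assert set(BINARY_ITEMS) == {"hyperesthesia", "proprioceptive_deficits"}


def test_binary_weight_is_configurable(normal):
    both = normal.model_copy(
        update={"hyperesthesia": True, "proprioceptive_deficits": True}
    )
    assert score_record(both, "pilot9", binary_weight=2).total == 4


def test_final_scale_has_exactly_seven_ordinal_categories():
    assert len(CATEGORIES) == 7
    assert set(CATEGORIES) == {
        "ambulatory", "cerebral", "cerebellar", "brainstem",
        "visual", "postural", "seizure",
    }


def test_scoring_is_deterministic(maximal):
    assert score_record(maximal) == score_record(maximal)


def test_unknown_category_rejected(normal):
    with pytest.raises(KeyError, match="unknown category"):
        rate_category("spinal", normal)


def test_contradictory_record_raises(make_record):
    bad = make_record(cerebral_signs={"stupor", "coma"})
    with pytest.raises(RecordValidationError, match="stupor and coma"):
        rate_category("cerebral", bad)
    with pytest.raises(RecordValidationError):
        score_record(bad)


# -------------------------------------------------------------- SE convention


def test_se_convention_ratings_and_total(se_record):
    sheet = apply_se_convention(se_record)
    for cat in ("ambulatory", "cerebral", "visual", "seizure"):
        assert sheet.category_ratings[cat] == 3
    for cat in ("cerebellar", "brainstem", "postural"):
        assert sheet.category_ratings[cat] == 0
    assert sheet.total == SE_CONVENTION_TOTAL == 12


def test_se_convention_rejects_non_se_record(normal):
    with pytest.raises(ValueError, match="not in status epilepticus"):
        apply_se_convention(normal)


# ------------------------------------- completeness and monotonicity (exhaustive)


def test_cerebral_rubric_is_total_and_monotone():
    """Every admissible sign set maps to exactly one rating, and adding a
    sign never lowers it (worst-deficit rule)."""
    for signs in subsets(CEREBRAL_SIGNS):
        if {"stupor", "coma"} <= signs:
            continue
        record = NeuroExamRecord(subject_id="d", cerebral_signs=signs)
        rating = rate_category("cerebral", record)
        assert rating in (0, 1, 2, 3)
        for extra in set(CEREBRAL_SIGNS) - signs:
            grown = signs | {extra}
            if {"stupor", "coma"} <= grown:
                continue
            bigger = NeuroExamRecord(subject_id="d", cerebral_signs=grown)
            assert rate_category("cerebral", bigger) >= rating


@pytest.mark.parametrize(
    "category, universe, field",
    [
        ("brainstem", BRAINSTEM_SIGNS, "brainstem_signs"),
        ("postural", POSTURAL_SIGNS, "posture"),
    ],
)
def test_set_categories_are_total_and_monotone(category, universe, field):
    for signs in subsets(universe):
        record = NeuroExamRecord(subject_id="d", **{field: signs})
        rating = rate_category(category, record)
        assert rating in (0, 1, 2, 3)
        for extra in set(universe) - signs:
            bigger = NeuroExamRecord(subject_id="d", **{field: signs | {extra}})
            assert rate_category(category, bigger) >= rating


def test_visual_rating_monotone_in_per_eye_severity():
    for left, right in itertools.product(MENACE, MENACE):
        record = NeuroExamRecord(
            subject_id="d", vision=VisionFindings(left=left, right=right)
        )
        rating = rate_category("visual", record)
        for worse in MENACE[MENACE.index(left) :]:
            worse_rec = NeuroExamRecord(
                subject_id="d", vision=VisionFindings(left=worse, right=right)
            )
            assert rate_category("visual", worse_rec) >= rating


def test_cerebellar_rating_monotone_over_valid_combinations():
    severities = ("none", "mild", "moderate", "severe")
    flags = list(itertools.product([False, True], repeat=3))
    ratings = {}
    for sev, (sway, hyper, trem) in itertools.product(severities, flags):
        record = NeuroExamRecord(
            subject_id="d",
            cerebellar=CerebellarFindings(
                severity=sev, truncal_sway=sway, hypermetria=hyper, tremors=trem
            ),
        )
        if validate_record(record):
            continue
        ratings[(sev, sway, hyper, trem)] = rate_category("cerebellar", record)
    for (sev, sway, hyper, trem), rating in ratings.items():
        assert rating in (0, 1, 2, 3)
        worse_sev = severities[severities.index(sev) :]
        for sev2 in worse_sev:
            key = (sev2, sway, hyper, trem)
            if key in ratings:
                assert ratings[key] >= rating
        if (sev, sway, hyper, True) in ratings:
            assert ratings[(sev, sway, hyper, True)] >= rating


# -------------------------------------------------- randomized whole-record


@st.composite
def valid_records(draw):
    severity = draw(st.sampled_from(["none", "mild", "moderate", "severe"]))
    sway = draw(st.booleans())
    hyper = draw(st.booleans())
    trem = draw(st.booleans())
    if severity in ("mild", "moderate") and not (sway or hyper):
        sway = True
    if severity == "severe" and not (sway or hyper or trem):
        trem = True
    cerebral = draw(
        st.sets(st.sampled_from(CEREBRAL_SIGNS)).filter(
            lambda s: not {"stupor", "coma"} <= s
        )
    )
    return NeuroExamRecord(
        subject_id="d",
        ambulatory=draw(
            st.sampled_from(
                ["normal", "ambulatory_mild_deficit",
                 "ambulatory_frequent_falling", "nonambulatory"]
            )
        ),
        cerebral_signs=cerebral,
        cerebellar=CerebellarFindings(
            severity=severity, truncal_sway=sway, hypermetria=hyper, tremors=trem
        ),
        brainstem_signs=draw(st.sets(st.sampled_from(BRAINSTEM_SIGNS))),
        vision=VisionFindings(
            left=draw(st.sampled_from(MENACE)), right=draw(st.sampled_from(MENACE))
        ),
        posture=draw(st.sets(st.sampled_from(POSTURAL_SIGNS))),
        seizure_history_7d=draw(
            st.sampled_from(
                ["none", "controlled", "cluster_or_refractory", "status_epilepticus"]
            )
        ),
        hyperesthesia=draw(st.booleans()),
        proprioceptive_deficits=draw(st.booleans()),
    )


@settings(max_examples=200, derandomize=True)
@given(record=valid_records())
def test_totals_are_sums_within_range(record):
    for version in ("final7", "pilot9"):
        sheet = score_record(record, version)
        expected = sum(sheet.category_ratings.values())
        if version == "pilot9":
            expected += sum(sheet.binary_items.values())
        assert sheet.total == expected
        assert 0 <= sheet.total <= MAX_TOTAL[version]
        assert all(r in (0, 1, 2, 3) for r in sheet.category_ratings.values())
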