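"""The canine meningoencephalitis neurodisability scale (NDS) rubric.

The NDS grades dysfunction 0-3 in seven categories — ambulatory status,
cerebral functions, cerebellar functions, brainstem functions, visual
functions, postural abnormalities, and seizures within the previous 7 days —
and totals them, giving 0 (normal) to a theoretical maximum of 21 (severe
disability). A 9-item pilot variant adds two binary items (hyperesthesia and
proprioceptive deficits); these showed poor inter-rater reliability and were
dropped from the final scale, but remain available here as ``pilot9``.

When a record satisfies the criteria of more than one row of a category, the
highest applicable rating is assigned (worst-deficit grading). Scoring is a
pure function of the record: the same record always yields the same sheet.

Patients presenting *in* status epilepticus cannot be examined meaningfully
(unconscious, recumbent, sedated); for them a fixed convention assigns the
maximum rating of 3 in the ambulatory, cerebral, visual, and seizure
categories and 0 in all other categories (total 12) — see
:func:`apply_se_convention`.
"""

from __future__ import annotations

from typing import Dict, Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .records import NeuroExamRecord, require_valid

ScaleVersion = Literal["final7", "pilot9"]

#: The seven ordinal categories of the final scale, in score-sheet order.
CATEGORIES = (
    "ambulatory",
    "cerebral",
    "cerebellar",
    "brainstem",
    "visual",
    "postural",
    "seizure",
)

#: The two binary items of the pilot scale.
BINARY_ITEMS = ("hyperesthesia", "proprioceptive_deficits")

MAX_TOTAL = {"final7": 21, "pilot9": 23}

#: Total assigned by the status-epilepticus convention (3+3+3+3).
SE_CONVENTION_TOTAL = 12


class NDSScoreSheet(BaseModel):
    """A completed NDS sheet: one rating per category plus the total."""

    model_config = ConfigDict(extra="forbid")

    subject_id: str
    rater_id: Optional[str] = None
    scale_version: ScaleVersion = "final7"
    category_ratings: Dict[str, int]
    binary_items: Optional[Dict[str, int]] = None
    total: int

    @model_validator(mode="after")
    def _check_consistency(self) -> "NDSScoreSheet":
        if set(self.category_ratings) != set(CATEGORIES):
            raise ValueError(f"category_ratings must cover exactly {CATEGORIES}")
        for cat, r in self.category_ratings.items():
            if r not in (0, 1, 2, 3):
                raise ValueError(f"rating for {cat!r} must be in 0..3, got {r}")
        expected = sum(self.category_ratings.values())
        if self.scale_version == "pilot9":
            if self.binary_items is None or set(self.binary_items) != set(BINARY_ITEMS):
                raise ValueError(f"pilot9 sheets must carry binary items {BINARY_ITEMS}")
            expected += sum(self.binary_items.values())
        elif self.binary_items is not None:
            raise ValueError("final7 sheets carry no binary items")
        if self.total != expected:
            raise ValueError(f"total {self.total} != sum of ratings {expected}")
        if not 0 <= self.total <= MAX_TOTAL[self.scale_version]:
            raise ValueError(f"total out of range for {self.scale_version}")
        return self


_AMBULATORY_RATING = {
    "normal": 0,
    "ambulatory_mild_deficit": 1,          # mild paresis/ataxia, no falling
    "ambulatory_frequent_falling": 2,      # moderate/severe paresis/ataxia
    "nonambulatory": 3,
}

_SEIZURE_RATING = {
    "none": 0,
    "controlled": 1,
    "cluster_or_refractory": 2,
    "status_epilepticus": 3,
}

# Cerebral row 3 signs; row 1/2 count how many of the milder triad are present.
_CEREBRAL_SEVERE = {"stupor", "coma", "compulsive_circling", "head_pressing"}
_CEREBRAL_MILD_TRIAD = {"disorientation", "obtundation", "behavior_change"}

_BRAINSTEM_MILD = {"facial_nerve_dysfunction", "positional_pathological_nystagmus"}
_BRAINSTEM_MODERATE = {
    "trigeminal_dysfunction",
    "hypoglossal_dysfunction",
    "persistent_pathological_nystagmus",
}
_BRAINSTEM_SEVERE = {"dysphagia", "laryngeal_dysfunction"}


def _rate_cerebral(record: NeuroExamRecord) -> int:
    signs = record.cerebral_signs
    if signs & _CEREBRAL_SEVERE:
        # stupor/coma/circling/head pressing cap the category at 3 regardless
        # of any accompanying disorientation, obtundation or behaviour change
        return 3
    n_mild = len(signs & _CEREBRAL_MILD_TRIAD)
    if n_mild >= 2:
        return 2
    return 1 if n_mild == 1 else 0


def _rate_cerebellar(record: NeuroExamRecord) -> int:
    cb = record.cerebellar
    if cb.severity == "severe":
        return 3
    if cb.severity in ("mild", "moderate") and cb.tremors:
        return 2
    # Moderate ataxia without tremors has no rubric row of its own; it is
    # graded 1 with mild ataxia rather than falling through to 0.
    if cb.severity in ("mild", "moderate"):
        return 1
    return 0


def _rate_brainstem(record: NeuroExamRecord) -> int:
    signs = record.brainstem_signs
    if signs & _BRAINSTEM_SEVERE:
        return 3
    if signs & _BRAINSTEM_MODERATE:
        return 2
    return 1 if signs & _BRAINSTEM_MILD else 0


def _rate_visual(record: NeuroExamRecord) -> int:
    eyes = (record.vision.left, record.vision.right)
    n_absent = eyes.count("absent_with_impaired_vision")
    n_reduced = eyes.count("reduced_with_impaired_vision")
    if n_absent == 2:
        return 3
    # One eye absent (other normal or reduced), or both eyes reduced.
    if n_absent == 1 or n_reduced == 2:
        return 2
    return 1 if n_reduced == 1 else 0


def _rate_postural(record: NeuroExamRecord) -> int:
    signs = record.posture
    if signs & {"decerebellate_rigidity", "decerebrate_rigidity"}:
        return 3
    if "pleurothotonus" in signs or {"head_tilt", "head_turn"} <= signs:
        return 2
    return 1 if signs & {"head_tilt", "head_turn"} else 0


_RATERS = {
    "ambulatory": lambda r: _AMBULATORY_RATING[r.ambulatory],
    "cerebral": _rate_cerebral,
    "cerebellar": _rate_cerebellar,
    "brainstem": _rate_brainstem,
    "visual": _rate_visual,
    "postural": _rate_postural,
    "seizure": lambda r: _SEIZURE_RATING[r.seizure_history_7d],
}


def rate_category(category: str, record: NeuroExamRecord) -> int:
    """Rate one ordinal category (0-3) for a validated exam record.

    The rating is that of the highest-severity rubric row whose criteria the
    record satisfies; 0 if no row applies.

    Raises
    ------
    KeyError
        If ``category`` is not one of the seven ordinal categories.
    RecordValidationError
        If the record breaks a record invariant (e.g. stupor and coma both
        flagged).
    """
    if category not in _RATERS:
        raise KeyError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        )
    require_valid(record)
    return _RATERS[category](record)


def score_record(
    record: NeuroExamRecord,
    scale_version: ScaleVersion = "final7",
    rater_id: Optional[str] = None,
    binary_weight: int = 1,
) -> NDSScoreSheet:
    """Score a record on the final 7-category scale or the 9-item pilot.

    The total is the sum of the seven category ratings; under ``pilot9`` each
    binary item present contributes ``binary_weight`` (default 1) point.
    """
    require_valid(record)
    ratings = {cat: _RATERS[cat](record) for cat in CATEGORIES}
    total = sum(ratings.values())
    binary: Optional[Dict[str, int]] = None
    if scale_version == "pilot9":
        binary = {
            "hyperesthesia": binary_weight if record.hyperesthesia else 0,
            "proprioceptive_deficits": binary_weight
            if record.proprioceptive_deficits
            else 0,
        }
        total += sum(binary.values())
    return NDSScoreSheet(
        subject_id=record.subject_id,
        rater_id=rater_id,
        scale_version=scale_version,
        category_ratings=ratings,
        binary_items=binary,
        total=total,
    )


def apply_se_convention(
    record: NeuroExamRecord, rater_id: Optional[str] = None
) -> NDSScoreSheet:
    """Score a patient presenting in status epilepticus by the fixed convention.

    Assigns the maximum rating of 3 in the ambulatory, cerebral, visual, and
    seizure categories and 0 in all other categories, for a total of 12.

    Raises
    ------
    ValueError
        If the record is not flagged ``in_status_epilepticus``.
    """
    if not record.in_status_epilepticus:
        raise ValueError(
            f"record {record.subject_id!r} is not in status epilepticus; "
            "the SE scoring convention does not apply"
        )
    ratings = {cat: 0 for cat in CATEGORIES}
    for cat in ("ambulatory", "cerebral", "visual", "seizure"):
        ratings[cat] = 3
    return NDSScoreSheet(
        subject_id=record.subject_id,
        rater_id=rater_id,
        scale_version="final7",
        category_ratings=ratings,
        total=SE_CONVENTION_TOTAL,
    )
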