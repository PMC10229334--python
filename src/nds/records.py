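"""Structured neurological-exam records for dogs with meningoencephalitis of
unknown origin (MUO).

A :class:`NeuroExamRecord` captures one assessment of one dog: the findings a
clinician judges at the bedside (gait status, cerebral signs, cerebellar
ataxia grade and its qualifiers, cranial-nerve deficits, per-eye menace
response, postural abnormalities, and the 7-day seizure history). Severity
adjectives such as *mild* / *moderate* / *severe* and "frequent falling" are
clinical judgements recorded as inputs; the scoring engine combines them but
never re-derives them from other findings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Set

from pydantic import BaseModel, ConfigDict, Field

AmbulatoryStatus = Literal[
    "normal",
    "ambulatory_mild_deficit",
    "ambulatory_frequent_falling",
    "nonambulatory",
]

CerebralSign = Literal[
    "disorientation",
    "obtundation",
    "behavior_change",
    "stupor",
    "coma",
    "compulsive_circling",
    "head_pressing",
]

CerebellarSeverity = Literal["none", "mild", "moderate", "severe"]

BrainstemSign = Literal[
    "facial_nerve_dysfunction",
    "positional_pathological_nystagmus",
    "trigeminal_dysfunction",
    "hypoglossal_dysfunction",
    "persistent_pathological_nystagmus",
    "dysphagia",
    "laryngeal_dysfunction",
]

MenaceStatus = Literal[
    "normal",
    "reduced_with_impaired_vision",
    "absent_with_impaired_vision",
]

PosturalSign = Literal[
    "head_tilt",
    "head_turn",
    "pleurothotonus",
    "decerebellate_rigidity",
    "decerebrate_rigidity",
]

SeizureHistory = Literal[
    "none",
    "controlled",
    "cluster_or_refractory",
    "status_epilepticus",
]
# "Refractory" means seizures requiring a dose increase of any antiepileptic
# drug or addition of a second medication; that judgement is made upstream and
# supplied as part of the seizure_history_7d flag, never computed here. The
# 7-day window is likewise closed and resolved upstream.


class CerebellarFindings(BaseModel):
    """Cerebellar ataxia grade plus the qualifying signs the rubric names."""

    model_config = ConfigDict(extra="forbid")

    severity: CerebellarSeverity = "none"
    truncal_sway: bool = False
    hypermetria: bool = False
    tremors: bool = False


class VisionFindings(BaseModel):
    """Menace-response status per eye, with impaired vision where reduced/absent."""

    model_config = ConfigDict(extra="forbid")

    left: MenaceStatus = "normal"
    right: MenaceStatus = "normal"


class NeuroExamRecord(BaseModel):
    """One neurological examination of one dog by one assessor.

    Field vocabulary follows the clinical-sign inventory of MUO presentations:
    proprioceptive deficits, obtundation, ataxia, visual deficits, head tilt,
    seizures, paresis, compulsive circling, hyperesthesia, behaviour changes,
    pathological nystagmus, hypermetria, head turn, cranial-nerve dysfunction
    and tremors. ``hyperesthesia`` and ``proprioceptive_deficits`` are the two
    binary items used only by the 9-item pilot scale.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    subject_id: str
    ambulatory: AmbulatoryStatus = "normal"
    cerebral_signs: Set[CerebralSign] = Field(default_factory=set)
    cerebellar: CerebellarFindings = Field(default_factory=CerebellarFindings)
    brainstem_signs: Set[BrainstemSign] = Field(default_factory=set)
    vision: VisionFindings = Field(default_factory=VisionFindings)
    posture: Set[PosturalSign] = Field(default_factory=set)
    seizure_history_7d: SeizureHistory = "none"
    hyperesthesia: bool = False
    proprioceptive_deficits: bool = False
    in_status_epilepticus: bool = False


@dataclass(frozen=True)
class Violation:
    """One broken record invariant, identified by a stable code."""

    code: str
    message: str


class RecordValidationError(ValueError):
    """Raised when an operation is given a record with invariant violations."""

    def __init__(self, subject_id: str, violations: list[Violation]):
        self.subject_id = subject_id
        self.violations = violations
        details = "; ".join(v.message for v in violations)
        super().__init__(f"invalid exam record {subject_id!r}: {details}")


def validate_record(record: NeuroExamRecord) -> list[Violation]:
    """Check the cross-field invariants of a record.

    Returns one :class:`Violation` per broken invariant (empty list means the
    record is well formed). Violations are returned, never raised, so callers
    can report every problem in a batch of records at once.
    """
    violations: list[Violation] = []
    if {"stupor", "coma"} <= record.cerebral_signs:
        violations.append(
            Violation(
                "stupor_coma_conflict",
                "stupor and coma are mutually exclusive levels of consciousness",
            )
        )
    cb = record.cerebellar
    if cb.severity in ("mild", "moderate") and not (cb.truncal_sway or cb.hypermetria):
        violations.append(
            Violation(
                "cerebellar_qualifier_missing",
                f"{cb.severity} cerebellar ataxia requires truncal sway or hypermetria",
            )
        )
    if cb.severity == "severe" and not (cb.truncal_sway or cb.hypermetria or cb.tremors):
        violations.append(
            Violation(
                "cerebellar_qualifier_missing",
                "severe cerebellar ataxia requires tremors, truncal sway, or hypermetria",
            )
        )
    return violations


def require_valid(record: NeuroExamRecord) -> None:
    """Raise :class:`RecordValidationError` if the record breaks any invariant."""
    violations = validate_record(record)
    if violations:
        raise RecordValidationError(record.subject_id, violations)


def normal_record(subject_id: str = "dog") -> NeuroExamRecord:
    """A neurologically normal record with no seizure history."""
    return NeuroExamRecord(subject_id=subject_id)


def maximal_record(subject_id: str = "dog") -> NeuroExamRecord:
    """A record meeting the most severe criteria of every ordinal category."""
    return NeuroExamRecord(
        subject_id=subject_id,
        ambulatory="nonambulatory",
        cerebral_signs={"stupor", "compulsive_circling", "head_pressing"},
        cerebellar=CerebellarFindings(
            severity="severe", truncal_sway=True, hypermetria=True, tremors=True
        ),
        brainstem_signs={"dysphagia", "laryngeal_dysfunction"},
        vision=VisionFindings(
            left="absent_with_impaired_vision", right="absent_with_impaired_vision"
        ),
        posture={"decerebrate_rigidity"},
        seizure_history_7d="status_epilepticus",
        hyperesthesia=True,
        proprioceptive_deficits=True,
    )
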