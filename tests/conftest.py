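import pytest

from nds.records import (
    CerebellarFindings,
    NeuroExamRecord,
    VisionFindings,
    maximal_record,
    normal_record,
)


@pytest.fixture
def normal():
    return normal_record("n1")


@pytest.fixture
def maximal():
    return maximal_record("m1")


@pytest.fixture
def make_record():
    """Factory for records with selective overrides of the normal baseline."""

    def _make(**kwargs) -> NeuroExamRecord:
        kwargs.setdefault("subject_id", "dog")
        return NeuroExamRecord(**kwargs)

    return _make


@pytest.fixture
def se_record():
    return NeuroExamRecord(
        subject_id="se1",
        seizure_history_7d="status_epilepticus",
        in_status_epilepticus=True,
    )


__all__ = ["CerebellarFindings", "VisionFindings"]
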