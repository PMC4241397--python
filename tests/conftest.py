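import pytest

from braincheck import (
    CohortRecord,
    IqcodeResponses,
    PatientResponses,
    default_rule_set,
    default_tree,
)
from braincheck.instrument import PATIENT_ITEMS

#: symptom questions denied, all clock criteria met
BENIGN_PROFILE = {q: False for q in PATIENT_ITEMS[:5]} | {
    c: True for c in PATIENT_ITEMS[5:]
}


@pytest.fixture
def rules():
    return default_rule_set()


@pytest.fixture
def tree():
    return default_tree()


@pytest.fixture
def make_patient():
    def _make(**overrides) -> PatientResponses:
        values = dict(BENIGN_PROFILE)
        values.update(overrides)
        return PatientResponses(**values)

    return _make


@pytest.fixture
def make_record(make_patient):
    """Factory for cohort records; ``iq`` is a constant rating for all 7 items."""

    def _make(label, iq=None, iq_items=None, id=None, **overrides) -> CohortRecord:
        if iq_items is None and iq is not None:
            iq_items = (iq,) * 7
        iqcode = IqcodeResponses(items=tuple(iq_items)) if iq_items is not None else None
        return CohortRecord(
            patient=make_patient(**overrides), label=label, iqcode=iqcode, id=id
        )

    return _make
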