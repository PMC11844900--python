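import pytest

from pehresponse import (
    Condition,
    Group,
    ParticipantRecord,
    SessionMeasurement,
    StudyDataset,
    Timepoint,
    generate_cohort,
)


@pytest.fixture
def toy_dataset() -> StudyDataset:
    """Two participants, one session measurement each."""
    return StudyDataset(
        participants=[
            ParticipantRecord(id="CAD001", group=Group.CAD),
            ParticipantRecord(id="CON001", group=Group.CON),
        ],
        measurements=[
            SessionMeasurement(
                participant_id="CAD001",
                condition=Condition.MOD,
                timepoint=Timepoint.PRE,
                hr=60.0,
                bsbp=112.0,
                bdbp=70.0,
                csbp=101.0,
            ),
            SessionMeasurement(
                participant_id="CON001",
                condition=Condition.MOD,
                timepoint=Timepoint.PRE,
                hr=63.0,
                bsbp=122.0,
                bdbp=77.0,
                csbp=122.0,
            ),
        ],
        provenance="toy",
    )


@pytest.fixture(scope="session")
def study_cohort():
    """One study-condition synthetic cohort (17 CAD + 18 CON) with truth."""
    return generate_cohort(seed=11)
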