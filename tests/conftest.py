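from datetime import date, datetime

import pytest

from cardioevent.ehr_model import (
    CodedDiagnosis,
    CodeSystem,
    Hospitalization,
    PatientRecord,
    PeriodOfInterest,
)
from cardioevent.phenotyper import AlgorithmConfig


@pytest.fixture(scope="session")
def period() -> PeriodOfInterest:
    """The 2010 surveillance year used throughout the tests."""
    return PeriodOfInterest(start=date(2010, 1, 1), end=date(2010, 12, 31))


@pytest.fixture(scope="session")
def config(period) -> AlgorithmConfig:
    return AlgorithmConfig(period=period)


def icd(code: str, position: int = 1) -> CodedDiagnosis:
    return CodedDiagnosis(system=CodeSystem.ICD9CM, code=code, position=position)


def imo(code: str, position: int = 1) -> CodedDiagnosis:
    return CodedDiagnosis(system=CodeSystem.IMO, code=code, position=position)


def stay(admit: str, discharge: str, diagnoses, elective: bool = False,
         procedures=()) -> Hospitalization:
    return Hospitalization(
        admit=datetime.fromisoformat(admit),
        discharge=datetime.fromisoformat(discharge),
        elective=elective,
        diagnoses=list(diagnoses),
        procedures=list(procedures),
    )


def patient(patient_id: str = "T-1", enrollment: str = "2006-06-01", **kw) -> PatientRecord:
    return PatientRecord(
        patient_id=patient_id, enrollment_start=date.fromisoformat(enrollment), **kw
    )
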