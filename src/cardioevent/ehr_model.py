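"""Domain types for a structured EHR extract and episode-of-care linkage.

One :class:`PatientRecord` holds everything the classification algorithms
consume for one patient: hospitalizations with ordered discharge diagnoses
and procedure codes, troponin/BNP results with assay upper limits of normal,
coded ECG interpretation statements, echocardiographic ejection fractions,
insurance claims, and the enrollment start date that anchors the
observation-time requirement.

Labs, ECGs and echos arrive as flat per-patient lists; :func:`link_episodes`
attaches them to hospitalizations by a date window to form episodes of care.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from enum import Enum
from typing import List

from pydantic import BaseModel, Field, field_validator, model_validator


class CodeSystem(str, Enum):
    """Coding system of a diagnosis or procedure code."""

    ICD9CM = "ICD9CM"
    IMO = "IMO"
    ICD9PROC = "ICD9PROC"
    CPT4 = "CPT4"


class PlaceOfService(str, Enum):
    OFFICE = "OFFICE"
    INPATIENT = "INPATIENT"
    ED = "ED"
    OTHER = "OTHER"


# Shape of a normalized code per system.  ICD-9-CM diagnoses are a 3-digit
# rubric with up to two decimal digits; IMO interface terms extend that with
# trailing uppercase letters (e.g. 410.90CP); ICD-9 procedures use a 2-digit
# rubric; CPT-4 codes are plain 5-digit strings.
_CODE_PATTERNS = {
    CodeSystem.ICD9CM: re.compile(r"\d{3}(\.\d{1,2})?"),
    CodeSystem.IMO: re.compile(r"\d{3}(\.\d{1,2})?[A-Z]*"),
    CodeSystem.ICD9PROC: re.compile(r"\d{2}(\.\d{1,2})?"),
    CodeSystem.CPT4: re.compile(r"\d{5}"),
}


class CodedDiagnosis(BaseModel):
    """A single diagnosis or procedure code with its rank in the discharge list."""

    system: CodeSystem
    code: str
    position: int = Field(default=1, ge=1)

    @field_validator("code", mode="before")
    @classmethod
    def _normalize(cls, v: object) -> object:
        if isinstance(v, str):
            return v.strip().upper()
        return v

    @model_validator(mode="after")
    def _check_pattern(self) -> "CodedDiagnosis":
        if not self.code:
            raise ValueError("code must be non-empty")
        pat = _CODE_PATTERNS[self.system]
        if not pat.fullmatch(self.code):
            raise ValueError(
                f"malformed {self.system.value} code {self.code!r} "
                f"(expected pattern {pat.pattern})"
            )
        return self


class LabResult(BaseModel):
    """A troponin or BNP result expressed with the assay's upper limit of normal."""

    class Analyte(str, Enum):
        TROPONIN = "TROPONIN"
        BNP = "BNP"

    analyte: Analyte
    value: float = Field(ge=0)
    uln: float = Field(gt=0)
    datetime: datetime

    def ratio(self) -> float:
        """Result as a multiple of the assay upper limit of normal."""
        return self.value / self.uln


class EcgRecord(BaseModel):
    """Coded ECG interpretation statements (numeric acronyms) for one tracing."""

    datetime: datetime
    acronyms: List[int] = Field(default_factory=list)

    @field_validator("acronyms")
    @classmethod
    def _non_negative(cls, v: List[int]) -> List[int]:
        if any(a < 0 for a in v):
            raise ValueError("ECG interpretation acronyms must be non-negative")
        return v


class EchoRecord(BaseModel):
    """One echocardiogram's left-ventricular ejection fraction in percent."""

    datetime: datetime
    ef_percent: float = Field(ge=0, le=100)


class Hospitalization(BaseModel):
    admit: datetime
    discharge: datetime
    elective: bool = False
    diagnoses: List[CodedDiagnosis] = Field(default_factory=list)
    procedures: List[CodedDiagnosis] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Hospitalization":
        if self.admit > self.discharge:
            raise ValueError("admit must not be after discharge")
        positions = sorted(d.position for d in self.diagnoses)
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError("diagnosis positions must be 1..k without gaps")
        for p in self.procedures:
            if p.system not in (CodeSystem.ICD9PROC, CodeSystem.CPT4):
                raise ValueError("procedures must be ICD9PROC or CPT4 codes")
        return self

    def primary_diagnosis(self) -> CodedDiagnosis | None:
        for d in self.diagnoses:
            if d.position == 1:
                return d
        return None


class Claim(BaseModel):
    """An insurance claim: service date, place of service and diagnosis codes."""

    date: datetime
    place: PlaceOfService
    diagnoses: List[CodedDiagnosis] = Field(min_length=1)


class PatientRecord(BaseModel):
    patient_id: str = Field(min_length=1)
    enrollment_start: date
    hospitalizations: List[Hospitalization] = Field(default_factory=list)
    labs: List[LabResult] = Field(default_factory=list)
    ecgs: List[EcgRecord] = Field(default_factory=list)
    echos: List[EchoRecord] = Field(default_factory=list)
    claims: List[Claim] = Field(default_factory=list)

    @model_validator(mode="after")
    def _events_after_enrollment(self) -> "PatientRecord":
        start = datetime.combine(self.enrollment_start, datetime.min.time())
        stamps = (
            [h.admit for h in self.hospitalizations]
            + [x.datetime for x in self.labs]
            + [x.datetime for x in self.ecgs]
            + [x.datetime for x in self.echos]
            + [c.date for c in self.claims]
        )
        bad = [t for t in stamps if t < start]
        if bad:
            raise ValueError(
                f"{len(bad)} event timestamp(s) precede enrollment_start {self.enrollment_start}"
            )
        return self


class PeriodOfInterest(BaseModel):
    """Calendar window over which events are classified for surveillance."""

    start: date
    end: date

    @model_validator(mode="after")
    def _ordered(self) -> "PeriodOfInterest":
        if self.start >= self.end:
            raise ValueError("period start must precede end")
        return self

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass
class Episode:
    """A hospitalization plus the labs, ECGs and echos attached to it."""

    hospitalization: Hospitalization
    labs: List[LabResult] = field(default_factory=list)
    ecgs: List[EcgRecord] = field(default_factory=list)
    echos: List[EchoRecord] = field(default_factory=list)


#: Events dated up to this long before admission or after discharge are
#: attached to the stay: pre-admission ED troponins and discharge-day echos
#: belong clinically to the episode of care.
LINKAGE_WINDOW = timedelta(hours=24)


def link_episodes(
    record: PatientRecord,
    period: PeriodOfInterest,
    window: timedelta = LINKAGE_WINDOW,
) -> List[Episode]:
    """Build episodes of care for hospitalizations discharged within *period*.

    A lab/ECG/echo is attached to a hospitalization when its timestamp lies
    in ``[admit - window, discharge + window]``; an event may attach to
    several overlapping stays.  Episodes are returned ordered by admission.
    """
    episodes: List[Episode] = []
    for hosp in sorted(record.hospitalizations, key=lambda h: h.admit):
        if not period.contains(hosp.discharge.date()):
            continue
        lo, hi = hosp.admit - window, hosp.discharge + window
        episodes.append(
            Episode(
                hospitalization=hosp,
                labs=[x for x in record.labs if lo <= x.datetime <= hi],
                ecgs=[x for x in record.ecgs if lo <= x.datetime <= hi],
                echos=[x for x in record.echos if lo <= x.datetime <= hi],
            )
        )
    return episodes


def observation_years(record: PatientRecord, as_of: date) -> float:
    """Observation time from enrollment start to *as_of* in 365.25-day years."""
    if as_of < record.enrollment_start:
        raise ValueError(
            f"as_of {as_of} precedes enrollment_start {record.enrollment_start}"
        )
    return (as_of - record.enrollment_start).days / 365.25
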