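"""Three generations of the hierarchical event-classification algorithm.

Each algorithm version assigns one label per patient for a period of
interest.  Categories are evaluated in a fixed clinical-priority order and
the first satisfied category wins: a patient with a STEMI complicated by
acute heart failure is a STEMI; acute heart failure with elevated troponin
but no ST elevation is heart failure.

Version 1 (V1) works from 4-digit ICD-9-CM discharge codes and troponin
alone; because ST-elevation ECG statements could not yet be searched, STEMI
and nSTEMI collapse into a single MI_UNSPECIFIED category.  Version 2 (V2)
adds coded ECG interpretation statements (acronyms 964-968 denote ST
elevation), a stricter troponin cut-off (>3x the upper limit of normal), an
ejection-fraction requirement for systolic heart failure, and claims-based
ambulatory/chronic criteria.  Version 3 (V3) replaces the ECG/troponin MI
split with IMO interface terms specific for STEMI vs nSTEMI, drops unstable
angina, and merges ambulatory presentation with chronic prevalent disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from cardioevent.codesets import CodeSet, builtin_codesets
from cardioevent.ehr_model import (
    CodedDiagnosis,
    Episode,
    LabResult,
    PatientRecord,
    PeriodOfInterest,
    link_episodes,
    observation_years,
)
from cardioevent.ehr_model import PlaceOfService


class Version(str, Enum):
    V1 = "V1"
    V2 = "V2"
    V3 = "V3"


class Label(str, Enum):
    STEMI = "STEMI"
    SYSTOLIC_HF = "SYSTOLIC_HF"
    NSTEMI = "NSTEMI"
    UNSTABLE_ANGINA = "UNSTABLE_ANGINA"
    AMBULATORY = "AMBULATORY"
    CHRONIC = "CHRONIC"
    AMBULATORY_OR_CHRONIC = "AMBULATORY_OR_CHRONIC"
    MI_UNSPECIFIED = "MI_UNSPECIFIED"
    UNCLASSIFIED = "UNCLASSIFIED"


#: Category priority per version, highest first.  UNCLASSIFIED is the
#: fall-through, not a criterion.
HIERARCHY: Dict[Version, Tuple[Label, ...]] = {
    Version.V1: (
        Label.MI_UNSPECIFIED,
        Label.SYSTOLIC_HF,
        Label.UNSTABLE_ANGINA,
        Label.AMBULATORY,
        Label.CHRONIC,
    ),
    Version.V2: (
        Label.STEMI,
        Label.SYSTOLIC_HF,
        Label.NSTEMI,
        Label.UNSTABLE_ANGINA,
        Label.AMBULATORY,
        Label.CHRONIC,
    ),
    Version.V3: (
        Label.STEMI,
        Label.SYSTOLIC_HF,
        Label.NSTEMI,
        Label.AMBULATORY_OR_CHRONIC,
    ),
}

VALID_LABELS: Dict[Version, Tuple[Label, ...]] = {
    v: HIERARCHY[v] + (Label.UNCLASSIFIED,) for v in Version
}


@dataclass
class AlgorithmConfig:
    """Thresholds and windows shared by the three algorithm versions.

    ``troponin_multiplier_v1`` / ``troponin_multiplier_v23`` are multiples of
    the assay upper limit of normal (V1 used any elevation, later versions
    >3x); ``ef_threshold`` is the ejection-fraction cut in percent (<=35
    denotes depressed systolic function); ``st_elevation_acronyms`` is the
    inclusive range of coded ECG interpretation statements denoting ST
    elevation; ``ambulatory_window_days`` is the V1 window around the first
    heart-disease diagnosis within which a nonelective hospitalization
    disqualifies an ambulatory presentation.
    """

    period: PeriodOfInterest
    troponin_multiplier_v1: float = 1.0
    troponin_multiplier_v23: float = 3.0
    ef_threshold: float = 35.0
    min_observation_years: float = 2.0
    st_elevation_acronyms: Tuple[int, int] = (964, 968)
    ambulatory_window_days: int = 30

    def __post_init__(self) -> None:
        if self.troponin_multiplier_v1 <= 0 or self.troponin_multiplier_v23 <= 0:
            raise ValueError("troponin multipliers must be positive")
        if self.ef_threshold <= 0:
            raise ValueError("ef_threshold must be positive")
        lo, hi = self.st_elevation_acronyms
        if lo > hi:
            raise ValueError("st_elevation_acronyms range is empty")


@dataclass
class EventClass:
    """Classification result: the winning label plus every criterion that fired."""

    label: Label
    version: Version
    rationale: List[str] = field(default_factory=list)


class InvalidCohortError(ValueError):
    pass


_SETS = builtin_codesets()


# ---------------------------------------------------------------------------
# Episode-level clinical predicates
# ---------------------------------------------------------------------------

def _troponins(episode: Episode) -> List[LabResult]:
    return [x for x in episode.labs if x.analyte is LabResult.Analyte.TROPONIN]


def troponin_exceeds(episode: Episode, multiplier: float) -> bool:
    """>=1 linked troponin strictly above multiplier x the assay ULN."""
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return any(x.value > multiplier * x.uln for x in _troponins(episode))


def bnp_exceeds(episode: Episode) -> bool:
    return any(
        x.value > x.uln
        for x in episode.labs
        if x.analyte is LabResult.Analyte.BNP
    )


def has_st_elevation(episode: Episode, config: AlgorithmConfig) -> bool:
    """Any linked ECG carries an interpretation acronym in the ST-elevation range."""
    lo, hi = config.st_elevation_acronyms
    return any(lo <= a <= hi for ecg in episode.ecgs for a in ecg.acronyms)


def ef_at_or_below(episode: Episode, threshold: float) -> bool:
    return any(e.ef_percent <= threshold for e in episode.echos)


def hf_criteria_met(episode: Episode, version: Version, config: AlgorithmConfig) -> bool:
    """Systolic heart failure: primary discharge code 425/428 plus BNP > ULN.

    V2/V3 additionally require a linked echo with EF at or below the
    threshold; V1 predates the EF requirement.
    """
    primary = episode.hospitalization.primary_diagnosis()
    if primary is None or not _SETS["HF_CODES"].matches_code(primary):
        return False
    if not bnp_exceeds(episode):
        return False
    if version is Version.V1:
        return True
    return ef_at_or_below(episode, config.ef_threshold)


# ---------------------------------------------------------------------------
# Record-level helpers
# ---------------------------------------------------------------------------

def _all_diagnoses(record: PatientRecord) -> Iterable[Tuple[date, CodedDiagnosis]]:
    """Every diagnosis code in the record with its event date (claims and stays)."""
    for hosp in record.hospitalizations:
        for dx in hosp.diagnoses:
            yield hosp.admit.date(), dx
    for claim in record.claims:
        for dx in claim.diagnoses:
            yield claim.date.date(), dx


def first_heart_disease_date(record: PatientRecord) -> Optional[date]:
    hd = _SETS["HEART_DISEASE"]
    dates = [d for d, dx in _all_diagnoses(record) if hd.matches_code(dx)]
    return min(dates) if dates else None


def _hospitalizations_overlapping(record: PatientRecord, period: PeriodOfInterest):
    for hosp in record.hospitalizations:
        if hosp.admit.date() <= period.end and hosp.discharge.date() >= period.start:
            yield hosp


def _dx_match(episode: Episode, codeset: CodeSet) -> bool:
    return any(codeset.matches_code(d) for d in episode.hospitalization.diagnoses)


def _heart_disease_claims(record: PatientRecord) -> List:
    hd = _SETS["HEART_DISEASE"]
    return sorted(
        (c for c in record.claims if any(hd.matches_code(d) for d in c.diagnoses)),
        key=lambda c: c.date,
    )


# ---------------------------------------------------------------------------
# Category criteria per version (record-level, over linked episodes)
# ---------------------------------------------------------------------------

def _v1_mi_unspecified(record, episodes, config) -> bool:
    # 410.0-410.9 with any troponin elevation, or 410.7/410.9/420-429 with
    # any troponin elevation; merged MI because ST statements were not yet
    # searchable.
    mi_any, ambiguous, other = _SETS["MI_ANY"], _SETS["MI_AMBIGUOUS"], _SETS["OTHER_HEART_420_429"]
    for ep in episodes:
        if not troponin_exceeds(ep, config.troponin_multiplier_v1):
            continue
        if _dx_match(ep, mi_any) or _dx_match(ep, ambiguous) or _dx_match(ep, other):
            return True
    return False


def _v1_unstable_angina(record, episodes, config) -> bool:
    ua = CodeSet("UA_411", [s for s in _SETS["UA_CODES"].specs if s.payload == "411"])
    return any(
        _dx_match(ep, ua) and not troponin_exceeds(ep, 1.0)
        for ep in episodes
    )


def _v1_ambulatory(record, episodes, config) -> bool:
    first_dx = first_heart_disease_date(record)
    if first_dx is None:
        return False
    if observation_years(record, first_dx) < config.min_observation_years:
        return False
    window = timedelta(days=config.ambulatory_window_days)
    lo, hi = first_dx - window, first_dx + window
    for hosp in record.hospitalizations:
        if hosp.elective:
            continue
        if hosp.admit.date() <= hi and hosp.discharge.date() >= lo:
            return False
    return True


def _v1_chronic(record, episodes, config) -> bool:
    if record.enrollment_start > config.period.start:
        return False
    if observation_years(record, config.period.start) < config.min_observation_years:
        return False
    chronic = _SETS["CHRONIC_V1"]
    first_year_end = record.enrollment_start + timedelta(days=365)
    return any(
        d <= first_year_end and chronic.matches_code(dx)
        for d, dx in _all_diagnoses(record)
    )


def _v2_stemi(record, episodes, config) -> bool:
    definite, ambiguous = _SETS["STEMI_ICD9_DEFINITE"], _SETS["MI_AMBIGUOUS"]
    for ep in episodes:
        if _dx_match(ep, definite):
            return True
        if (
            _dx_match(ep, ambiguous)
            and has_st_elevation(ep, config)
            and troponin_exceeds(ep, config.troponin_multiplier_v23)
        ):
            return True
    return False


def _v2_nstemi(record, episodes, config) -> bool:
    ambiguous = _SETS["MI_AMBIGUOUS"]
    return any(
        _dx_match(ep, ambiguous)
        and not has_st_elevation(ep, config)
        and troponin_exceeds(ep, config.troponin_multiplier_v23)
        for ep in episodes
    )


def _v2_unstable_angina(record, episodes, config) -> bool:
    ua, pacer = _SETS["UA_CODES"], _SETS["PACER_DEFIB"]
    return any(
        _dx_match(ep, ua)
        and not troponin_exceeds(ep, config.troponin_multiplier_v23)
        and not any(pacer.matches_code(p) for p in ep.hospitalization.procedures)
        for ep in episodes
    )


def _v2_ambulatory(record, episodes, config) -> bool:
    # Incident diagnosis in the ambulatory setting: the patient's first
    # heart-disease claim ever falls in the period and comes from an office.
    hd_claims = _heart_disease_claims(record)
    if not hd_claims:
        return False
    first = hd_claims[0]
    if first.place is not PlaceOfService.OFFICE:
        return False
    if not config.period.contains(first.date.date()):
        return False
    if record.enrollment_start > config.period.start:
        return False
    return observation_years(record, config.period.start) >= config.min_observation_years


def _v2_chronic(record, episodes, config) -> bool:
    if record.enrollment_start > config.period.start:
        return False
    if observation_years(record, config.period.start) < config.min_observation_years:
        return False
    hd = _SETS["HEART_DISEASE"]
    diagnosed_before = any(
        d < config.period.start and hd.matches_code(dx)
        for d, dx in _all_diagnoses(record)
    )
    if not diagnosed_before:
        return False
    chest_pain = _SETS["CHEST_PAIN"]
    for hosp in _hospitalizations_overlapping(record, config.period):
        if any(hd.matches_code(d) or chest_pain.matches_code(d) for d in hosp.diagnoses):
            return False
    return True


def _v3_stemi(record, episodes, config) -> bool:
    return any(_dx_match(ep, _SETS["STEMI_V3"]) for ep in episodes)


def _v3_nstemi(record, episodes, config) -> bool:
    return any(_dx_match(ep, _SETS["NSTEMI_V3"]) for ep in episodes)


def _v3_ambulatory_or_chronic(record, episodes, config) -> bool:
    hd = _SETS["HEART_DISEASE"]
    if not any(hd.matches_code(dx) for _, dx in _all_diagnoses(record)):
        return False
    for hosp in _hospitalizations_overlapping(record, config.period):
        if hosp.elective:
            continue
        if any(hd.matches_code(d) for d in hosp.diagnoses):
            return False
    return True


_Criterion = Callable[[PatientRecord, List[Episode], AlgorithmConfig], bool]

_CRITERIA: Dict[Version, Tuple[Tuple[Label, _Criterion], ...]] = {
    Version.V1: (
        (Label.MI_UNSPECIFIED, _v1_mi_unspecified),
        (Label.SYSTOLIC_HF, lambda r, eps, c: any(hf_criteria_met(e, Version.V1, c) for e in eps)),
        (Label.UNSTABLE_ANGINA, _v1_unstable_angina),
        (Label.AMBULATORY, _v1_ambulatory),
        (Label.CHRONIC, _v1_chronic),
    ),
    Version.V2: (
        (Label.STEMI, _v2_stemi),
        (Label.SYSTOLIC_HF, lambda r, eps, c: any(hf_criteria_met(e, Version.V2, c) for e in eps)),
        (Label.NSTEMI, _v2_nstemi),
        (Label.UNSTABLE_ANGINA, _v2_unstable_angina),
        (Label.AMBULATORY, _v2_ambulatory),
        (Label.CHRONIC, _v2_chronic),
    ),
    Version.V3: (
        (Label.STEMI, _v3_stemi),
        (Label.SYSTOLIC_HF, lambda r, eps, c: any(hf_criteria_met(e, Version.V3, c) for e in eps)),
        (Label.NSTEMI, _v3_nstemi),
        (Label.AMBULATORY_OR_CHRONIC, _v3_ambulatory_or_chronic),
    ),
}


def classify(record: PatientRecord, version: Version, config: AlgorithmConfig) -> EventClass:
    """Classify one patient for the configured period under one algorithm version.

    Every category criterion is evaluated; the highest-priority satisfied
    category becomes the label and all satisfied criteria are recorded in
    the rationale.  A record satisfying no criterion is UNCLASSIFIED.
    """
    episodes = link_episodes(record, config.period)
    fired = [
        label
        for label, criterion in _CRITERIA[version]
        if criterion(record, episodes, config)
    ]
    label = fired[0] if fired else Label.UNCLASSIFIED
    rationale = [f"{version.value}:{lab.value}" for lab in fired] or [f"{version.value}:no_criterion_met"]
    return EventClass(label=label, version=version, rationale=rationale)


def classify_v1(record: PatientRecord, config: AlgorithmConfig) -> EventClass:
    return classify(record, Version.V1, config)


def classify_v2(record: PatientRecord, config: AlgorithmConfig) -> EventClass:
    return classify(record, Version.V2, config)


def classify_v3(record: PatientRecord, config: AlgorithmConfig) -> EventClass:
    return classify(record, Version.V3, config)


def classify_cohort(
    records: Sequence[PatientRecord],
    version: Version,
    config: AlgorithmConfig,
) -> pd.DataFrame:
    """Classify a cohort; returns columns patient_id, version, label, rationale."""
    ids = [r.patient_id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise InvalidCohortError(f"duplicate patient_id(s): {sorted(dupes)}")
    rows = []
    for record in records:
        result = classify(record, version, config)
        rows.append(
            {
                "patient_id": record.patient_id,
                "version": version.value,
                "label": result.label.value,
                "rationale": ";".join(result.rationale),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "version", "label", "rationale"])
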