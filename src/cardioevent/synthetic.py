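"""Seeded synthetic EHR cohorts for exercising the classification algorithms.

Each generated patient record is constructed to satisfy exactly one
category's criteria under one algorithm version — with jittered dates and
lab values drawn safely interior to the thresholds, so jitter can never flip
a label — and is verified against the classifier before being returned.
Discordant records (algorithm label differing from the gold label) emulate
algorithm-vs-reviewer disagreement: for example a heart-failure admission
whose primary discharge code is an nSTEMI interface term, which the
algorithm reads as nSTEMI while reviewers call it heart failure.

The generator emulates the coded traces of the study conditions only; it
makes no attempt at realistic marginal epidemiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, time, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from cardioevent.codesets import NSTEMI_IMO_TERMS, STEMI_IMO_TERMS
from cardioevent.ehr_model import (
    Claim,
    CodedDiagnosis,
    CodeSystem,
    EchoRecord,
    EcgRecord,
    Hospitalization,
    LabResult,
    PatientRecord,
    PeriodOfInterest,
    PlaceOfService,
)
from cardioevent.phenotyper import (
    HIERARCHY,
    VALID_LABELS,
    AlgorithmConfig,
    Label,
    Version,
    classify,
)

#: ECG interpretation acronyms that never denote ST elevation (963/969
#: bracket the ST-elevation range 964-968).
BENIGN_ACRONYMS = (10, 22, 55, 102, 140, 963, 969)

#: Jitter ranges, as multiples of the assay ULN (labs) or percent (EF),
#: chosen safely interior to the decision thresholds.
TROPONIN_POSITIVE = (3.5, 20.0)
TROPONIN_NEGATIVE = (0.1, 0.9)
BNP_POSITIVE = (1.5, 10.0)
EF_DEPRESSED = (15.0, 35.0)

_TROPONIN_ULNS = (0.04, 0.1)
_BNP_ULN = 100.0


class GenerationError(RuntimeError):
    pass


class InfeasibleDiscordanceError(GenerationError):
    """No perturbation can make the algorithm fire the requested label."""


@dataclass
class CohortSpec:
    """Sampling design for a synthetic cohort."""

    version: Version
    period: PeriodOfInterest
    counts: Dict[Label, int]
    discordance: Dict[Tuple[Label, Label], int] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        valid = set(VALID_LABELS[self.version])
        for lab in self.counts:
            if lab not in valid:
                raise ValueError(f"category {lab} not valid for {self.version}")
        for (a, g), k in self.discordance.items():
            if a == g:
                raise ValueError("discordance pairs must have distinct members")
            if a not in valid or g not in valid:
                raise ValueError(f"discordance pair ({a}, {g}) not valid for {self.version}")
            if k < 0:
                raise ValueError("discordance counts must be non-negative")


@dataclass
class NegativeControl:
    """A near-miss record violating exactly one conjunct of one criterion."""

    record: PatientRecord
    forbidden: Tuple[Label, ...]
    expected: Optional[Label]
    note: str


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _dx(system: CodeSystem, code: str, position: int = 1) -> CodedDiagnosis:
    return CodedDiagnosis(system=system, code=code, position=position)


def _stay(
    period: PeriodOfInterest,
    rng: np.random.Generator,
    codes: List[Tuple[CodeSystem, str]],
    elective: bool = False,
    procedures: Optional[List[Tuple[CodeSystem, str]]] = None,
) -> Hospitalization:
    span = (period.end - period.start).days
    admit_day = int(rng.integers(0, max(span - 9, 1)))
    admit = datetime.combine(period.start, time(8, 0)) + timedelta(days=admit_day)
    discharge = admit + timedelta(days=int(rng.integers(2, 7)), hours=int(rng.integers(0, 8)))
    return Hospitalization(
        admit=admit,
        discharge=discharge,
        elective=elective,
        diagnoses=[_dx(s, c, i + 1) for i, (s, c) in enumerate(codes)],
        procedures=[_dx(s, c) for s, c in (procedures or [])],
    )


def _in_stay(stay: Hospitalization, rng: np.random.Generator) -> datetime:
    span_h = max(int((stay.discharge - stay.admit).total_seconds() // 3600) - 1, 1)
    return stay.admit + timedelta(hours=int(rng.integers(1, span_h + 1)))


def _troponin(stay: Hospitalization, rng: np.random.Generator, ratio: float) -> LabResult:
    uln = float(rng.choice(_TROPONIN_ULNS))
    return LabResult(
        analyte=LabResult.Analyte.TROPONIN,
        value=ratio * uln,
        uln=uln,
        datetime=_in_stay(stay, rng),
    )


def _bnp(stay: Hospitalization, rng: np.random.Generator, ratio: float) -> LabResult:
    return LabResult(
        analyte=LabResult.Analyte.BNP,
        value=ratio * _BNP_ULN,
        uln=_BNP_ULN,
        datetime=_in_stay(stay, rng),
    )


def _benign_ecg(stay: Hospitalization, rng: np.random.Generator) -> EcgRecord:
    k = int(rng.integers(1, 4))
    acronyms = [int(a) for a in rng.choice(BENIGN_ACRONYMS, size=k, replace=False)]
    return EcgRecord(datetime=_in_stay(stay, rng), acronyms=acronyms)


def _st_ecg(stay: Hospitalization, rng: np.random.Generator) -> EcgRecord:
    acronyms = [int(rng.integers(964, 969)), int(rng.choice(BENIGN_ACRONYMS))]
    return EcgRecord(datetime=_in_stay(stay, rng), acronyms=acronyms)


def _echo(stay: Hospitalization, rng: np.random.Generator, ef: float) -> EchoRecord:
    return EchoRecord(datetime=_in_stay(stay, rng), ef_percent=ef)


def _office_claim(d: date, codes: List[Tuple[CodeSystem, str]]) -> Claim:
    return Claim(
        date=datetime.combine(d, time(10, 0)),
        place=PlaceOfService.OFFICE,
        diagnoses=[_dx(s, c, i + 1) for i, (s, c) in enumerate(codes)],
    )


def _enrollment_before(period: PeriodOfInterest, rng: np.random.Generator,
                       lo_years: float = 2.5, hi_years: float = 6.0) -> date:
    return period.start - timedelta(days=int(rng.uniform(lo_years, hi_years) * 365.25))


_HD_CLAIM_CODES = ("414.01", "414.00", "413.9")


# ---------------------------------------------------------------------------
# Per-category scenario builders
# ---------------------------------------------------------------------------

def _build_scenario(
    category: Label,
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> PatientRecord:
    period = config.period
    enrollment = _enrollment_before(period, rng)
    kw: dict = dict(patient_id=patient_id, enrollment_start=enrollment)

    if category is Label.MI_UNSPECIFIED:  # V1 merged MI
        code = str(rng.choice(["410.01", "410.11", "410.41", "410.71", "410.91"]))
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
        kw.update(
            hospitalizations=[stay],
            labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE))],
            ecgs=[_benign_ecg(stay, rng)],
        )

    elif category is Label.STEMI:
        if version is Version.V2:
            if rng.random() < 0.5:
                code = str(rng.choice(["410.01", "410.11", "410.31", "410.81"]))
                stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
                ecgs = [_benign_ecg(stay, rng)]
            else:
                code = str(rng.choice(["410.71", "410.90", "410.91"]))
                stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
                ecgs = [_st_ecg(stay, rng)]
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE))],
                ecgs=ecgs,
            )
        else:  # V3: a single IMO STEMI term (or a definite ICD code) suffices
            if rng.random() < 0.7:
                dx = (CodeSystem.IMO, str(rng.choice(STEMI_IMO_TERMS)))
            else:
                dx = (CodeSystem.ICD9CM, str(rng.choice(["410.01", "410.11", "410.81"])))
            stay = _stay(period, rng, [dx])
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE))],
            )

    elif category is Label.NSTEMI:
        if version is Version.V2:
            code = str(rng.choice(["410.70", "410.71", "410.90", "410.92"]))
            stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE))],
                ecgs=[_benign_ecg(stay, rng)],
            )
        else:  # V3
            if rng.random() < 0.7:
                dx = (CodeSystem.IMO, str(rng.choice(NSTEMI_IMO_TERMS + ("410.91B",))))
            else:
                dx = (CodeSystem.ICD9CM, str(rng.choice(["410.70", "410.71"])))
            stay = _stay(period, rng, [dx])
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE))],
            )

    elif category is Label.SYSTOLIC_HF:
        code = str(rng.choice(["428.0", "428.22", "425.4"]))
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
        labs = [_bnp(stay, rng, rng.uniform(*BNP_POSITIVE))]
        if version is Version.V1:
            # any troponin above the ULN would reroute to merged MI (428 is
            # within 420-429), so troponin stays normal if drawn at all
            if rng.random() < 0.5:
                labs.append(_troponin(stay, rng, rng.uniform(*TROPONIN_NEGATIVE)))
        elif rng.random() < 0.5:
            labs.append(_troponin(stay, rng, rng.uniform(*TROPONIN_POSITIVE)))
        kw.update(
            hospitalizations=[stay],
            labs=labs,
            echos=[_echo(stay, rng, rng.uniform(*EF_DEPRESSED))],
        )

    elif category is Label.UNSTABLE_ANGINA:
        code = str(rng.choice(["411.1", "411.81"]))
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, code)])
        labs = []
        if rng.random() < 0.7:
            labs.append(_troponin(stay, rng, rng.uniform(*TROPONIN_NEGATIVE)))
        kw.update(hospitalizations=[stay], labs=labs, ecgs=[_benign_ecg(stay, rng)])

    elif category is Label.AMBULATORY:
        span = (period.end - period.start).days
        claim_date = period.start + timedelta(days=int(rng.integers(0, span)))
        code = str(rng.choice(_HD_CLAIM_CODES))
        kw.update(claims=[_office_claim(claim_date, [(CodeSystem.ICD9CM, code)])])

    elif category is Label.CHRONIC:
        code = str(rng.choice(_HD_CLAIM_CODES))
        if version is Version.V1:
            # codes 412-414 / 420-429 within the first year of enrollment
            claim_date = enrollment + timedelta(days=int(rng.integers(30, 300)))
        else:
            latest = (period.start - enrollment).days - 30
            claim_date = enrollment + timedelta(days=int(rng.integers(60, max(latest, 61))))
        kw.update(claims=[_office_claim(claim_date, [(CodeSystem.ICD9CM, code)])])

    elif category is Label.AMBULATORY_OR_CHRONIC:  # V3
        code = str(rng.choice(_HD_CLAIM_CODES))
        if rng.random() < 0.5:
            claim_date = enrollment + timedelta(days=int(rng.integers(30, 600)))
        else:
            claim_date = period.start + timedelta(
                days=int(rng.integers(0, (period.end - period.start).days))
            )
        kw.update(claims=[_office_claim(claim_date, [(CodeSystem.ICD9CM, code)])])
        if rng.random() < 0.3:
            # an elective heart-disease admission does not disqualify
            kw["hospitalizations"] = [
                _stay(period, rng, [(CodeSystem.ICD9CM, code)], elective=True)
            ]

    elif category is Label.UNCLASSIFIED:
        if version is Version.V3:
            # bare 410.92 matches neither IMO list nor the definite/410.7 rules
            stay = _stay(period, rng, [(CodeSystem.ICD9CM, "410.92")])
            kw.update(hospitalizations=[stay])
        elif version is Version.V2:
            # chest-pain admission for pacemaker revision: excluded from UA
            stay = _stay(
                period, rng,
                [(CodeSystem.ICD9CM, "786.50")],
                procedures=[(CodeSystem.ICD9PROC, "37.85")],
            )
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_NEGATIVE))],
            )
        else:
            # chest pain without 411.x fits no first-generation category
            stay = _stay(period, rng, [(CodeSystem.ICD9CM, "786.50")])
            kw.update(
                hospitalizations=[stay],
                labs=[_troponin(stay, rng, rng.uniform(*TROPONIN_NEGATIVE))],
            )

    else:
        raise GenerationError(f"no scenario builder for {category}")

    return PatientRecord(**kw)


def generate_patient(
    category: Label,
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
    patient_id: str = "SYN-0",
) -> Tuple[PatientRecord, Label]:
    """Generate one record that classifies to *category*; gold label = category."""
    if category not in VALID_LABELS[version]:
        raise ValueError(f"category {category} not valid for version {version}")
    record = _build_scenario(category, version, config, rng, patient_id)
    got = classify(record, version, config).label
    if got is not category:
        raise GenerationError(
            f"generated {category} scenario classified as {got} under {version}"
        )
    return record, category


# ---------------------------------------------------------------------------
# Discordance construction
# ---------------------------------------------------------------------------

def _target_stay(record: PatientRecord, period: PeriodOfInterest,
                 rng: np.random.Generator) -> Hospitalization:
    for hosp in record.hospitalizations:
        if period.contains(hosp.discharge.date()):
            return hosp
    stay = _stay(period, rng, [(CodeSystem.ICD9CM, "786.50")])
    record.hospitalizations.append(stay)
    return stay


def _append_dx(stay: Hospitalization, system: CodeSystem, code: str) -> None:
    stay.diagnoses.append(_dx(system, code, len(stay.diagnoses) + 1))


def _add_trigger(
    record: PatientRecord,
    alg: Label,
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
) -> bool:
    """Perturb coded data so the algorithm fires *alg*; True when a recipe exists."""
    stay = _target_stay(record, config.period, rng)
    if alg is Label.MI_UNSPECIFIED:
        _append_dx(stay, CodeSystem.ICD9CM, "410.11")
        record.labs.append(_troponin(stay, rng, 5.0))
        return True
    if alg is Label.STEMI:
        if version is Version.V3:
            _append_dx(stay, CodeSystem.IMO, str(rng.choice(STEMI_IMO_TERMS)))
        else:
            _append_dx(stay, CodeSystem.ICD9CM, "410.11")
        return True
    if alg is Label.NSTEMI:
        if version is Version.V3:
            _append_dx(stay, CodeSystem.IMO, str(rng.choice(NSTEMI_IMO_TERMS)))
        else:
            _append_dx(stay, CodeSystem.ICD9CM, "410.71")
            record.labs.append(_troponin(stay, rng, 5.0))
        return True
    if alg is Label.SYSTOLIC_HF:
        for d in stay.diagnoses:
            d.position += 1
        stay.diagnoses.insert(0, _dx(CodeSystem.ICD9CM, "428.0", 1))
        record.labs.append(_bnp(stay, rng, 3.0))
        record.echos.append(_echo(stay, rng, 28.0))
        return True
    if alg is Label.UNSTABLE_ANGINA:
        _append_dx(stay, CodeSystem.ICD9CM, "411.1")
        return True
    return False


def _soft_evidence(
    record: PatientRecord,
    gold: Label,
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
) -> None:
    """Add gold-suggestive data that must not change the algorithm's label."""
    stays = [h for h in record.hospitalizations if config.period.contains(h.discharge.date())]
    if not stays:
        return
    stay = stays[0]
    if gold is Label.SYSTOLIC_HF:
        # heart failure the reviewers would recognize, coded only in a
        # non-primary position so the algorithmic HF criterion stays unmet
        _append_dx(stay, CodeSystem.ICD9CM, "428.0")
        record.labs.append(_bnp(stay, rng, 3.0))
        record.echos.append(_echo(stay, rng, 28.0))
    elif gold in (Label.NSTEMI, Label.MI_UNSPECIFIED):
        record.labs.append(_troponin(stay, rng, 6.0))
    elif gold is Label.STEMI:
        record.ecgs.append(_st_ecg(stay, rng))


def generate_discordant(
    alg: Label,
    gold: Label,
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
    patient_id: str = "SYN-D0",
) -> PatientRecord:
    """A record the algorithm labels *alg* while carrying gold label *gold*."""
    if alg == gold:
        raise ValueError("discordant pair must differ")
    order = {lab: i for i, lab in enumerate(HIERARCHY[version])}
    big = len(order)
    if order.get(alg, big) < order.get(gold, big):
        # the algorithm label outranks the gold one: add its trigger to a
        # genuine gold scenario and let the hierarchy promote it
        record = _build_scenario(gold, version, config, rng, patient_id)
        if _add_trigger(record, alg, version, config, rng):
            if classify(record, version, config).label is alg:
                return record
    # otherwise: an algorithm-side scenario decorated with gold-suggestive
    # but non-triggering clinical data (reverted if it flips the label)
    record = _build_scenario(alg, version, config, rng, patient_id)
    decorated = record.model_copy(deep=True)
    _soft_evidence(decorated, gold, version, config, rng)
    if classify(decorated, version, config).label is alg:
        record = decorated
    if classify(record, version, config).label is not alg:
        raise InfeasibleDiscordanceError(
            f"cannot construct a record classifying as {alg} with gold {gold} under {version}"
        )
    return record


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> Tuple[List[PatientRecord], pd.DataFrame]:
    """Generate a cohort per the sampling design; returns (records, gold table).

    Deterministic given the spec (including its seed): each patient draws
    from a counter-derived substream, so one patient's data never depends on
    how many others precede it.
    """
    config = AlgorithmConfig(period=spec.period)
    records: List[PatientRecord] = []
    gold_rows: List[dict] = []
    i = 0
    for category, count in spec.counts.items():
        for _ in range(count):
            rng = np.random.default_rng([spec.seed, i])
            pid = f"P{i:05d}"
            rec, g = generate_patient(category, spec.version, config, rng, patient_id=pid)
            records.append(rec)
            gold_rows.append({"patient_id": pid, "label": g.value})
            i += 1
    for (alg, gold), count in spec.discordance.items():
        for _ in range(count):
            rng = np.random.default_rng([spec.seed, i])
            pid = f"P{i:05d}"
            rec = generate_discordant(alg, gold, spec.version, config, rng, patient_id=pid)
            records.append(rec)
            gold_rows.append({"patient_id": pid, "label": gold.value})
            i += 1
    gold = pd.DataFrame(gold_rows, columns=["patient_id", "label"])
    return records, gold


# ---------------------------------------------------------------------------
# Negative controls: near-misses violating exactly one conjunct
# ---------------------------------------------------------------------------

def negative_controls(
    version: Version,
    config: AlgorithmConfig,
    rng: np.random.Generator,
) -> List[NegativeControl]:
    """Near-miss records, each violating exactly one conjunct of one criterion."""
    period = config.period
    controls: List[NegativeControl] = []
    n = 0

    def make(forbidden, expected, note, **kw) -> None:
        nonlocal n
        enrollment = kw.pop("enrollment_start", _enrollment_before(period, rng))
        rec = PatientRecord(patient_id=f"NC-{version.value}-{n}", enrollment_start=enrollment, **kw)
        controls.append(NegativeControl(rec, tuple(forbidden), expected, note))
        n += 1

    if version in (Version.V2, Version.V3):
        # EF exactly one point above the cut-off blocks the HF criterion
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "428.0")])
        make(
            [Label.SYSTOLIC_HF], None, "EF 36% with all other HF conjuncts met",
            hospitalizations=[stay],
            labs=[_bnp(stay, rng, 3.0)],
            echos=[_echo(stay, rng, config.ef_threshold + 1.0)],
        )

    if version is Version.V2:
        # troponin exactly at 3x ULN fails the strict inequality
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "410.71")])
        uln = 0.04
        make(
            [Label.NSTEMI, Label.STEMI], None, "troponin exactly 3x ULN with 410.7",
            hospitalizations=[stay],
            labs=[LabResult(analyte=LabResult.Analyte.TROPONIN, value=3 * uln, uln=uln,
                            datetime=_in_stay(stay, rng))],
        )
        # acronym 963 sits just below the ST-elevation range
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "410.91")])
        make(
            [Label.STEMI], Label.NSTEMI, "ECG acronym 963 only, troponin >3x ULN",
            hospitalizations=[stay],
            labs=[_troponin(stay, rng, 6.0)],
            ecgs=[EcgRecord(datetime=_in_stay(stay, rng), acronyms=[963])],
        )
        # pacemaker-revision procedure excludes the unstable-angina category
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "411.1")],
                     procedures=[(CodeSystem.ICD9PROC, "37.85")])
        make(
            [Label.UNSTABLE_ANGINA], None, "pacer/defibrillator procedure with 411.1",
            hospitalizations=[stay],
            labs=[_troponin(stay, rng, 0.5)],
        )

    if version in (Version.V1, Version.V2):
        # 1.9 years of observation misses the 2-year requirement
        claim_date = period.start + timedelta(days=30)
        make(
            [Label.AMBULATORY], None, "observation 1.9 years before period",
            enrollment_start=period.start - timedelta(days=int(1.9 * 365.25)),
            claims=[_office_claim(claim_date, [(CodeSystem.ICD9CM, "414.01")])],
        )

    if version is Version.V3:
        # an elective admission does NOT disqualify ambulatory/chronic
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "414.01")], elective=True)
        make(
            [], Label.AMBULATORY_OR_CHRONIC, "elective heart-disease admission only",
            hospitalizations=[stay],
            claims=[_office_claim(period.start + timedelta(days=14),
                                  [(CodeSystem.ICD9CM, "414.01")])],
        )
        # bare 410.92 without a letter suffix falls in neither IMO term list
        stay = _stay(period, rng, [(CodeSystem.ICD9CM, "410.92")])
        make(
            [Label.STEMI, Label.NSTEMI], Label.UNCLASSIFIED,
            "bare 410.92 matches neither STEMI nor nSTEMI term list",
            hospitalizations=[stay],
            labs=[_troponin(stay, rng, 6.0)],
        )

    return controls
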