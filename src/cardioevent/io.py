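"""File I/O: JSON-lines cohorts, classification/gold CSVs, report JSON, manifests.

Cohorts are streamed as JSON-lines (one patient object per line) so large
extracts diff and concatenate cleanly.  All writers are deterministic:
rerunning with identical inputs yields byte-identical outputs, which the
run manifest records via SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
from pydantic import ValidationError

from cardioevent.agreement import AgreementReport
from cardioevent.ehr_model import PatientRecord

logger = logging.getLogger("cardioevent")

PathLike = Union[str, Path]


class CohortSchemaError(ValueError):
    """One or more JSON-lines records failed validation; lists all offenders."""

    def __init__(self, line_errors: List[tuple]):
        self.line_errors = line_errors
        msgs = "; ".join(f"line {ln}: {msg}" for ln, msg in line_errors)
        super().__init__(f"invalid cohort records — {msgs}")


def read_cohort(path: PathLike) -> List[PatientRecord]:
    """Read and validate a JSON-lines cohort; blank lines are ignored."""
    records: List[PatientRecord] = []
    errors: List[tuple] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(PatientRecord.model_validate_json(line))
            except (ValidationError, ValueError) as err:
                errors.append((lineno, _summarize_error(err)))
    if errors:
        raise CohortSchemaError(errors)
    if not records:
        logger.warning("cohort file %s contains no records", path)
    return records


def _summarize_error(err: Exception) -> str:
    if isinstance(err, ValidationError):
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        return f"{loc or '<record>'}: {first['msg']}"
    return str(err)


def write_cohort(records: Sequence[PatientRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for record in records:
            fh.write(record.model_dump_json())
            fh.write("\n")


def write_classifications(table: pd.DataFrame, path: PathLike) -> None:
    """CSV with stable columns patient_id,version,label,rationale."""
    cols = ["patient_id", "version", "label", "rationale"]
    table.loc[:, cols].to_csv(path, index=False, lineterminator="\n")


def read_classifications(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"patient_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"classification CSV missing column(s): {sorted(missing)}")
    return df


def write_gold(table: pd.DataFrame, path: PathLike) -> None:
    table.loc[:, ["patient_id", "label"]].to_csv(path, index=False, lineterminator="\n")


def read_gold(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"patient_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"gold CSV missing column(s): {sorted(missing)}")
    return df


def write_report(report: AgreementReport, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: PathLike) -> AgreementReport:
    with open(path, "r", encoding="utf-8") as fh:
        return AgreementReport.from_dict(json.load(fh))


def sha256_file(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj: object) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    ).hexdigest()


@dataclass
class RunManifest:
    """Provenance for one CLI run: tool version, digests of config and inputs."""

    tool_version: str
    command: str
    config_digest: str
    input_digests: Dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
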