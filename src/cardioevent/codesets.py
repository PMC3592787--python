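"""Declarative code-matching engine for ICD-9-CM ranges and IMO term lists.

All three algorithm generations are written in terms of named code sets
(acute-MI ranges, heart-failure codes, pacemaker/defibrillator procedures,
the IMO interface terms that split ambiguous 410.9 into STEMI and nSTEMI).
A :class:`CodeSpec` expresses one matching rule — exact code, prefix at a
code boundary, numeric rubric range, or prefix-with-exclusions — and a
:class:`CodeSet` is a named union of specs.  Sites can extend the built-in
registry (for instance with additional IMO terms) from a YAML file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import yaml

from cardioevent.ehr_model import CodedDiagnosis, CodeSystem


class SpecKind(str, Enum):
    EXACT = "EXACT"
    PREFIX = "PREFIX"
    RUBRIC_RANGE = "RUBRIC_RANGE"
    PREFIX_EXCEPT = "PREFIX_EXCEPT"


class MalformedSpecError(ValueError):
    pass


_PARSE = re.compile(r"(?P<int>\d+)(?:\.(?P<dec>\d+))?(?P<letters>[A-Z]*)")


def _parse_code(code: str) -> Tuple[str, str, str]:
    """Split a normalized code into (integer rubric, decimal digits, letter suffix)."""
    m = _PARSE.fullmatch(code)
    if m is None:
        raise MalformedSpecError(f"cannot parse code {code!r}")
    return m.group("int"), m.group("dec") or "", m.group("letters")


def _rubric_value(code: str, decimals: int) -> Tuple[int, int] | None:
    """Numeric value of a code truncated to *decimals* decimal digits.

    Returns ``None`` when the code carries fewer decimal digits than the
    requested precision: a bare rubric like ``410`` is not within a
    four-digit range such as 410.0-410.6, while ``410.65`` truncates to
    410.6 and is (fifth digits subdivide the four-digit rubric).
    """
    intpart, dec, _ = _parse_code(code)
    if len(dec) < decimals:
        return None
    return int(intpart), int(dec[:decimals]) if decimals else 0


def _prefix_match(code: str, prefix: str, allow_letters: bool) -> bool:
    """Prefix match at a code boundary.

    ``410.7`` matches ``410.7``/``410.71``; ``425`` matches ``425``/``425.4``
    but never ``4254``.  A letter remainder (IMO-style ``410.75X`` against
    ``410.7``, or ``410.91D`` against ``410.91``) only matches when
    *allow_letters* is set.
    """
    if code == prefix:
        return True
    if "." in prefix:
        if not code.startswith(prefix):
            return False
        rest = code[len(prefix):]
    else:
        if not code.startswith(prefix + "."):
            return False
        rest = code[len(prefix) + 1:]
    m = re.fullmatch(r"\d*(?P<letters>[A-Z]*)", rest)
    if m is None:
        return False
    if m.group("letters") and not allow_letters:
        return False
    return True


PayloadType = Union[str, Tuple[str, str], Tuple[str, Tuple[str, ...]]]


@dataclass(frozen=True)
class CodeSpec:
    """One declarative matching rule against codes of a single system."""

    system: CodeSystem
    kind: SpecKind
    payload: PayloadType

    def __post_init__(self) -> None:
        if self.kind in (SpecKind.EXACT, SpecKind.PREFIX):
            if not isinstance(self.payload, str) or not self.payload:
                raise MalformedSpecError(f"{self.kind.value} payload must be a non-empty string")
        elif self.kind is SpecKind.RUBRIC_RANGE:
            lo, hi = self.payload  # type: ignore[misc]
            if not lo or not hi:
                raise MalformedSpecError("range endpoints must be non-empty")
            lo_i, lo_d, lo_s = _parse_code(lo)
            hi_i, hi_d, hi_s = _parse_code(hi)
            if lo_s or hi_s:
                raise MalformedSpecError("range endpoints must be numeric rubrics")
            if len(lo_d) != len(hi_d):
                raise MalformedSpecError("range endpoints must share decimal precision")
            if (int(lo_i), int(lo_d or 0)) > (int(hi_i), int(hi_d or 0)):
                raise MalformedSpecError(f"range low {lo} exceeds high {hi}")
        elif self.kind is SpecKind.PREFIX_EXCEPT:
            prefix, excluded = self.payload  # type: ignore[misc]
            if not prefix:
                raise MalformedSpecError("PREFIX_EXCEPT prefix must be non-empty")
            if not excluded:
                raise MalformedSpecError("PREFIX_EXCEPT exclusion list must be non-empty")
            object.__setattr__(self, "payload", (prefix, tuple(excluded)))


def matches(code: CodedDiagnosis, spec: CodeSpec) -> bool:
    """Whether one coded diagnosis satisfies one spec.

    A system mismatch (e.g. an ICD-9-CM code against an IMO spec) is simply
    ``False``: mixed extracts are expected.
    """
    if code.system != spec.system:
        return False
    allow_letters = spec.system is CodeSystem.IMO
    if spec.kind is SpecKind.EXACT:
        return code.code == spec.payload
    if spec.kind is SpecKind.PREFIX:
        return _prefix_match(code.code, spec.payload, allow_letters)  # type: ignore[arg-type]
    if spec.kind is SpecKind.RUBRIC_RANGE:
        lo, hi = spec.payload  # type: ignore[misc]
        decimals = len(_parse_code(lo)[1])
        value = _rubric_value(code.code, decimals)
        if value is None:
            return False
        lo_v = _rubric_value(lo, decimals)
        hi_v = _rubric_value(hi, decimals)
        return lo_v <= value <= hi_v  # type: ignore[operator]
    if spec.kind is SpecKind.PREFIX_EXCEPT:
        prefix, excluded = spec.payload  # type: ignore[misc]
        return _prefix_match(code.code, prefix, allow_letters) and code.code not in excluded
    raise MalformedSpecError(f"unknown spec kind {spec.kind}")


@dataclass(frozen=True)
class CodeSet:
    """A named union of code specs."""

    name: str
    specs: Tuple[CodeSpec, ...]

    def __init__(self, name: str, specs: Iterable[CodeSpec]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "specs", tuple(specs))

    def matches_code(self, code: CodedDiagnosis) -> bool:
        return any(matches(code, s) for s in self.specs)


def any_match(codes: Sequence[CodedDiagnosis], codeset: CodeSet) -> bool:
    """True iff any code in the sequence matches any spec of the set."""
    return any(codeset.matches_code(c) for c in codes)


# The IMO interface terms that disambiguate ICD-9-CM 410.9 (acute MI,
# unspecified site) into ST-elevation vs non-ST-elevation infarction.
STEMI_IMO_TERMS = (
    "410.90CP", "410.90CS", "410.90CU", "410.90CX", "410.90DV", "410.90FZ",
    "410.90GB", "410.90GD", "410.91D", "410.92F", "410.92S",
)
NSTEMI_IMO_TERMS = (
    "410.90BT", "410.90CQ", "410.90CR", "410.90FY", "410.90GC", "410.90GE",
    "410.90N", "410.92E", "410.92H",
)

_DX_SYSTEMS = (CodeSystem.ICD9CM, CodeSystem.IMO)


def _both(kind: SpecKind, payload: PayloadType) -> List[CodeSpec]:
    """The same rule stated for ICD-9-CM codes and for IMO interface terms.

    IMO terms refine ICD-9-CM codes, so a diagnostic range such as 410-414
    covers an extract coded in either vocabulary.
    """
    return [CodeSpec(sys, kind, payload) for sys in _DX_SYSTEMS]


def builtin_codesets() -> Dict[str, CodeSet]:
    """Registry of the named code sets used by the three algorithm generations."""
    raw: Dict[str, List[CodeSpec]] = {
        # "Heart disease" wherever the criteria say so: rubrics 410-414
        # (ischemic heart disease), 425 (cardiomyopathy), 428 (heart failure).
        "HEART_DISEASE": (
            _both(SpecKind.RUBRIC_RANGE, ("410", "414"))
            + _both(SpecKind.PREFIX, "425")
            + _both(SpecKind.PREFIX, "428")
        ),
        # Acute-MI fourth digits that are specific for STEMI.
        "STEMI_ICD9_DEFINITE": [
            CodeSpec(CodeSystem.ICD9CM, SpecKind.RUBRIC_RANGE, ("410.0", "410.6")),
            CodeSpec(CodeSystem.ICD9CM, SpecKind.PREFIX, "410.8"),
        ],
        # 410.7 (subendocardial, i.e. nSTEMI) and ambiguous 410.9.
        "MI_AMBIGUOUS": [
            CodeSpec(CodeSystem.ICD9CM, SpecKind.PREFIX, "410.7"),
            CodeSpec(CodeSystem.ICD9CM, SpecKind.PREFIX, "410.9"),
        ],
        "MI_ANY": [CodeSpec(CodeSystem.ICD9CM, SpecKind.RUBRIC_RANGE, ("410.0", "410.9"))],
        "STEMI_IMO": [CodeSpec(CodeSystem.IMO, SpecKind.EXACT, t) for t in STEMI_IMO_TERMS],
        "NSTEMI_IMO": (
            [CodeSpec(CodeSystem.IMO, SpecKind.EXACT, t) for t in NSTEMI_IMO_TERMS]
            + [CodeSpec(CodeSystem.IMO, SpecKind.PREFIX_EXCEPT, ("410.91", ("410.91D",)))]
        ),
        "HF_CODES": _both(SpecKind.PREFIX, "425") + _both(SpecKind.PREFIX, "428"),
        "OTHER_HEART_420_429": _both(SpecKind.RUBRIC_RANGE, ("420", "429")),
        "UA_CODES": _both(SpecKind.PREFIX, "411") + _both(SpecKind.PREFIX, "786.5"),
        "CHEST_PAIN": _both(SpecKind.PREFIX, "786.5"),
        "PACER_DEFIB": [
            CodeSpec(CodeSystem.ICD9PROC, SpecKind.RUBRIC_RANGE, ("37.80", "37.99")),
            CodeSpec(CodeSystem.CPT4, SpecKind.EXACT, "33216"),
        ],
        "CHRONIC_V1": (
            _both(SpecKind.RUBRIC_RANGE, ("412", "414"))
            + _both(SpecKind.RUBRIC_RANGE, ("420", "429"))
        ),
        # Third-generation composites: "any discharge code starting with ..."
        # applies to ICD-9-CM codes and IMO terms alike, plus the explicit
        # IMO term lists that split 410.9.
        "STEMI_V3": (
            _both(SpecKind.RUBRIC_RANGE, ("410.0", "410.6"))
            + _both(SpecKind.PREFIX, "410.8")
            + [CodeSpec(CodeSystem.IMO, SpecKind.EXACT, t) for t in STEMI_IMO_TERMS]
        ),
        "NSTEMI_V3": (
            _both(SpecKind.PREFIX, "410.7")
            + [CodeSpec(CodeSystem.IMO, SpecKind.EXACT, t) for t in NSTEMI_IMO_TERMS]
            + [CodeSpec(CodeSystem.IMO, SpecKind.PREFIX_EXCEPT, ("410.91", ("410.91D",)))]
        ),
    }
    return {name: CodeSet(name, specs) for name, specs in raw.items()}


def load_codesets(path: str) -> Dict[str, CodeSet]:
    """Load additional code sets from YAML: ``name: [{system, kind, payload}, ...]``.

    Payload forms: a string (EXACT/PREFIX), a two-element list (RUBRIC_RANGE
    low/high), or a mapping ``{prefix: ..., except: [...]}`` (PREFIX_EXCEPT).
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    registry: Dict[str, CodeSet] = {}
    for name, entries in data.items():
        specs = []
        for entry in entries:
            system = CodeSystem(entry["system"])
            kind = SpecKind(entry["kind"])
            payload = entry["payload"]
            if kind is SpecKind.RUBRIC_RANGE:
                payload = (str(payload[0]), str(payload[1]))
            elif kind is SpecKind.PREFIX_EXCEPT:
                payload = (str(payload["prefix"]), tuple(payload["except"]))
            specs.append(CodeSpec(system, kind, payload))
        registry[name] = CodeSet(name, specs)
    return registry
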