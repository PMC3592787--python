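"""Agreement statistics between algorithm labels and manual-review labels.

Provides the confusion matrix (algorithm on rows, gold standard on columns),
observed and per-category agreement, and Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),

where p_o is the observed proportion of agreement (the trace over n) and
p_e = sum_i p_i. * p_.i is the agreement expected by chance from the
marginals.  The default 95% CI uses Cohen's large-sample standard error

    SE = sqrt( p_o (1 - p_o) / (n (1 - p_e)^2) );

the Fleiss-Cohen-Everitt variance is available as an option.  Endpoints are
truncated to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class ConfusionMatrix:
    """Square label-by-label count table; rows = algorithm, columns = gold."""

    labels: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if k < 2:
            raise ValueError("need at least 2 categories")
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion_matrix(
    pred: Mapping[str, str],
    gold: Mapping[str, str],
    labels: Sequence[str],
) -> ConfusionMatrix:
    """Cross-tabulate per-patient algorithm labels against gold labels."""
    if not pred or not gold:
        raise ValueError("pred and gold must be non-empty")
    if set(pred) != set(gold):
        missing = set(pred) ^ set(gold)
        raise ValueError(f"pred and gold patient_id sets differ (e.g. {sorted(missing)[:5]})")
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        raise ValueError("labels must be unique")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for pid, p_label in pred.items():
        g_label = gold[pid]
        try:
            counts[index[p_label], index[g_label]] += 1
        except KeyError as err:
            raise ValueError(f"label {err} for patient {pid!r} not in label list") from None
    return ConfusionMatrix(labels=list(labels), counts=counts)


def observed_agreement(m: ConfusionMatrix) -> float:
    """Proportion of exact agreement: trace / n."""
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m.counts)) / m.n


def expected_agreement(m: ConfusionMatrix) -> float:
    """Chance agreement from the marginals: sum of p_i. * p_.i."""
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    n = m.n
    return float((m.row_totals() * m.col_totals()).sum()) / (n * n)


def cohens_kappa(m: ConfusionMatrix) -> float:
    """Chance-corrected agreement between the two raters."""
    if m.n < 2:
        raise ValueError("need n >= 2 for kappa")
    p_o = observed_agreement(m)
    p_e = expected_agreement(m)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: expected agreement 1 with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_se(m: ConfusionMatrix, method: str = "cohen") -> float:
    """Large-sample standard error of kappa.

    ``"cohen"`` is the simple asymptotic form sqrt(p_o(1-p_o)/(n(1-p_e)^2));
    ``"fleiss"`` is the Fleiss-Cohen-Everitt variance, which accounts for
    the marginal structure of the table.
    """
    n = m.n
    p_o = observed_agreement(m)
    p_e = expected_agreement(m)
    if p_e == 1.0:
        if p_o == 1.0:
            return 0.0
        raise ValueError("SE undefined: expected agreement 1 with imperfect agreement")
    if method == "cohen":
        return float(np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2)))
    if method == "fleiss":
        p = m.counts / n
        pi_dot = p.sum(axis=1)
        p_dot_i = p.sum(axis=0)
        k = cohens_kappa(m)
        diag = np.diag(p)
        term1 = float(np.sum(diag * (1.0 - (pi_dot + p_dot_i) * (1.0 - k)) ** 2))
        cross = (p_dot_i[None, :] + pi_dot[:, None]) ** 2
        off = p * cross
        np.fill_diagonal(off, 0.0)
        term2 = float((1.0 - k) ** 2 * off.sum())
        term3 = float((k - p_e * (1.0 - k)) ** 2)
        var = (term1 + term2 - term3) / (n * (1.0 - p_e) ** 2)
        return float(np.sqrt(max(var, 0.0)))
    raise ValueError(f"unknown SE method {method!r}")


def kappa_ci(
    m: ConfusionMatrix,
    level: float = 0.95,
    method: str = "cohen",
) -> Tuple[float, float]:
    """Normal-approximation CI for kappa, truncated to [-1, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    k = cohens_kappa(m)
    se = kappa_se(m, method=method)
    z = stats.norm.ppf(0.5 + level / 2.0)
    low, high = k - z * se, k + z * se
    return max(low, -1.0), min(high, 1.0)


@dataclass
class CategoryAgreement:
    concordant: int
    total: int
    proportion: Optional[float]  # None when the denominator is zero


def per_category_agreement(
    m: ConfusionMatrix,
    basis: str = "ALGORITHM_ROWS",
) -> Dict[str, CategoryAgreement]:
    """Per-category agreement: diagonal over row (or column) totals.

    The ALGORITHM_ROWS basis uses the number of cases the algorithm assigned
    to the category as denominator — the convention of reporting agreement
    among "cases identified by the computer algorithm".
    """
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    if basis == "ALGORITHM_ROWS":
        totals = m.row_totals()
    elif basis == "GOLD_COLUMNS":
        totals = m.col_totals()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    out: Dict[str, CategoryAgreement] = {}
    for i, lab in enumerate(m.labels):
        concordant = int(m.counts[i, i])
        total = int(totals[i])
        out[lab] = CategoryAgreement(
            concordant=concordant,
            total=total,
            proportion=(concordant / total) if total else None,
        )
    return out


@dataclass
class AgreementReport:
    """Full validation summary, serializable to/from plain dicts (JSON)."""

    labels: List[str]
    n: int
    observed_agreement: float
    expected_agreement: float
    kappa: float
    ci_low: float
    ci_high: float
    level: float
    per_category: Dict[str, CategoryAgreement]
    confusion: List[List[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "n": self.n,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "kappa": self.kappa,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "per_category": {
                lab: {
                    "concordant": c.concordant,
                    "total": c.total,
                    "proportion": c.proportion,
                }
                for lab, c in self.per_category.items()
            },
            "confusion": self.confusion,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementReport":
        return cls(
            labels=list(d["labels"]),
            n=int(d["n"]),
            observed_agreement=float(d["observed_agreement"]),
            expected_agreement=float(d["expected_agreement"]),
            kappa=float(d["kappa"]),
            ci_low=float(d["ci_low"]),
            ci_high=float(d["ci_high"]),
            level=float(d["level"]),
            per_category={
                lab: CategoryAgreement(
                    concordant=int(c["concordant"]),
                    total=int(c["total"]),
                    proportion=None if c["proportion"] is None else float(c["proportion"]),
                )
                for lab, c in d["per_category"].items()
            },
            confusion=[list(map(int, row)) for row in d["confusion"]],
        )


def validation_report(
    pred: Mapping[str, str],
    gold: Mapping[str, str],
    labels: Sequence[str],
    level: float = 0.95,
    se_method: str = "cohen",
) -> AgreementReport:
    """Assemble confusion matrix, agreement, kappa and CI into one report."""
    m = confusion_matrix(pred, gold, labels)
    low, high = kappa_ci(m, level=level, method=se_method)
    return AgreementReport(
        labels=list(labels),
        n=m.n,
        observed_agreement=observed_agreement(m),
        expected_agreement=expected_agreement(m),
        kappa=cohens_kappa(m),
        ci_low=low,
        ci_high=high,
        level=level,
        per_category=per_category_agreement(m),
        confusion=m.counts.tolist(),
    )
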