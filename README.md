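# cardioevent

Rule-based classification of acute coronary and heart-failure events from
structured electronic-health-record data, for disease-surveillance work that
wants to avoid manual chart review.

Given one structured extract per patient — hospital discharge diagnoses
(ICD-9-CM codes and IMO interface terms), troponin and BNP results with
their assay upper limits of normal (ULN), coded ECG interpretation
statements, echocardiographic ejection fraction (EF), insurance claims and
the enrollment start date — the package assigns each patient one event
category for a surveillance period: **STEMI**, **systolic heart failure**,
**nSTEMI**, **unstable angina**, **ambulatory presentation**, **chronic
prevalent disease**, or **unclassified**. The categories are hierarchical:
criteria are evaluated in clinical-priority order and the first match wins,
so a STEMI complicated by acute heart failure is a STEMI.

Three algorithm generations are implemented:

| | MI split | key criteria |
|---|---|---|
| **V1** | STEMI/nSTEMI merged | 410.x discharge codes + any troponin > ULN; HF = primary 425/428 + BNP > ULN |
| **V2** | ECG-based | ST-elevation ECG statement codes 964–968 + troponin > 3×ULN split 410.7/410.9; HF adds EF ≤ 35%; pacemaker/defibrillator procedures (37.80–37.99, CPT-4 33216) excluded from unstable angina |
| **V3** | IMO interface terms | terms such as 410.90CP (STEMI) vs 410.91 except 410.91D (nSTEMI) split the ambiguous 410.9; unstable angina dropped; ambulatory and chronic merged |

Validation against gold-standard (manual-review) labels uses the confusion
matrix, observed and per-category agreement, and Cohen's κ

    κ = (p_o − p_e) / (1 − p_e),   SE = sqrt( p_o (1 − p_o) / (n (1 − p_e)²) )

with normal-approximation confidence intervals truncated to [−1, 1]. A
seeded synthetic-cohort generator produces records that provably satisfy (or
minimally violate) each category's criteria, including injected
algorithm-vs-reviewer discordances, so the whole pipeline is testable
without patient data.

## Worked example

```python
from datetime import date
import numpy as np
from cardioevent import (
    PeriodOfInterest, AlgorithmConfig, CohortSpec, Label, Version,
    generate_cohort, classify_cohort, validation_report,
)

period = PeriodOfInterest(start=date(2010, 1, 1), end=date(2010, 12, 31))
spec = CohortSpec(
    version=Version.V3, period=period,
    counts={Label.STEMI: 50, Label.NSTEMI: 49,
            Label.SYSTOLIC_HF: 34, Label.AMBULATORY_OR_CHRONIC: 50},
    discordance={(Label.NSTEMI, Label.SYSTOLIC_HF): 1},
    seed=1,
)
records, gold = generate_cohort(spec)
table = classify_cohort(records, Version.V3, AlgorithmConfig(period=period))
report = validation_report(
    dict(zip(table.patient_id, table.label)),
    dict(zip(gold.patient_id, gold.label)),
    ["STEMI", "SYSTOLIC_HF", "NSTEMI", "AMBULATORY_OR_CHRONIC"],
)
print(f"n={report.n} agreement={report.observed_agreement:.4f} "
      f"kappa={report.kappa:.4f} CI=({report.ci_low:.2f}, {report.ci_high:.2f})")
```

prints

```
n=184 agreement=0.9946 kappa=0.9927 CI=(0.98, 1.00)
```

184 patients, one disagreement (a heart-failure admission whose primary
discharge code is an nSTEMI interface term, which the algorithm reads as
nSTEMI): observed agreement 183/184, κ 0.99 with 95% CI 0.98–1.00 — the
near-perfect agreement achievable once interface terms disambiguate 410.9.

The same workflow is available from the shell:

```bash
cardioevent simulate --spec spec.yaml --out cohort.jsonl --gold gold.csv --seed 1
cardioevent classify --input cohort.jsonl --config config.yaml --out cls.csv
cardioevent validate --pred cls.csv --gold gold.csv \
    --labels STEMI,SYSTOLIC_HF,NSTEMI,AMBULATORY_OR_CHRONIC --out report.json
cardioevent codesets list
```

## Layout

- `cardioevent.ehr_model` — extract schema, episode-of-care linkage
- `cardioevent.codesets` — declarative ICD-9-CM / IMO code matching
- `cardioevent.phenotyper` — the three hierarchical algorithms
- `cardioevent.agreement` — confusion matrix, κ, confidence intervals
- `cardioevent.synthetic` — seeded cohort generator and negative controls
- `cardioevent.io` / `cardioevent.cli` — files, manifests, command line

See `docs/methods.md` for the modelling assumptions and design choices.
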