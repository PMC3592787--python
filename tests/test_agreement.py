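"""Confusion matrix, observed/per-category agreement, Cohen's kappa and CI.

The kappa implementation is checked against two independent routes: a
rational-arithmetic brute-force oracle defined here, and the implementations
in statsmodels / scikit-learn.
"""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

from cardioevent.agreement import (
    CategoryAgreement,
    ConfusionMatrix,
    cohens_kappa,
    confusion_matrix,
    expected_agreement,
    kappa_ci,
    kappa_se,
    observed_agreement,
    per_category_agreement,
    validation_report,
)

LABELS4 = ["STEMI", "SYSTOLIC_HF", "NSTEMI", "AMBULATORY_OR_CHRONIC"]


def third_generation_matrix() -> ConfusionMatrix:
    """Reconstruction from the study's sampling counts and single disagreement.

    Algorithm rows: 50 STEMI, 50 nSTEMI, 34 heart failure, 50 ambulatory/
    chronic; the one off-diagonal case was called nSTEMI by the algorithm and
    systolic heart failure by the reviewers.
    """
    counts = np.diag([50, 49, 34, 50])
    labels = ["STEMI", "NSTEMI", "SYSTOLIC_HF", "AMBULATORY_OR_CHRONIC"]
    counts[1, 2] = 1  # algorithm NSTEMI, gold SYSTOLIC_HF
    return ConfusionMatrix(labels=labels, counts=counts)


def second_generation_matrix() -> ConfusionMatrix:
    """Diagonal from printed per-category counts; remainders off-diagonal."""
    diag = [16, 21, 39, 19, 23, 45]
    totals = [24, 21, 50, 50, 50, 50]
    labels = ["STEMI", "SYSTOLIC_HF", "NSTEMI", "UNSTABLE_ANGINA", "AMBULATORY", "CHRONIC"]
    counts = np.zeros((6, 6), dtype=int)
    for i, (d, t) in enumerate(zip(diag, totals)):
        counts[i, i] = d
        counts[i, (i + 1) % 6] += t - d
    return ConfusionMatrix(labels=labels, counts=counts)


# ---------------------------------------------------------------------------
# Independent oracle: explicit rational summation
# ---------------------------------------------------------------------------

def oracle_kappa(counts: np.ndarray) -> Fraction:
    n = int(counts.sum())
    k = counts.shape[0]
    po = Fraction(int(np.trace(counts)), n)
    pe = sum(
        Fraction(int(counts[i, :].sum()) * int(counts[:, i].sum()), n * n)
        for i in range(k)
    )
    return (po - pe) / (1 - pe)


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        pred = {f"p{i}": ("A" if i < 6 else "B") for i in range(10)}
        m = confusion_matrix(pred, dict(pred), ["A", "B"])
        assert m.n == 10
        assert np.array_equal(m.counts, [[6, 0], [0, 4]])

    def test_single_disagreement_off_diagonal(self):
        pred = {"p": "NSTEMI"}
        gold = {"p": "SYSTOLIC_HF"}
        m = confusion_matrix(pred, gold, ["NSTEMI", "SYSTOLIC_HF"])
        assert m.counts[0, 1] == 1 and m.counts.sum() == 1

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix({}, {}, ["A", "B"])
        with pytest.raises(ValueError):
            confusion_matrix({"a": "A"}, {"b": "A"}, ["A", "B"])
        with pytest.raises(ValueError):
            confusion_matrix({"a": "C"}, {"a": "A"}, ["A", "B"])


class TestObservedAgreement:
    def test_second_generation_overall(self):
        m = second_generation_matrix()
        assert m.n == 245
        assert observed_agreement(m) == pytest.approx(163 / 245)

    def test_perfect_and_zero(self):
        perfect = ConfusionMatrix(labels=["A", "B"], counts=np.diag([3, 4]))
        assert observed_agreement(perfect) == 1.0
        zero = ConfusionMatrix(labels=["A", "B"], counts=np.array([[0, 3], [4, 0]]))
        assert observed_agreement(zero) == 0.0


class TestKappa:
    def test_third_generation_value(self):
        k = cohens_kappa(third_generation_matrix())
        assert k == pytest.approx(0.9927, abs=5e-4)
        assert round(k, 2) == 0.99

    def test_perfect_diagonal_is_one(self):
        m = ConfusionMatrix(labels=["A", "B", "C"], counts=np.diag([5, 1, 2]))
        assert cohens_kappa(m) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        m = ConfusionMatrix(labels=["A", "B"], counts=np.array([[25, 25], [25, 25]]))
        assert cohens_kappa(m) == pytest.approx(0.0)

    def test_degenerate_single_category_perfect(self):
        m = ConfusionMatrix(labels=["A", "B"], counts=np.array([[9, 0], [0, 0]]))
        assert cohens_kappa(m) == 1.0

    def test_permutation_invariance(self):
        m = third_generation_matrix()
        rng = np.random.default_rng(11)
        perm = rng.permutation(4)
        permuted = ConfusionMatrix(
            labels=[m.labels[i] for i in perm],
            counts=m.counts[np.ix_(perm, perm)],
        )
        assert cohens_kappa(permuted) == pytest.approx(cohens_kappa(m))

    def test_kappa_bounded_by_observed_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            counts = rng.integers(0, 4, size=(4, 4))
            m = _valid(counts)
            if m is None:
                continue
            k = cohens_kappa(m)
            assert -1.0 - 1e-12 <= k <= observed_agreement(m) + 1e-12

    def test_exhaustive_two_by_two_against_oracle(self):
        """Every 2x2 table with entries 0..3 matches rational-arithmetic oracle."""
        checked = 0
        for cells in product(range(4), repeat=4):
            counts = np.array(cells).reshape(2, 2)
            m = _valid(counts)
            if m is None:
                continue
            assert cohens_kappa(m) == pytest.approx(float(oracle_kappa(counts)), abs=1e-12)
            checked += 1
        assert checked > 200

    def test_sampled_four_by_four_against_oracle_and_libraries(self):
        """Seeded 4x4 samples match the oracle, statsmodels and scikit-learn."""
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 300:
            counts = rng.integers(0, 4, size=(4, 4))
            m = _valid(counts)
            if m is None:
                continue
            k = cohens_kappa(m)
            assert k == pytest.approx(float(oracle_kappa(counts)), abs=1e-12)
            assert k == pytest.approx(sm_kappa(counts, return_results=True).kappa, abs=1e-10)
            pred, gold = _to_label_vectors(counts)
            assert k == pytest.approx(
                cohen_kappa_score(pred, gold, labels=list(range(4))), abs=1e-10
            )
            checked += 1


def _valid(counts: np.ndarray) -> ConfusionMatrix | None:
    """Wrap counts unless kappa is undefined (n < 2 or chance agreement 1)."""
    labels = [str(i) for i in range(counts.shape[0])]
    m = ConfusionMatrix(labels=labels, counts=counts)
    if m.n < 2:
        return None
    if expected_agreement(m) == 1.0:
        return None
    return m


def _to_label_vectors(counts: np.ndarray):
    pred, gold = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            pred += [i] * counts[i, j]
            gold += [j] * counts[i, j]
    return pred, gold


class TestKappaCI:
    def test_third_generation_interval(self):
        m = third_generation_matrix()
        assert kappa_se(m) == pytest.approx(0.00728, abs=5e-5)
        low, high = kappa_ci(m)
        assert round(low, 2) == 0.98
        assert high == 1.0  # truncated from above 1

    def test_perfect_agreement_zero_width(self):
        m = ConfusionMatrix(labels=["A", "B"], counts=np.diag([5, 5]))
        assert kappa_ci(m) == (1.0, 1.0)

    def test_independence_symmetric_about_zero(self):
        m = ConfusionMatrix(labels=["A", "B"], counts=np.array([[25, 25], [25, 25]]))
        low, high = kappa_ci(m)
        # closed form: SE = sqrt(0.25 / (100 * 0.25)) = 0.1
        assert low == pytest.approx(-high)
        assert high == pytest.approx(1.959964 * 0.1, abs=1e-5)

    def test_width_shrinks_with_n(self):
        base = third_generation_matrix()
        big = ConfusionMatrix(labels=base.labels, counts=base.counts * 100)
        w = lambda m: np.diff(kappa_ci(m, method="fleiss"))[0]
        assert w(big) < w(base) / 5

    def test_fleiss_variance_matches_statsmodels(self):
        m = third_generation_matrix()
        se = kappa_se(m, method="fleiss")
        res = sm_kappa(np.asarray(m.counts), return_results=True)
        assert se == pytest.approx(float(np.sqrt(res.var_kappa)), rel=1e-6)


class TestPerCategory:
    def test_second_generation_stemi_row(self):
        m = second_generation_matrix()
        per = per_category_agreement(m)
        assert per["STEMI"].concordant == 16
        assert per["STEMI"].total == 24
        assert per["STEMI"].proportion == pytest.approx(16 / 24)
        assert per["SYSTOLIC_HF"].proportion == 1.0

    def test_first_generation_merged_mi_row(self):
        counts = np.array([[60, 4], [0, 10]])
        m = ConfusionMatrix(labels=["MI_UNSPECIFIED", "OTHER"], counts=counts)
        per = per_category_agreement(m)
        assert per["MI_UNSPECIFIED"].total == 64
        assert per["MI_UNSPECIFIED"].proportion == pytest.approx(0.9375)
        assert round(per["MI_UNSPECIFIED"].proportion * 100) == 94

    def test_zero_denominator_is_undefined_not_zero(self):
        m = ConfusionMatrix(labels=["A", "B"], counts=np.array([[0, 0], [1, 3]]))
        assert per_category_agreement(m)["A"] == CategoryAgreement(0, 0, None)

    def test_gold_columns_basis(self):
        m = third_generation_matrix()
        per = per_category_agreement(m, basis="GOLD_COLUMNS")
        assert per["SYSTOLIC_HF"].total == 35  # 34 concordant + 1 missed by algorithm


class TestValidationReport:
    def test_third_generation_reconstruction(self):
        m = third_generation_matrix()
        pred, gold = {}, {}
        for i, row_label in enumerate(m.labels):
            for j, col_label in enumerate(m.labels):
                for r in range(m.counts[i, j]):
                    pid = f"{i}-{j}-{r}"
                    pred[pid], gold[pid] = row_label, col_label
        report = validation_report(pred, gold, m.labels)
        assert report.n == 184
        assert report.observed_agreement > 0.99
        assert round(report.kappa, 2) == 0.99
        assert round(report.ci_low, 2) == 0.98 and round(report.ci_high, 2) == 1.0
        assert report.confusion == m.counts.tolist()

    def test_identical_vectors(self):
        pred = {f"p{i}": ("A" if i % 2 else "B") for i in range(20)}
        report = validation_report(pred, dict(pred), ["A", "B"])
        assert report.kappa == pytest.approx(1.0)
        assert all(c.proportion == 1.0 for c in report.per_category.values())

    def test_permuted_gold_labels_give_near_zero_kappa(self):
        rng = np.random.default_rng(99)
        labels = ["A", "B", "C", "D"]
        values = [labels[i % 4] for i in range(1000)]
        pred = {f"p{i}": v for i, v in enumerate(values)}
        gold = {f"p{i}": v for i, v in enumerate(rng.permutation(values))}
        report = validation_report(pred, gold, labels)
        assert abs(report.kappa) < 0.1
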