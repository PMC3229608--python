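"""The five performance measures, cross-validation, and measure concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from tsmut.evaluation import (
    EPS,
    acc_mcc,
    class_kl,
    confusion,
    cross_validate,
    distribution_distance,
    evaluate,
    kl_divergence,
    leave_one_protein_out,
    measure_concordance,
    mutual_information,
    precision_recall,
    roc_auc,
)


def brute_force_auc(probs, y):
    """Mann–Whitney pair counting: P(score_TS > score_neutral) + ½ ties."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_split(self):
        probs = np.r_[np.ones(5), np.zeros(5)]
        y = np.r_[np.ones(5), np.zeros(5)]
        assert confusion(probs, y) == (5, 0, 5, 0)

    def test_threshold_inclusive(self):
        probs = np.full(10, 0.5)
        y = np.r_[np.ones(4), np.zeros(6)]
        tp, fp, tn, fn = confusion(probs, y)
        assert (tp, fp) == (4, 6) and (tn, fn) == (0, 0)

    def test_matches_loop_recount(self):
        rng = np.random.default_rng(0)
        probs = rng.random(200)
        y = rng.integers(0, 2, 200)
        tp, fp, tn, fn = confusion(probs, y, 0.4)
        exp = [0, 0, 0, 0]
        for p, yy in zip(probs, y):
            pred = p >= 0.4
            if pred and yy:
                exp[0] += 1
            elif pred:
                exp[1] += 1
            elif not yy:
                exp[2] += 1
            else:
                exp[3] += 1
        assert (tp, fp, tn, fn) == tuple(exp)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestAccMcc:
    def test_perfect(self):
        assert acc_mcc((50, 0, 50, 0)) == (1.0, 1.0)

    def test_inverted(self):
        acc, mcc = acc_mcc((0, 50, 0, 50))
        assert acc == 0.0 and mcc == pytest.approx(-1.0)

    def test_arithmetic_example(self):
        acc, mcc = acc_mcc((40, 20, 30, 10))
        assert mcc == pytest.approx(1000 / math.sqrt(60 * 50 * 50 * 40))
        assert acc == pytest.approx(0.7)

    def test_zero_denominator_gives_zero(self):
        _, mcc = acc_mcc((0, 0, 50, 50))
        assert mcc == 0.0

    def test_label_inversion_flips_mcc(self):
        rng = np.random.default_rng(1)
        probs = rng.random(100)
        y = rng.integers(0, 2, 100)
        while y.sum() in (0, 100):
            y = rng.integers(0, 2, 100)
        _, mcc = acc_mcc(confusion(probs, y))
        acc_i, mcc_i = acc_mcc(confusion(1 - probs + 1e-12, y))
        assert mcc_i == pytest.approx(-mcc, abs=0.05)


class TestKl:
    def test_identical_distributions_zero(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0)

    def test_point_mass_vs_fair_coin(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet([1, 1])
        q = rng.dirichlet([1, 1])
        expected = sum(pi * math.log2(pi / qi) for pi, qi in zip(p, q))
        assert kl_divergence(p, q) == pytest.approx(expected)


class TestDistributionDistance:
    def test_identical_class_distributions_zero(self):
        probs = np.r_[np.tile([0.1, 0.5, 0.9], 10), np.tile([0.1, 0.5, 0.9], 10)]
        y = np.r_[np.ones(30), np.zeros(30)]
        assert distribution_distance(probs, y) == pytest.approx(0.0, abs=1e-9)

    def test_fully_separated_closed_form(self):
        """TS in the last bin, neutral in the first: value fixed by ε."""
        probs = np.r_[np.full(20, 0.99), np.full(20, 0.01)]
        y = np.r_[np.ones(20), np.zeros(20)]
        # P = (ε..ε,1)/Z, Q = (1,ε..ε)/Z with Z = 1 + 9ε
        z = 1 + 9 * EPS
        p = np.full(10, EPS / z)
        p[-1] = 1 / z
        q = np.full(10, EPS / z)
        q[0] = 1 / z
        expected = np.sum(p * np.log2(p / q))
        assert distribution_distance(probs, y) == pytest.approx(expected)

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(3)
        probs = rng.random(60)
        y = rng.integers(0, 2, 60)
        while y.sum() in (0, 60):
            y = rng.integers(0, 2, 60)
        base = distribution_distance(probs, y)
        perm = rng.permutation(60)
        assert distribution_distance(probs[perm], y[perm]) == pytest.approx(base)
        assert distribution_distance(np.r_[probs, probs], np.r_[y, y]) == pytest.approx(base)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance(np.random.rand(10), np.ones(10))


class TestRocAuc:
    def test_perfect_separation(self):
        probs = np.r_[np.linspace(0.6, 1, 10), np.linspace(0, 0.4, 10)]
        y = np.r_[np.ones(10), np.zeros(10)]
        _, auc = roc_auc(probs, y)
        assert auc == 1.0

    def test_constant_scores_half(self):
        probs = np.full(20, 0.5)
        y = np.r_[np.ones(10), np.zeros(10)]
        _, auc = roc_auc(probs, y)
        assert auc == 0.5

    def test_ties_counted_half_vs_brute_force(self):
        probs = np.array([0.1, 0.4, 0.4, 0.6, 0.8, 0.8])
        y = np.array([0, 0, 1, 0, 1, 1])
        _, auc = roc_auc(probs, y)
        assert auc == pytest.approx(brute_force_auc(probs, y), abs=1e-12)

    def test_trapezoid_equals_mann_whitney_without_ties(self):
        rng = np.random.default_rng(4)
        probs = rng.random(100)
        y = rng.integers(0, 2, 100)
        while y.sum() in (0, 100):
            y = rng.integers(0, 2, 100)
        roc, auc = roc_auc(probs, y)
        pts = np.array(roc)
        trap = np.trapezoid(pts[:, 1], pts[:, 0])
        assert trap == pytest.approx(auc, abs=1e-12)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 200)
        y = rng.integers(0, 2, 200)
        while y.sum() in (0, 200):
            y = rng.integers(0, 2, 200)
        _, auc = roc_auc(probs, y)
        assert auc == pytest.approx(roc_auc_score(y, probs), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.random.rand(5), np.ones(5))

    @settings(max_examples=100, derandomize=True)
    @given(
        st_.lists(st_.floats(min_value=0, max_value=1, allow_nan=False),
                  min_size=4, max_size=30),
        st_.randoms(use_true_random=False),
    )
    def test_score_negation_complements_auc(self, scores, rand):
        probs = np.asarray(scores)
        y = np.array([rand.randint(0, 1) for _ in scores])
        if y.sum() in (0, y.size):
            y[0] = 1 - y[0]
        _, auc = roc_auc(probs, y)
        _, auc_neg = roc_auc(-probs, y)
        assert auc + auc_neg == pytest.approx(1.0, abs=1e-12)


class TestPrecisionRecall:
    def test_perfect_ranking_unit_precision(self):
        probs = np.r_[np.linspace(0.6, 1, 5), np.linspace(0, 0.4, 5)]
        y = np.r_[np.ones(5), np.zeros(5)]
        pr = precision_recall(probs, y)
        assert all(prec == 1.0 for rec, prec in pr if rec <= 1.0)

    def test_reversed_ranking_prevalence_at_full_recall(self):
        probs = np.r_[np.linspace(0, 0.4, 5), np.linspace(0.6, 1, 5)]
        y = np.r_[np.ones(5), np.zeros(5)]
        pr = precision_recall(probs, y)
        full = [prec for rec, prec in pr if rec == 1.0]
        assert full[-1] == pytest.approx(0.5)  # prevalence

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        probs = rng.random(50)
        y = rng.integers(0, 2, 50)
        while y.sum() in (0, 50):
            y = rng.integers(0, 2, 50)
        pr = precision_recall(probs, y)
        # loop oracle: one point per distinct threshold, descending, stopping
        # at the first threshold that achieves full recall
        expected = []
        for t in sorted(np.unique(probs), reverse=True):
            tp = ((probs >= t) & (y == 1)).sum()
            fp = ((probs >= t) & (y == 0)).sum()
            fn = ((probs < t) & (y == 1)).sum()
            expected.append((tp / (tp + fn), tp / (tp + fp)))
            if fn == 0:
                break
        assert pr == pytest.approx(expected)


class _MeanModel:
    """Deterministic scorer: distance of x to the positive-class train mean."""

    def __init__(self, mu_pos, mu_neg):
        self.mu_pos, self.mu_neg = mu_pos, mu_neg

    def predict_proba(self, X):
        X = np.asarray(X, float)
        d_pos = np.abs(X[:, 0] - self.mu_pos)
        d_neg = np.abs(X[:, 0] - self.mu_neg)
        return 1 / (1 + np.exp(d_pos - d_neg))


def _mean_fit(values, y):
    x = np.asarray(values, float)[:, 0]
    y = np.asarray(y)
    return _MeanModel(x[y == 1].mean(), x[y == 0].mean())


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, 100)
    x = rng.normal(loc=y * 1.5, size=100)
    return pd.DataFrame({"x": x}), y


class TestCrossValidation:
    def test_every_row_in_exactly_one_test_fold(self, data):
        values, y = data
        report = cross_validate(values, y, _mean_fit, k=10, seed=0)
        assert report.n_pos + report.n_neg == 100

    def test_deterministic_under_seed(self, data):
        values, y = data
        r1 = cross_validate(values, y, _mean_fit, k=10, seed=3)
        r2 = cross_validate(values, y, _mean_fit, k=10, seed=3)
        assert r1.auc == r2.auc and r1.mcc == r2.mcc

    def test_leave_one_out_equals_enumeration(self, data):
        """With a deterministic scorer, k = n folds equal direct enumeration."""
        values, y = data
        n = len(y)
        report = cross_validate(values, y, _mean_fit, k=n, seed=0)
        probs = np.empty(n)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            model = _mean_fit(values.iloc[train], y[train])
            probs[i] = model.predict_proba(values.iloc[[i]])[0]
        _, expected_auc = roc_auc(probs, y)
        assert report.auc == pytest.approx(expected_auc, abs=1e-12)

    def test_lopo_one_report_per_scorable_protein(self, data):
        values, y = data
        pids = np.repeat([f"P{i}" for i in range(5)], 20)
        reports = leave_one_protein_out(values, y, pids, _mean_fit)
        scorable = {f"P{i}" for i in range(5)
                    if len(np.unique(y[pids == f"P{i}"])) == 2}
        assert set(reports) == scorable
        assert len(reports) == 5  # with this seed all proteins have both classes


class TestConcordance:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(8)
        rows = [{"ACC": a, "MCC": m, "AUC": u, "KL": k, "DD": d}
                for a, m, u, k, d in rng.random((20, 5))]
        pearson, mi = measure_concordance(rows)
        np.testing.assert_allclose(np.diag(pearson), 1.0)
        assert pearson.shape == (5, 5) and mi.shape == (5, 5)

    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 15)
        rows = [{"ACC": xi, "MCC": -xi, "AUC": xi, "KL": xi, "DD": xi} for xi in x]
        pearson, _ = measure_concordance(rows)
        assert pearson.loc["ACC", "MCC"] == pytest.approx(-1.0)

    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        table = rng.random((25, 5))
        rows = [dict(zip(("ACC", "MCC", "AUC", "KL", "DD"), r)) for r in table]
        pearson, _ = measure_concordance(rows)
        x, yv = table[:, 0], table[:, 3]
        num = np.sum((x - x.mean()) * (yv - yv.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((yv - yv.mean()) ** 2))
        assert pearson.loc["ACC", "KL"] == pytest.approx(num / den)

    def test_constant_measure_masked(self):
        rows = [{"ACC": 0.5, "MCC": m, "AUC": u, "KL": k, "DD": d}
                for m, u, k, d in np.random.default_rng(10).random((10, 4))]
        pearson, _ = measure_concordance(rows)
        assert math.isnan(pearson.loc["ACC", "MCC"])

    def test_mutual_information_nonnegative_and_symmetricish(self):
        rng = np.random.default_rng(11)
        x, y = rng.random(200), rng.random(200)
        assert mutual_information(x, y) >= 0
        assert mutual_information(x, x) > mutual_information(x, y)

    def test_too_few_classifiers_rejected(self):
        with pytest.raises(ValueError):
            measure_concordance([{"ACC": 1, "MCC": 1, "AUC": 1, "KL": 1, "DD": 1}] * 2)


class TestEvaluateReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 80)
        probs = np.clip(y * 0.6 + rng.normal(0, 0.25, 80), 0, 1)
        report = evaluate(probs, y)
        assert 0 <= report.acc <= 1
        assert -1 <= report.mcc <= 1
        assert 0 <= report.auc <= 1
        assert report.dd >= 0
        tp, fp, tn, fn = confusion(probs, y)
        assert report.acc == pytest.approx((tp + tn) / 80)
        assert report.kl == pytest.approx(class_kl(probs, y))
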