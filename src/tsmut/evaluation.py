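"""The five-measure evaluation suite for TS classifiers.

Threshold measures (at p ≥ 0.5 ⇒ predicted TS): accuracy (ACC), Matthews
correlation coefficient (MCC), and the Kullback–Leibler divergence (KL)
between predicted and observed class probabilities. Threshold-free
measures: area under the ROC curve (AUC, equal to the Mann–Whitney
probability with ties counted one half) and the distribution distance (DD),
a KL-style divergence between the 10-bin histograms of posterior
probabilities of the TS and neutral classes. DD is zero exactly when the
two binned distributions coincide.

All logarithms are base 2 (bits); empty histogram bins and zero
probabilities are smoothed with ε = 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import labels_to_int, stratified_folds

EPS = 1e-10


@dataclass
class EvaluationReport:
    acc: float
    mcc: float
    kl: float
    dd: float
    auc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    pr: list[tuple[float, float]] = field(default_factory=list)
    threshold: float = 0.5
    n_pos: int = 0
    n_neg: int = 0
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ACC": self.acc, "MCC": self.mcc, "KL": self.kl,
            "DD": self.dd, "AUC": self.auc,
            "threshold": self.threshold,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def confusion(probs, labels, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with p ≥ threshold predicting TS (inclusive)."""
    probs = np.asarray(probs, float)
    y = labels_to_int(labels)
    if probs.size == 0:
        raise ValueError("empty input")
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def acc_mcc(conf: tuple[int, int, int, int]) -> tuple[float, float]:
    """Accuracy and Matthews correlation coefficient of a confusion matrix.

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields MCC = 0.
    """
    tp, fp, tn, fn = conf
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    denom_factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in denom_factors):
        return acc, 0.0
    mcc = (tp * tn - fp * fn) / np.sqrt(np.prod([float(f) for f in denom_factors]))
    return acc, float(mcc)


def kl_divergence(pred_dist, obs_dist) -> float:
    """KL divergence Σ P(i) log2(P(i)/Q(i)) over the {TS, neutral} classes."""
    p = np.clip(np.asarray(pred_dist, float), EPS, None)
    q = np.clip(np.asarray(obs_dist, float), EPS, None)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log2(p / q)))


def class_kl(probs, labels, threshold: float = 0.5) -> float:
    """KL between predicted and observed TS/neutral probabilities."""
    tp, fp, tn, fn = confusion(probs, labels, threshold)
    n = tp + fp + tn + fn
    pred = np.array([(tp + fp) / n, (tn + fn) / n])
    obs = np.array([(tp + fn) / n, (tn + fp) / n])
    return kl_divergence(pred, obs)


def distribution_distance(probs, labels, bins: int = 10,
                          prob_range: tuple[float, float] = (0.0, 1.0)) -> float:
    """KL-style distance between binned TS and neutral posterior histograms.

    The probability range is split into ``bins`` equal intervals (last bin
    right-closed); each class histogram is normalized to a distribution with
    ε-smoothing on empty bins. Zero iff the binned distributions coincide.
    """
    probs = np.asarray(probs, float)
    y = labels_to_int(labels)
    if not (y == 1).any() or not (y == 0).any():
        raise ValueError("both classes must be present")
    edges = np.linspace(prob_range[0], prob_range[1], bins + 1)
    h_ts, _ = np.histogram(probs[y == 1], bins=edges)
    h_neu, _ = np.histogram(probs[y == 0], bins=edges)
    p = np.clip(h_ts / h_ts.sum(), EPS, None)
    q = np.clip(h_neu / h_neu.sum(), EPS, None)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log2(p / q)))


def roc_auc(probs, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC.

    AUC is computed as the Mann–Whitney probability that a random TS score
    exceeds a random neutral score, ties counted one half; the trapezoidal
    area under the returned ROC points equals it.
    """
    probs = np.asarray(probs, float)
    y = labels_to_int(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # Mann–Whitney via midranks
    order = np.argsort(probs, kind="mergesort")
    ranks = np.empty(probs.size, float)
    sorted_p = probs[order]
    i = 0
    while i < probs.size:
        j = i
        while j + 1 < probs.size and sorted_p[j + 1] == sorted_p[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # ROC curve over descending unique thresholds
    desc = np.argsort(-probs, kind="mergesort")
    tps = np.cumsum(y[desc] == 1)
    fps = np.cumsum(y[desc] == 0)
    distinct = np.nonzero(np.diff(probs[desc]))[0]
    keep = np.r_[distinct, probs.size - 1]
    roc = [(0.0, 0.0)] + [
        (fps[k] / n_neg, tps[k] / n_pos) for k in keep
    ]
    if roc[-1] != (1.0, 1.0):
        roc.append((1.0, 1.0))
    return roc, float(auc)


def precision_recall(probs, labels) -> list[tuple[float, float]]:
    """(recall, precision) points over descending score thresholds."""
    probs = np.asarray(probs, float)
    y = labels_to_int(labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    desc = np.argsort(-probs, kind="mergesort")
    tps = np.cumsum(y[desc] == 1)
    preds = np.arange(1, probs.size + 1)
    distinct = np.nonzero(np.diff(probs[desc]))[0]
    keep = np.r_[distinct, probs.size - 1]
    # stop at the first threshold achieving full recall
    full = np.nonzero(tps[keep] == n_pos)[0]
    if full.size:
        keep = keep[: full[0] + 1]
    return [(tps[k] / n_pos, tps[k] / preds[k]) for k in keep]


def evaluate(probs, labels, threshold: float = 0.5, dd_bins: int = 10,
             dd_range: tuple[float, float] = (0.0, 1.0)) -> EvaluationReport:
    """Full five-measure report for a set of posterior probabilities."""
    conf = confusion(probs, labels, threshold)
    acc, mcc = acc_mcc(conf)
    kl = class_kl(probs, labels, threshold)
    dd = distribution_distance(probs, labels, bins=dd_bins, prob_range=dd_range)
    roc, auc = roc_auc(probs, labels)
    pr = precision_recall(probs, labels)
    y = labels_to_int(labels)
    return EvaluationReport(
        acc=acc, mcc=mcc, kl=kl, dd=dd, auc=auc, roc=roc, pr=pr,
        threshold=threshold, n_pos=int(y.sum()), n_neg=int((y == 0).sum()),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    values,
    labels,
    fit_fn,
    k: int = 10,
    seed: int = 0,
    pooled: bool = True,
    max_refold: int = 10,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classifier.

    ``fit_fn(train_values, train_labels) -> model`` must return an object
    with ``predict_proba``. Out-of-fold predictions are pooled and scored
    once (default); with ``pooled=False`` the report carries per-fold
    measures and the headline numbers are fold averages.
    """
    import pandas as pd

    y = labels_to_int(labels)
    n = y.size
    for retry in range(max_refold):
        rng = np.random.default_rng(seed + retry)
        folds = stratified_folds(y, k, rng)
        ok = all(
            len(np.unique(y[np.setdiff1d(np.arange(n), f)])) == 2 for f in folds
        )
        if ok:
            break
    else:
        raise ValueError("could not build folds with both classes in training")
    probs = np.full(n, np.nan)
    per_fold = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        tv = values.iloc[train_idx] if isinstance(values, pd.DataFrame) else values[train_idx]
        ev = values.iloc[test_idx] if isinstance(values, pd.DataFrame) else values[test_idx]
        model = fit_fn(tv, y[train_idx])
        p = model.predict_proba(ev)
        probs[test_idx] = p
        if not pooled and len(np.unique(y[test_idx])) == 2:
            per_fold.append({"fold": fold_no, **evaluate(p, y[test_idx]).to_dict()})
    report = evaluate(probs, y)
    if not pooled and per_fold:
        keys = ("ACC", "MCC", "KL", "DD", "AUC")
        means = {kk: float(np.mean([f[kk] for f in per_fold])) for kk in keys}
        report = EvaluationReport(
            acc=means["ACC"], mcc=means["MCC"], kl=means["KL"],
            dd=means["DD"], auc=means["AUC"], roc=report.roc, pr=report.pr,
            n_pos=report.n_pos, n_neg=report.n_neg, per_fold=per_fold,
        )
    else:
        report.per_fold = per_fold
    return report


def leave_one_protein_out(
    values, labels, protein_ids, fit_fn
) -> dict[str, EvaluationReport]:
    """One report per held-out protein (trained on all other proteins)."""
    import pandas as pd

    y = labels_to_int(labels)
    pids = np.asarray(protein_ids)
    unique = list(dict.fromkeys(pids))
    if len(unique) < 2:
        raise ValueError("need at least two proteins")
    out = {}
    for pid in unique:
        test = pids == pid
        if len(np.unique(y[test])) < 2:
            continue  # cannot score a single-class protein
        train = ~test
        tv = values.loc[train] if isinstance(values, pd.DataFrame) else values[train]
        ev = values.loc[test] if isinstance(values, pd.DataFrame) else values[test]
        model = fit_fn(tv, y[train])
        out[str(pid)] = evaluate(model.predict_proba(ev), y[test])
    return out


# ---------------------------------------------------------------------------
# Concordance between measures
# ---------------------------------------------------------------------------

MEASURE_NAMES = ("ACC", "MCC", "AUC", "KL", "DD")


def mutual_information(x, y, bins: int = 10) -> float:
    """Mutual information (bits) via equal-width 2-D discretization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def measure_concordance(reports, bins: int = 10):
    """Pearson and mutual-information matrices between the five measures.

    ``reports`` is a sequence of per-classifier results (EvaluationReport or
    dicts keyed by measure name). Constant measures have undefined Pearson
    correlations; those cells are NaN.
    """
    import pandas as pd

    rows = []
    for r in reports:
        d = r.to_dict() if hasattr(r, "to_dict") else dict(r)
        rows.append([d[m] for m in MEASURE_NAMES])
    table = np.asarray(rows, float)
    if table.shape[0] < 3:
        raise ValueError("need at least 3 classifiers")
    k = len(MEASURE_NAMES)
    pearson = np.full((k, k), np.nan)
    mi = np.zeros((k, k))
    sds = table.std(axis=0)
    for i in range(k):
        for j in range(k):
            if sds[i] > 0 and sds[j] > 0:
                pearson[i, j] = float(np.corrcoef(table[:, i], table[:, j])[0, 1])
            mi[i, j] = mutual_information(table[:, i], table[:, j], bins=bins)
    idx = list(MEASURE_NAMES)
    return (
        pd.DataFrame(pearson, index=idx, columns=idx),
        pd.DataFrame(mi, index=idx, columns=idx),
    )
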