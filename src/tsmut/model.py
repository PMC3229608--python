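"""Class-weighted logistic classifier with Lasso/LARS feature selection.

The classifier is the two-stage procedure: (1) least-angle regression with
the Lasso modification on the weighted, standardized least-squares surrogate
selects an active feature subset; (2) a plain class-weighted logistic
regression refit on that subset yields the posterior probability

    P(TS | x) = 1 / (1 + exp(-(β₀ + Σ βᵢ xᵢ))).

Positive and negative examples are weighted inversely to their class counts
so that training mimics a 50-50 mixture of TS and neutral mutations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_TO_INT = {"TS": 1, "neutral": 0}


def labels_to_int(labels) -> np.ndarray:
    """Map TS/neutral labels (or 0/1) to a 0/1 integer array."""
    out = []
    for v in labels:
        if isinstance(v, str):
            out.append(LABEL_TO_INT[v])
        else:
            out.append(int(v))
    return np.asarray(out, dtype=int)


def class_weights(y) -> np.ndarray:
    """Per-sample weights inverse to class counts, normalized to sum to n.

    Each class receives total weight n/2, so the weighted sample behaves
    like a balanced 50-50 mixture; the per-sample weight ratio
    w_pos/w_neg equals n_neg/n_pos.
    """
    y = labels_to_int(y)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to weight them")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ez = np.exp(eta[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _weighted_loglik(y, p, w, eps=1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    ridge: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Maximize the weighted logistic log-likelihood by damped IRLS.

    Returns (coefficients, intercept). On (quasi-)separation the optimizer
    falls back to a small ridge penalty (λ = 1e-6, intercept unpenalized)
    with a warning. Deterministic for a fixed input order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = labels_to_int(y).astype(float)
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    X1 = np.column_stack([np.ones(n), X])
    pen = np.zeros(p + 1)
    pen[1:] = ridge
    beta = np.zeros(p + 1)

    def objective(b):
        return _weighted_loglik(y, _sigmoid(X1 @ b), w) - 0.5 * float(pen @ (b * b))

    ll = objective(beta)
    converged = False
    for _ in range(max_iter):
        eta = X1 @ beta
        prob = _sigmoid(eta)
        grad = X1.T @ (w * (y - prob)) - pen * beta
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        wls = w * prob * (1 - prob)
        H = (X1 * wls[:, None]).T @ X1 + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            converged = False
            break
        # damping: halve the step until the penalized log-likelihood improves
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            if objective(cand) >= ll - 1e-14:
                break
            t *= 0.5
        beta = beta + t * step
        ll = objective(beta)
    prob = _sigmoid(X1 @ beta)
    saturated = bool(np.all(prob * (1 - prob) < 1e-6))
    if (not converged or saturated) and ridge == 0.0:
        warnings.warn(
            "logistic fit did not converge cleanly (possible separation); "
            "refitting with ridge 1e-6",
            RuntimeWarning,
        )
        return fit_weighted_logistic(X, y, w, tol=tol, max_iter=max_iter, ridge=1e-6)
    return beta[1:], float(beta[0])


# ---------------------------------------------------------------------------
# LARS with the Lasso modification
# ---------------------------------------------------------------------------

@dataclass
class LarsStep:
    step: int
    action: str        # "add" | "drop"
    feature: int       # column index
    l1_norm: float     # Σ|β| after the step
    active: list[int] = field(default_factory=list)
    coef: np.ndarray | None = None


def lars_lasso_path(
    X: np.ndarray, y: np.ndarray, max_steps: int | None = None, tol: float = 1e-10
) -> list[LarsStep]:
    """Trace the Lasso solution path by least-angle regression.

    ``X`` must have centered, comparably scaled columns and ``y`` must be
    centered. At each breakpoint all active features are equally correlated
    with the residual; a coefficient that would cross zero leaves the active
    set (the Lasso modification). Returns the sequence of add/drop steps
    with the coefficient vector at each breakpoint.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if max_steps is None:
        max_steps = 8 * min(n - 1, p)
    beta = np.zeros(p)
    mu = np.zeros(n)
    active: list[int] = []
    signs: dict[int, float] = {}
    path: list[LarsStep] = []
    drop_next: list[int] = []
    for step_no in range(1, max_steps + 1):
        c = X.T @ (y - mu)
        C = float(np.max(np.abs(c))) if p else 0.0
        if C < tol:
            break
        if drop_next:
            for j in drop_next:
                active.remove(j)
                signs.pop(j)
            drop_next = []
        else:
            inactive = [j for j in range(p) if j not in active]
            if not inactive:
                pass
            else:
                j_new = max(inactive, key=lambda j: abs(c[j]))
                if abs(c[j_new]) >= C - tol * max(1.0, C):
                    active.append(j_new)
                    signs[j_new] = float(np.sign(c[j_new])) or 1.0
                    path.append(
                        LarsStep(step_no, "add", j_new, float(np.abs(beta).sum()),
                                 list(active), beta.copy())
                    )
        if not active:
            break
        A_idx = np.array(active)
        s = np.array([signs[j] for j in active])
        XA = X[:, A_idx] * s
        G = XA.T @ XA
        try:
            Ginv_ones = np.linalg.solve(G, np.ones(len(active)))
        except np.linalg.LinAlgError:
            logger.warning("singular active-set Gram matrix; stopping path")
            break
        denom = float(np.ones(len(active)) @ Ginv_ones)
        if denom <= 0:
            break
        A_norm = 1.0 / np.sqrt(denom)
        w_dir = A_norm * Ginv_ones
        u = XA @ w_dir
        a = X.T @ u
        C = float(np.max(np.abs(X.T @ (y - mu))))
        gamma_candidates = []
        for j in range(p):
            if j in signs:
                continue
            for num, den in ((C - c[j], A_norm - a[j]), (C + c[j], A_norm + a[j])):
                if den > tol and num / den > tol:
                    gamma_candidates.append(num / den)
        gamma = min(gamma_candidates) if gamma_candidates else C / A_norm
        # Lasso modification: stop at the first coefficient sign change
        d = np.zeros(p)
        d[A_idx] = s * w_dir
        dropping = []
        for j in active:
            if d[j] != 0 and beta[j] * d[j] < 0:
                g = -beta[j] / d[j]
                if tol < g < gamma - tol:
                    gamma = g
                    dropping = [j]
                elif abs(g - gamma) <= tol and dropping:
                    dropping.append(j)
        beta = beta + gamma * d
        mu = mu + gamma * u
        if dropping:
            for j in dropping:
                beta[j] = 0.0
                path.append(
                    LarsStep(step_no, "drop", j, float(np.abs(beta).sum()),
                             [k for k in active if k not in dropping], beta.copy())
                )
            drop_next = dropping
        else:
            if path:
                path[-1].l1_norm = float(np.abs(beta).sum())
                path[-1].coef = beta.copy()
        if len(active) >= min(p, n - 1) and not drop_next:
            break
    return path


def weighted_standardize(
    X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize columns to weighted mean 0, weighted sd 1.

    Returns (X_std, means, sds); zero-variance columns keep sd = 0 and are
    the caller's responsibility to drop.
    """
    w = np.asarray(w, float)
    wsum = w.sum()
    means = (w[:, None] * X).sum(axis=0) / wsum
    centered = X - means
    sds = np.sqrt((w[:, None] * centered**2).sum(axis=0) / wsum)
    with np.errstate(invalid="ignore", divide="ignore"):
        X_std = np.where(sds > 0, centered / sds, 0.0)
    return X_std, means, sds


def impute(
    X: np.ndarray, mask: np.ndarray, means: np.ndarray | None = None,
    sample_weight: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill masked cells with (weighted) training means.

    When ``means`` is given (test time), those stored values are used;
    otherwise column means are computed from the observed training cells.
    Returns (X_complete, means_used).
    """
    X = np.array(X, dtype=float)
    mask = np.asarray(mask, bool)
    n, p = X.shape
    if means is None:
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        means = np.empty(p)
        for j in range(p):
            obs = ~mask[:, j]
            if not obs.any():
                means[j] = np.nan
            else:
                means[j] = float(np.average(X[obs, j], weights=w[obs]))
    means = np.asarray(means, float)
    for j in range(p):
        X[mask[:, j], j] = means[j]
    return X, means


# ---------------------------------------------------------------------------
# Fitted model container and the two-stage pipeline
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted TS classifier on a selected feature subset.

    Coefficients apply to standardized features; prediction imputes masked
    inputs with the stored training means, standardizes with the stored
    constants, and evaluates the logistic posterior.
    """

    selected_features: list[str]
    coef: np.ndarray
    intercept: float
    class_weight_ratio: tuple[float, float]  # (w_TS, w_neutral)
    means: np.ndarray            # standardization means (selected features)
    sds: np.ndarray              # standardization sds
    impute_means: np.ndarray     # training means used to fill masked cells
    lasso_path: list[tuple[int, str, str, float]] = field(default_factory=list)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior TS probability for each row of a feature table."""
        if hasattr(X, "values") and hasattr(X, "feature_names"):  # FeatureMatrix
            X = X.values
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise KeyError(f"feature table lacks selected features: {missing}")
            X = X[self.selected_features].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X, _ = impute(X, np.isnan(X), means=self.impute_means)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = np.where(self.sds > 0, (X - self.means) / self.sds, 0.0)
        return _sigmoid(self.intercept + Z @ self.coef)

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_features": self.selected_features,
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "class_weight_ratio": list(self.class_weight_ratio),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "impute_means": self.impute_means.tolist(),
                "lasso_path": [list(t) for t in self.lasso_path],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            selected_features=d["selected_features"],
            coef=np.asarray(d["coef"], float),
            intercept=float(d["intercept"]),
            class_weight_ratio=tuple(d["class_weight_ratio"]),
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            impute_means=np.asarray(d["impute_means"], float),
            lasso_path=[tuple(t) for t in d.get("lasso_path", [])],
        )


def _prepare(values: pd.DataFrame, w: np.ndarray):
    """Impute, drop unusable columns, and standardize a feature table."""
    mask = values.isna().to_numpy()
    all_masked = mask.all(axis=0)
    if all_masked.any():
        dropped = list(values.columns[all_masked])
        logger.warning("dropping all-masked features: %s", dropped)
        values = values.loc[:, ~all_masked]
        mask = mask[:, ~all_masked]
    X, imp_means = impute(values.to_numpy(dtype=float), mask, sample_weight=w)
    X_std, means, sds = weighted_standardize(X, w)
    usable = sds > 0
    if not usable.all():
        logger.warning(
            "dropping zero-variance features: %s", list(values.columns[~usable])
        )
    names = list(values.columns[usable])
    return X_std[:, usable], names, means[usable], sds[usable], imp_means[usable]


def _cv_deviance(X, y, w, subset_idx, k=5, seed=0) -> float:
    """Stratified k-fold CV deviance of a weighted-logistic refit on a subset."""
    y = labels_to_int(y)
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    dev = 0.0
    for test_idx in folds:
        train = np.setdiff1d(np.arange(y.size), test_idx)
        if len(np.unique(y[train])) < 2:
            return np.inf
        coef, b0 = fit_weighted_logistic(X[np.ix_(train, subset_idx)], y[train], w[train])
        p = _sigmoid(b0 + X[np.ix_(test_idx, subset_idx)] @ coef)
        dev -= 2.0 * _weighted_loglik(y[test_idx], p, w[test_idx])
    return dev


def stratified_folds(y, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint label-stratified folds covering all indices."""
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    c = 0  # global round-robin counter, so k = n reduces to leave-one-out
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for ix in idx:
            folds[c % k].append(int(ix))
            c += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def fit_ts_model(
    values: pd.DataFrame,
    labels,
    feature_subset: list[str] | None = None,
    n_steps: int | None = None,
    cv: int = 5,
    seed: int = 0,
    max_steps: int | None = None,
) -> FittedModel:
    """Two-stage fit: LARS-lasso selection, then weighted logistic refit.

    ``n_steps`` forces the number of LARS steps; otherwise the selection
    point is the path breakpoint minimizing k-fold CV deviance of the
    downstream refit. ``feature_subset`` restricts the candidate features
    (e.g. the site-only or neighborhood-only model).
    """
    if hasattr(values, "values") and hasattr(values, "feature_names"):  # FeatureMatrix
        values = values.values
    if feature_subset is not None:
        values = values[list(feature_subset)]
    y = labels_to_int(labels)
    w = class_weights(y)
    X_std, names, means, sds, imp_means = _prepare(values, w)
    n, p = X_std.shape

    # LARS on the weighted least-squares surrogate: fold weights into rows.
    sw = np.sqrt(w)
    y_centered = y - np.average(y, weights=w)
    Xw = X_std * sw[:, None]
    yw = y_centered * sw
    path = lars_lasso_path(Xw, yw, max_steps=max_steps)

    if p == 0 or not path:
        selected_idx: list[int] = []
        path_chosen = []
    elif n_steps is not None:
        upto = [s for s in path if s.step <= n_steps] or path[:1]
        selected_idx = list(upto[-1].active)
        path_chosen = upto
    else:
        best, best_dev = None, np.inf
        seen: set[tuple[int, ...]] = set()
        for s in path:
            key = tuple(sorted(s.active))
            if not key or key in seen:
                continue
            seen.add(key)
            dev = _cv_deviance(X_std, y, w, list(s.active), k=cv, seed=seed)
            if dev < best_dev - 1e-9:
                best, best_dev = s, dev
        if best is None:
            selected_idx = []
            path_chosen = []
        else:
            selected_idx = list(best.active)
            path_chosen = [s for s in path if s.step <= best.step]

    if selected_idx:
        coef, b0 = fit_weighted_logistic(X_std[:, selected_idx], y, w)
    else:
        coef = np.zeros(0)
        _, b0 = fit_weighted_logistic(np.zeros((n, 0)), y, w)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return FittedModel(
        selected_features=[names[j] for j in selected_idx],
        coef=coef,
        intercept=b0,
        class_weight_ratio=(y.size / (2.0 * n_pos), y.size / (2.0 * n_neg)),
        means=means[selected_idx],
        sds=sds[selected_idx],
        impute_means=imp_means[selected_idx],
        lasso_path=[(s.step, s.action, names[s.feature], s.l1_norm) for s in path_chosen],
    )


def fit_logistic_model(values: pd.DataFrame, labels, seed: int = 0) -> FittedModel:
    """Weighted logistic fit on all given features, without Lasso selection."""
    if hasattr(values, "values") and hasattr(values, "feature_names"):
        values = values.values
    y = labels_to_int(labels)
    w = class_weights(y)
    X_std, names, means, sds, imp_means = _prepare(values, w)
    coef, b0 = fit_weighted_logistic(X_std, y, w)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return FittedModel(
        selected_features=names,
        coef=coef,
        intercept=b0,
        class_weight_ratio=(y.size / (2.0 * n_pos), y.size / (2.0 * n_neg)),
        means=means,
        sds=sds,
        impute_means=imp_means,
    )
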