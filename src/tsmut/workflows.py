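"""Composite analysis workflows built from the core modules.

These wire feature extraction, model fitting and cross-validation into the
study protocols: the neighborhood-cutoff scan (classifier on the 20-D
residue-count vector at each cutoff), per-feature single-classifier
evaluation for feature ranking and measure concordance, and the standard
model-group comparison (site vs neighborhood vs all features).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import neighborhoods as nbh
from .constants import AA_ORDER
from .evaluation import EvaluationReport, cross_validate, evaluate
from .features import FeatureMatrix, feature_groups
from .model import fit_logistic_model, fit_ts_model, labels_to_int


def count_vector_table(
    structure, sites, kind: str, cutoff: float,
    tessellation: nbh.Tessellation | None = None,
) -> pd.DataFrame:
    """Per-site 20-D residue-count vectors for one neighborhood definition."""
    n = len(structure)
    if kind == "topological" and tessellation is None:
        tessellation = nbh.delaunay_tessellation(structure.ca_coords())
    rows = []
    seq = structure.sequence
    for site in sites:
        if kind == "sequence":
            nb = nbh.sequence_neighborhood(n, site, int(cutoff))
        elif kind == "euclidean":
            nb = nbh.euclidean_neighborhood(structure, site, cutoff)
        elif kind == "topological":
            nb = nbh.topological_neighborhood(structure, tessellation, site, cutoff)
        else:
            raise ValueError(f"unknown neighborhood kind {kind!r}")
        counts = np.zeros(20)
        for j in nb.members:
            counts[AA_ORDER.index(seq[j])] += 1
        rows.append(counts)
    return pd.DataFrame(rows, columns=[f"count_{aa}" for aa in AA_ORDER])


def scan_cutoffs(
    structure,
    sites,
    labels,
    kinds=("sequence", "euclidean", "topological"),
    cutoffs=range(6, 16),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated AUC of the 20-D count classifier at each cutoff.

    For the sequence neighborhood the cutoff is a residue window; for the
    structural neighborhoods it is the sphere radius in Å. Returns a tidy
    frame (kind, cutoff, auc).
    """
    y = labels_to_int(labels)
    tess = nbh.delaunay_tessellation(structure.ca_coords())
    out = []
    for kind in kinds:
        for cutoff in cutoffs:
            table = count_vector_table(structure, sites, kind, float(cutoff), tess)
            report = cross_validate(
                table, y, lambda tv, ty: fit_logistic_model(tv, ty), k=k, seed=seed
            )
            out.append({"kind": kind, "cutoff": float(cutoff), "auc": report.auc})
    return pd.DataFrame(out)


def per_feature_reports(
    fm: FeatureMatrix | pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
    features=None,
) -> pd.DataFrame:
    """Five-measure CV report for a single-feature classifier per feature.

    Features that are entirely masked or constant are skipped. Returns a
    frame indexed by feature name with columns ACC, MCC, AUC, KL, DD.
    """
    values = fm.values if isinstance(fm, FeatureMatrix) else fm
    y = labels_to_int(labels)
    rows = {}
    for name in (features or values.columns):
        col = values[[name]]
        observed = col[name].dropna()
        if observed.empty or observed.nunique() < 2:
            continue
        report = cross_validate(
            col, y, lambda tv, ty: fit_logistic_model(tv, ty), k=k, seed=seed
        )
        rows[name] = report.to_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return frame[["ACC", "MCC", "AUC", "KL", "DD"]]


def fit_model_groups(
    fm: FeatureMatrix | pd.DataFrame,
    labels,
    groups=("site", "neighborhood", "all"),
    k: int = 10,
    seed: int = 0,
    n_steps: int | None = None,
    cv_select: int = 5,
    max_steps: int | None = 30,
) -> dict[str, EvaluationReport]:
    """Cross-validated evaluation of the standard feature-group models.

    Each group (site features, neighborhood features, per-neighborhood
    subsets, sequence/structure splits, or all) gets the full two-stage
    pipeline — Lasso selection then weighted logistic refit — inside every
    training fold.
    """
    values = fm.values if isinstance(fm, FeatureMatrix) else fm
    y = labels_to_int(labels)
    grouping = feature_groups(values.columns)
    out = {}
    for g in groups:
        cols = grouping[g]
        out[g] = cross_validate(
            values[cols],
            y,
            lambda tv, ty: fit_ts_model(tv, ty, n_steps=n_steps, cv=cv_select,
                                        seed=seed, max_steps=max_steps),
            k=k,
            seed=seed,
        )
    return out
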