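"""Reference projection of query cells by multinomial logistic regression.

A softmax classifier with an L2 penalty is trained on reference cells
labelled by lineage/stage cluster; query cells (cell lines or external
embryo datasets) are scored by their predicted class probabilities, and
per-group means of those probabilities are the quantitative matching
scores between datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .qc_lineage import NormalizedMatrix

__all__ = ["ProjectionModel", "fit_projection", "score_cells", "group_match_scores"]


@dataclass
class ProjectionModel:
    """Fitted multinomial classifier over reference clusters."""

    class_names: list[str]
    feature_genes: list[str]
    weights: np.ndarray  # classes x (genes + 1), intercept last
    regularisation_strength: float
    _estimator: LogisticRegression

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("model weights are not finite")


def _top_variable_genes(norm: NormalizedMatrix, n_top: int) -> list[str]:
    x = norm.values
    mean = np.asarray(x.mean(axis=1)).ravel()
    mean_sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    var = mean_sq - mean**2
    order = np.argsort(-var, kind="mergesort")[:n_top]
    return [norm.gene_ids[i] for i in sorted(order)]


def fit_projection(
    reference_norm: NormalizedMatrix,
    labels: Sequence[str],
    lam: float = 1.0,
    n_feature_genes: int = 2000,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> ProjectionModel:
    """Fit the L2-penalised softmax classifier on reference cells.

    ``lam`` is the L2 penalty strength (sklearn's ``C = 1/lam``); features
    are the ``n_feature_genes`` most variable genes of the reference.  The
    objective is convex, so the fit is deterministic given the data and
    ``lam``.  Every class needs at least 5 cells.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two reference classes")
    small = classes[counts < 5]
    if small.size:
        raise ValueError(f"classes with fewer than 5 cells: {small.tolist()}")
    if lam <= 0:
        raise ValueError("regularisation strength must be positive")
    feature_genes = _top_variable_genes(reference_norm, n_feature_genes)
    x = reference_norm.dense_rows(feature_genes).T  # cells x genes
    est = LogisticRegression(
        penalty="l2", C=1.0 / lam, solver="lbfgs", max_iter=max_iter, tol=tol
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(x, labels)
    weights = np.hstack([est.coef_, est.intercept_[:, None]])
    return ProjectionModel(
        class_names=[str(c) for c in est.classes_],
        feature_genes=feature_genes,
        weights=weights,
        regularisation_strength=lam,
        _estimator=est,
    )


def score_cells(model: ProjectionModel, query_norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-cell class probabilities for query cells (rows sum to 1).

    Query genes are intersected with the model's feature genes; features
    absent from the query are imputed as 0 (post-normalisation) with a
    warning.
    """
    present = set(query_norm.gene_ids)
    shared = [g for g in model.feature_genes if g in present]
    if not shared:
        raise ValueError("query shares no genes with the model's features")
    missing = [g for g in model.feature_genes if g not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} model features absent from query; imputed as 0",
            stacklevel=2,
        )
    x = np.zeros((query_norm.n_cells, len(model.feature_genes)))
    col = {g: j for j, g in enumerate(model.feature_genes)}
    x[:, [col[g] for g in shared]] = query_norm.dense_rows(shared).T
    probs = model._estimator.predict_proba(x)
    return pd.DataFrame(
        probs,
        index=pd.Index(query_norm.cell_ids, name="barcode"),
        columns=model.class_names,
    )


def group_match_scores(per_cell_probs: pd.DataFrame, group_ids: Sequence[str]) -> pd.DataFrame:
    """Mean class probability per query group (groups x classes).

    Each row is an arithmetic mean of probability vectors, so rows sum
    to 1.
    """
    groups = pd.Series(list(group_ids), index=per_cell_probs.index, name="group")
    if groups.isna().any():
        raise ValueError("every cell needs a group")
    return per_cell_probs.groupby(groups).mean()
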