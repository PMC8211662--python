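"""Co-expression, sub-clustering, regulon activity and pluripotency panels.

The anterior-hypoblast analysis asks whether *CER1* is co-expressed with
other secreted antagonists of the BMP, NODAL and WNT pathways within the
hypoblast, whether a CER1-high sub-population separates in expression
space, and how active each transcription-factor regulon is per cell
(rank-based area-under-the-recovery-curve, as in AUCell).
"""

from __future__ import annotations

import warnings
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

if TYPE_CHECKING:  # pragma: no cover
    from .io_core import RegulonSet
    from .qc_lineage import NormalizedMatrix

__all__ = [
    "ANTAGONIST_PANEL",
    "PLURIPOTENCY_PANELS",
    "bh_adjust",
    "correlate_with_target",
    "partition_cells",
    "regulon_activity",
    "pluripotency_panel",
]

#: WNT/BMP/NODAL antagonists tested for co-expression with CER1
ANTAGONIST_PANEL = (
    "LEFTY1",
    "LEFTY2",
    "HHEX",
    "NOG",
    "DKK4",
    "DKK1",
    "SFRP1",
    "NCLN",
    "CHRD",
    "SOSTDC1",
)

#: marker panels for the naive -> primed pluripotency transition
PLURIPOTENCY_PANELS: dict[str, tuple[str, ...]] = {
    "naive": ("KLF4", "KLF17", "PRDM14", "DNMT3L", "SOX15", "TFCP2L1", "ZFP42"),
    "primed": ("FGF2", "DNMT3B", "SOX11", "SFRP2", "SALL2"),
    "core": ("POU5F1", "NANOG", "SOX2"),
}


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving.

    ``q_i = min over j with p_(j) >= p_(i) of p_(j) * m / j``, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def correlate_with_target(
    norm: "NormalizedMatrix",
    target: str = "CER1",
    panel: Sequence[str] = ANTAGONIST_PANEL,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate a target gene with a panel across cells, with BH correction.

    Expects the matrix restricted to one lineage (e.g. hypoblast cells).
    Spearman rank correlation by default; Pearson available.  A constant
    target leaves every correlation undefined (flagged with NaN rho and
    q = 1).
    """
    if norm.n_cells < 10:
        raise ValueError("need at least 10 cells for a meaningful correlation")
    present = [g for g in panel if g in norm.gene_ids]
    dropped = [g for g in panel if g not in norm.gene_ids]
    if dropped:
        warnings.warn(f"panel genes absent from matrix: {dropped}", stacklevel=2)
    if not present:
        raise ValueError("no panel genes present in the matrix")
    x = norm.gene_vector(target)
    rows = []
    constant_target = np.ptp(x) == 0
    for gene in present:
        y = norm.gene_vector(gene)
        if constant_target or np.ptp(y) == 0:
            rho, pval = float("nan"), 1.0
        elif method == "spearman":
            rho, pval = scipy.stats.spearmanr(x, y)
        elif method == "pearson":
            rho, pval = scipy.stats.pearsonr(x, y)
        else:
            raise ValueError(f"unknown correlation method: {method}")
        rows.append((target, gene, float(rho), float(pval)))
    frame = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p_raw"])
    frame["q_bh"] = bh_adjust(frame["p_raw"].to_numpy())
    frame["n_cells"] = norm.n_cells
    return frame


def partition_cells(
    norm: "NormalizedMatrix",
    k: int = 3,
    n_pcs: int = 10,
    seed: int = 0,
    anterior_marker: str = "CER1",
) -> tuple[np.ndarray, int | None]:
    """PCA + k-means sub-clustering of one lineage's cells.

    Returns ``(labels, anterior_cluster)`` where the anterior cluster is
    the sub-cluster with the highest mean expression of
    ``anterior_marker`` (``None`` if the marker is absent).  Deterministic
    given the seed (k-means++ with 50 restarts).
    """
    n = norm.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} cells for k={k}")
    x = np.asarray(norm.values.todense()).T  # cells x genes
    n_comp = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x - x.mean(axis=0))
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(pcs)
    anterior = None
    if anterior_marker in norm.gene_ids:
        marker = norm.gene_vector(anterior_marker)
        means = [marker[labels == c].mean() for c in range(k)]
        anterior = int(np.argmax(means))
    return labels, anterior


def regulon_activity(
    norm: "NormalizedMatrix",
    regulons: "RegulonSet",
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Rank-based AUC activity of each regulon in each cell (AUCell-style).

    Per cell, genes are ranked by expression (descending, ties broken
    lexicographically by symbol for determinism).  The recovery curve
    counts regulon genes within the top ``x`` ranks for ``x = 1 ..
    ceil(top_fraction * n_genes)``; its area, normalised by the maximum
    achievable area, is the activity score in [0, 1].  Regulons with no
    targets in the matrix are dropped with a warning.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    gene_ids = np.asarray(norm.gene_ids)
    present = set(norm.gene_ids)
    kept: list[tuple[str, np.ndarray]] = []
    for name, targets in regulons:
        idx = np.flatnonzero(np.isin(gene_ids, sorted(targets)))
        if idx.size == 0:
            warnings.warn(f"regulon {name} has no targets in the matrix; dropped", stacklevel=2)
            continue
        if len(targets - present):
            warnings.warn(
                f"regulon {name}: {len(targets - present)} targets absent from matrix",
                stacklevel=2,
            )
        kept.append((name, idx))
    if not kept:
        raise ValueError("no regulon has targets in the matrix")
    n_genes = norm.n_genes
    window = int(np.ceil(top_fraction * n_genes))
    dense = np.asarray(norm.values.todense())
    # lexicographic tie-break: stable sort by name after sorting by -expression
    name_order = np.argsort(gene_ids, kind="mergesort")
    scores = np.zeros((norm.n_cells, len(kept)))
    for j in range(norm.n_cells):
        expr = dense[:, j]
        order = name_order[np.argsort(-expr[name_order], kind="mergesort")]
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[order] = np.arange(n_genes)  # 0-based rank
        for r, (_, idx) in enumerate(kept):
            ranks = rank_of[idx]
            inside = ranks[ranks < window]
            auc = float(np.sum(window - inside))
            g = idx.size
            if g >= window:
                auc_max = window * (window + 1) / 2
            else:
                auc_max = g * (g + 1) / 2 + (window - g) * g
            scores[j, r] = auc / auc_max
    return pd.DataFrame(
        scores,
        index=pd.Index(norm.cell_ids, name="barcode"),
        columns=[name for name, _ in kept],
    )


def pluripotency_panel(
    norm: "NormalizedMatrix",
    stages: Sequence[object] | None = None,
    panels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Median expression per gene per developmental stage, long format.

    ``stages`` defaults to the matrix's per-cell ``stage_dpf`` metadata.
    Genes absent from the matrix are emitted with a ``missing`` flag and
    NaN medians.
    """
    if panels is None:
        panels = PLURIPOTENCY_PANELS
    if stages is None:
        stages = norm.cell_meta["stage_dpf"].to_numpy()
    stages = pd.Series(list(stages), index=norm.cell_ids)
    known = stages[stages.notna()]
    if known.empty:
        raise ValueError("no cells with a known stage")
    rows = []
    for panel_name, genes in panels.items():
        for gene in genes:
            missing = gene not in norm.gene_ids
            values = None if missing else pd.Series(norm.gene_vector(gene), index=norm.cell_ids)
            for stage in sorted(known.unique()):
                cells = known.index[known == stage]
                median = float("nan") if missing else float(values[cells].median())
                rows.append((panel_name, gene, stage, median, len(cells), missing))
    return pd.DataFrame(
        rows,
        columns=["panel", "gene", "stage", "median_expression", "n_cells", "missing"],
    )
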