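"""Cell quality control, library-size normalisation and lineage annotation.

Cells are kept when at most 20% of their counts are mitochondrial and at
least 1000 genes are detected.  Embryos enter the analysis only when all
three lineages (epiblast, hypoblast and trophoblast) are represented.
Lineages are called by marker-signature scoring: each cell's score for a
lineage is the mean z-scored normalised expression of that lineage's
marker genes, and the argmax wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io_core import GeneMatrix
from .signalling import bh_adjust

__all__ = [
    "LINEAGES",
    "DEFAULT_MARKER_SETS",
    "CellQC",
    "NormalizedMatrix",
    "ConfigurationError",
    "compute_cell_qc",
    "filter_cells",
    "normalize_log",
    "score_signatures",
    "assign_lineages",
    "embryo_inclusion",
    "rank_markers",
]

#: canonical lineage order; also the deterministic tie-break order
LINEAGES = ("EPI", "HYP", "CTB", "STB")

#: top enriched genes per lineage used as default annotation signatures
DEFAULT_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "EPI": ("POU5F1", "NANOG", "SOX2", "DPPA5", "KHDC1L", "MT1X", "KHDC3L", "MT1G"),
    "HYP": ("PDGFRA", "GATA6", "APOA1", "FN1", "S100A14", "COL4A1", "APOA2"),
    "CTB": ("PEG10", "FABP5", "HIST1H4C", "KRT19", "TPM1", "CDH1", "ITGA6"),
    "STB": ("CGA", "PRR9", "ANXA1", "LGALS16", "ATF3"),
}


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g. an empty marker set)."""


@dataclass
class CellQC:
    """Per-cell QC quantities.

    ``mito_fraction`` is mitochondrial counts over total counts (0 for
    empty cells); ``n_detected_genes`` counts genes with at least one
    count.
    """

    cell_ids: list[str]
    mito_fraction: np.ndarray
    n_detected_genes: np.ndarray
    total_counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mito_fraction": self.mito_fraction,
                "n_detected_genes": self.n_detected_genes,
                "total_counts": self.total_counts,
            },
            index=pd.Index(self.cell_ids, name="barcode"),
        )


@dataclass
class NormalizedMatrix:
    """Genes x cells log-normalised expression with the source metadata."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.spmatrix
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_vector(self, gene: str) -> np.ndarray:
        idx = self.gene_ids.index(gene)
        return np.asarray(self.values[idx].todense()).ravel()

    def dense_rows(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [lookup[g] for g in genes]
        return np.asarray(self.values[idx].todense())

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else np.asarray(mask)
        return NormalizedMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            values=self.values[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


def compute_cell_qc(m: GeneMatrix) -> CellQC:
    """Mitochondrial fraction, detected-gene count and depth per cell."""
    counts = m.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito = np.asarray(counts[m.mito_mask].sum(axis=0)).ravel()
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return CellQC(
        cell_ids=list(m.cell_ids),
        mito_fraction=frac,
        n_detected_genes=detected.astype(int),
        total_counts=total.astype(int),
    )


def filter_cells(qc: CellQC, mito_max: float = 0.20, min_genes: int = 1000) -> np.ndarray:
    """Keep mask: mito fraction <= ``mito_max`` and detected genes >= ``min_genes``.

    Removal is strict above the mitochondrial threshold (a cell at exactly
    20% is kept) and strict below the gene threshold (999 genes is
    removed).
    """
    if not 0 <= mito_max <= 1:
        raise ValueError("mito_max must be in [0, 1]")
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    return (qc.mito_fraction <= mito_max) & (qc.n_detected_genes >= min_genes)


def normalize_log(m: GeneMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalise then log-transform: ``x -> log(1 + scale*x/total)``.

    Cells with zero total counts stay all-zero.
    """
    counts = m.counts.tocsc().astype(float)
    total = np.asarray(counts.sum(axis=0)).ravel()
    factors = np.where(total > 0, scale / np.maximum(total, 1), 0.0)
    scaled = counts @ sp.diags(factors)
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        values=scaled,
        cell_meta=m.cell_meta.copy(),
    )


def score_signatures(
    norm: NormalizedMatrix,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-cell lineage signature scores (cells x lineages).

    A lineage's score is the mean across its marker genes of gene-wise
    z-scored expression (z across cells).  Constant genes contribute 0;
    marker genes absent from the matrix are dropped with a warning, and a
    lineage whose whole set is missing is a configuration error.
    """
    if marker_sets is None:
        marker_sets = DEFAULT_MARKER_SETS
    present = set(norm.gene_ids)
    surviving: dict[str, list[str]] = {}
    for lineage, genes in marker_sets.items():
        kept = [g for g in genes if g in present]
        dropped = [g for g in genes if g not in present]
        if dropped:
            warnings.warn(
                f"{lineage}: marker genes absent from matrix: {dropped}",
                stacklevel=2,
            )
        if not kept:
            raise ConfigurationError(f"no marker genes of lineage {lineage} in matrix")
        surviving[lineage] = kept
    union = sorted({g for genes in surviving.values() for g in genes})
    x = norm.dense_rows(union)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    row = {g: i for i, g in enumerate(union)}
    scores = {
        lineage: z[[row[g] for g in genes]].mean(axis=0)
        for lineage, genes in surviving.items()
    }
    return pd.DataFrame(scores, index=pd.Index(norm.cell_ids, name="barcode"))


def assign_lineages(scores: pd.DataFrame, min_margin: float = 0.0) -> np.ndarray:
    """Argmax lineage per cell; ``UNASSIGNED`` when the top margin is too small.

    Exact ties break deterministically by the fixed lineage order
    EPI < HYP < CTB < STB (then column order for non-canonical labels).
    """
    if not np.all(np.isfinite(scores.to_numpy())):
        raise ValueError("signature scores must be finite")
    order = [l for l in LINEAGES if l in scores.columns] + [
        c for c in scores.columns if c not in LINEAGES
    ]
    arr = scores[order].to_numpy()
    best = arr.argmax(axis=1)  # first occurrence wins ties
    labels = np.array([order[i] for i in best], dtype=object)
    if min_margin > 0 and arr.shape[1] > 1:
        part = np.sort(arr, axis=1)
        margin = part[:, -1] - part[:, -2]
        labels[margin < min_margin] = "UNASSIGNED"
    return labels


def embryo_inclusion(
    labels: np.ndarray,
    embryo_ids: Sequence[str],
    min_cells_per_lineage: int = 1,
) -> set[str]:
    """Embryos with all three lineages represented.

    Requires at least ``min_cells_per_lineage`` epiblast cells, as many
    hypoblast cells, and as many trophoblast cells (cytotrophoblast and
    syncytiotrophoblast pooled).
    """
    df = pd.DataFrame({"label": labels, "embryo": list(embryo_ids)})
    kept = set()
    for embryo, sub in df.groupby("embryo"):
        n_epi = int((sub["label"] == "EPI").sum())
        n_hyp = int((sub["label"] == "HYP").sum())
        n_tro = int(sub["label"].isin(["CTB", "STB"]).sum())
        if min(n_epi, n_hyp, n_tro) >= min_cells_per_lineage:
            kept.add(embryo)
    return kept


def rank_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker ranking per lineage.

    For each gene and lineage: a two-sided Wilcoxon rank-sum test of the
    lineage's cells against all others, the log2 fold-change of mean
    ``expm1`` expression (pseudocount 1e-9), and the fractions of
    expressing cells.  p-values are BH-adjusted within each lineage and
    rows sorted by (q, |log2 fold-change| descending).
    """
    labels = np.asarray(labels)
    lineages = [l for l in pd.unique(labels) if l != "UNASSIGNED"]
    sized = [l for l in lineages if (labels == l).sum() >= min_cells]
    for l in set(lineages) - set(sized):
        warnings.warn(f"lineage {l} has fewer than {min_cells} cells; skipped", stacklevel=2)
    if len(sized) < 2:
        raise ValueError("need at least two lineages with enough cells")
    dense = np.asarray(norm.values.todense())
    expm1 = np.expm1(dense)
    eps = 1e-9
    frames = []
    for lineage in sized:
        mask = labels == lineage
        x_in = dense[:, mask]
        x_out = dense[:, ~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = scipy.stats.mannwhitneyu(
                x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
            )
        # genes constant across every cell have no rank information
        p = np.where(np.isnan(np.asarray(res.pvalue, dtype=float)), 1.0, res.pvalue)
        mean_in = expm1[:, mask].mean(axis=1)
        mean_out = expm1[:, ~mask].mean(axis=1)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        frame = pd.DataFrame(
            {
                "gene": norm.gene_ids,
                "lineage": lineage,
                "log2_fold_change": lfc,
                "p_raw": p,
                "q_bh": bh_adjust(p),
                "frac_expressing_in": (x_in > 0).mean(axis=1),
                "frac_expressing_out": (x_out > 0).mean(axis=1),
            }
        )
        frame = frame.sort_values(
            ["q_bh", "log2_fold_change"],
            key=lambda s: s if s.name == "q_bh" else -s.abs(),
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
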