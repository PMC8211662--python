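"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as the 10x-style triple (MatrixMarket ``matrix.mtx``
plus ``features.tsv`` and ``barcodes.tsv``), with an optional sidecar
metadata TSV keyed by barcode.  Regulon gene sets are plain GMT.  Segmented
nucleus coordinates are a flat CSV, one row per cell.

Matrices are gene-major on disk and in memory: ``counts[i, j]`` is gene *i*
in cell *j*.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .axis_geometry import EmbryoGeometry, GEOMETRY_MARKERS

__all__ = [
    "FormatError",
    "GeneMatrix",
    "RegulonSet",
    "read_counts",
    "write_counts",
    "read_gmt",
    "read_geometry",
    "write_geometry",
]

#: columns of the cell metadata sidecar TSV
META_COLUMNS = ("barcode", "embryo_id", "stage_dpf", "source")


class FormatError(ValueError):
    """An input file violates its declared format."""


def _empty_meta(cell_ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": pd.array([""] * len(cell_ids), dtype="string"),
            "stage_dpf": pd.array([pd.NA] * len(cell_ids), dtype="Int64"),
            "source": pd.array([""] * len(cell_ids), dtype="string"),
        },
        index=pd.Index(cell_ids, name="barcode"),
    )


@dataclass
class GeneMatrix:
    """Genes x cells integer count matrix with per-cell metadata.

    Parameters
    ----------
    gene_ids
        Gene symbols, one per matrix row; must be unique.
    cell_ids
        Cell barcodes, one per matrix column; must be unique.
    counts
        Non-negative integer sparse matrix, shape ``(genes, cells)``.
    cell_meta
        Per-cell frame indexed by barcode with columns ``embryo_id``,
        ``stage_dpf`` (nullable integer; days post-fertilisation) and
        ``source``.  Defaults to unknown metadata.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts contain negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and not np.allclose(data, np.round(data)):
                raise FormatError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if self.cell_meta is None:
            self.cell_meta = _empty_meta(self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def mito_mask(self) -> np.ndarray:
        """Boolean per gene: mitochondrially encoded (``MT-`` symbol prefix)."""
        return np.array([g.startswith("MT-") for g in self.gene_ids])

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"gene not in matrix: {exc.args[0]}") from exc

    def subset_cells(self, mask: np.ndarray) -> "GeneMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GeneMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass
class RegulonSet:
    """Transcription factors with their inferred target gene sets."""

    entries: list[tuple[str, set[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise FormatError("duplicate regulon (TF) names")
        for name, targets in self.entries:
            if not targets:
                raise FormatError(f"regulon {name!r} has no targets")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def targets(self, name: str) -> set[str]:
        for n, t in self.entries:
            if n == name:
                return t
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, set[str]]]:
        return iter(self.entries)


def read_counts(
    matrix_path: str | os.PathLike,
    features_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
) -> GeneMatrix:
    """Read a 10x-style MTX triple (plus optional metadata TSV).

    The features/barcodes TSVs may carry extra columns (10x convention);
    only the first column is used.  A missing metadata file leaves all
    stages unknown.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    gene_ids = features.iloc[:, 0].tolist()
    cell_ids = barcodes.iloc[:, 0].tolist()
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"MTX header declares {mat.shape}, but features/barcodes give "
            f"({len(gene_ids)}, {len(cell_ids)})"
        )
    meta = None
    if meta_path is not None:
        raw = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
        missing = set(META_COLUMNS) - set(raw.columns)
        if missing:
            raise FormatError(f"metadata TSV lacks columns: {sorted(missing)}")
        raw = raw.set_index("barcode")
        meta = pd.DataFrame(
            {
                "embryo_id": raw["embryo_id"].astype("string"),
                "stage_dpf": pd.array(raw["stage_dpf"], dtype="Int64"),
                "source": raw["source"].astype("string"),
            }
        ).reindex(cell_ids)
    return GeneMatrix(gene_ids=gene_ids, cell_ids=cell_ids, counts=mat, cell_meta=meta)


def write_counts(m: GeneMatrix, dir_path: str | os.PathLike) -> dict[str, Path]:
    """Write a :class:`GeneMatrix` as the MTX triple plus ``meta.tsv``.

    Lossless for integer counts; ``read_counts`` on the result reproduces
    the matrix exactly (ids, order and values).
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "meta.tsv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(m.counts), field="integer")
    pd.Series(m.gene_ids).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    meta = m.cell_meta.copy()
    meta.index.name = "barcode"
    meta.to_csv(paths["meta"], sep="\t")
    return paths


def read_gmt(path: str | os.PathLike) -> RegulonSet:
    """Parse a tab-separated GMT file into a :class:`RegulonSet`.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are dropped, duplicate TF names are an error.
    """
    entries: list[tuple[str, set[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, _desc, *genes = fields
            entries.append((name, set(g for g in genes if g)))
    return RegulonSet(entries=entries)


def read_geometry(path: str | os.PathLike) -> EmbryoGeometry:
    """Read a segmented-nucleus coordinate CSV into an :class:`EmbryoGeometry`.

    Expected columns: ``cell_id,x_um,y_um,z_um,lineage`` plus one 0/1 column
    per marker (``CER1,GATA6,OCT4,LEFTY1,pSMAD15``) and optionally
    ``embryo_id`` and ``stage_dpf``.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "x_um", "y_um", "z_um", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"geometry CSV lacks columns: {sorted(missing)}")
    for marker in GEOMETRY_MARKERS:
        if marker in df.columns:
            df[marker] = df[marker].astype(int).astype(bool)
        else:
            df[marker] = False
    if "embryo_id" not in df.columns:
        df["embryo_id"] = ""
    if "stage_dpf" not in df.columns:
        df["stage_dpf"] = pd.NA
    return EmbryoGeometry(df)


def write_geometry(g: EmbryoGeometry, path: str | os.PathLike) -> Path:
    """Write an :class:`EmbryoGeometry` as CSV with 0/1 marker columns."""
    df = g.data.copy()
    for marker in GEOMETRY_MARKERS:
        df[marker] = df[marker].astype(int)
    df.to_csv(path, index=False)
    return Path(path)
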