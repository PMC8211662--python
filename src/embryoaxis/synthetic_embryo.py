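"""Synthetic count matrices and 3D embryo geometries.

The generator emulates the statistical structure the downstream analyses
assume: four marker-separable lineages with realistic cluster proportions,
an explicitly injected population of low-quality cells (high mitochondrial
fraction, few detected genes), and hemispherical hypoblast geometries in
which marker-positive cells are either spread evenly (7 d.p.f.-like) or
concentrated toward one lateral side (9 d.p.f.-like), with a von
Mises-Fisher-style concentration parameter kappa spanning the two regimes.

Counts follow a negative-binomial (gamma-Poisson) noise model; the
geometry places epiblast cells in a proximal ball and hypoblast cells on
a distal hemispherical shell of radius ``radius_um``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .axis_geometry import GEOMETRY_MARKERS, EmbryoGeometry
from .io_core import GeneMatrix
from .qc_lineage import DEFAULT_MARKER_SETS, LINEAGES

__all__ = [
    "MITO_GENES",
    "STAGE_GEOMETRY_DEFAULTS",
    "SyntheticCountParams",
    "SyntheticGeometryParams",
    "simulate_counts",
    "simulate_geometry",
    "simulate_geometry_cohort",
    "simulate_stage_counts",
    "simulate_hypoblast_subpops",
]

#: the 13 protein-coding mitochondrially encoded genes (GRCh38 symbols)
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: per-stage geometry defaults: (marker_fraction mean, between-embryo sd, kappa)
#: 7 d.p.f.: widespread CER1 domain (cohort IQR ~69-82% positive, no bias);
#: 9 d.p.f.: restricted domain (cohort IQR ~17-43%) concentrated to one side.
STAGE_GEOMETRY_DEFAULTS: dict[int, tuple[float, float, float]] = {
    7: (0.755, 0.04, 0.0),
    9: (0.30, 0.07, 4.0),
}

#: stage labels and programs for the epiblast pluripotency transition
STAGE_CLASSES = ("ICM-5dpf", "preEpi-6-7dpf", "postEpi-9dpf", "postEpi-11dpf")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and variance ``mean + mean^2/dispersion``."""
    mean = np.asarray(mean, dtype=float)
    if not math.isfinite(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 0) / dispersion)
    return rng.poisson(lam)


@dataclass
class SyntheticCountParams:
    """Parameters of the synthetic count-matrix generator.

    Default lineage sizes mirror the reference dataset's cluster sizes
    (166 epiblast, 136 hypoblast, 2182 cytotrophoblast, 2336
    syncytiotrophoblast cells across 16 embryos, half at 9 and half at
    11 d.p.f.).
    """

    n_cells_per_lineage: Mapping[str, int] = field(
        default_factory=lambda: {"EPI": 166, "HYP": 136, "CTB": 2182, "STB": 2336}
    )
    marker_programs: Mapping[str, tuple[Sequence[str], float]] = field(
        default_factory=lambda: {l: (list(g), 20.0) for l, g in DEFAULT_MARKER_SETS.items()}
    )
    baseline_mean: float = 1.0
    nb_dispersion: float = 2.0
    mito_fraction_mean: float = 0.05
    n_lowquality_cells: int = 300
    lowquality_mito: float = 0.5
    lowquality_depth_factor: float = 0.1
    n_genes: int = 2000
    n_embryos: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_cells_per_lineage:
            raise ValueError("n_cells_per_lineage must not be empty")
        unknown = set(self.n_cells_per_lineage) - set(LINEAGES)
        if unknown:
            raise ValueError(f"unknown lineages: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("mito_fraction_mean", "lowquality_mito"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


def _gene_universe(p: SyntheticCountParams) -> list[str]:
    genes: list[str] = []
    for lineage in LINEAGES:
        if lineage in p.marker_programs:
            for g in p.marker_programs[lineage][0]:
                if g not in genes:
                    genes.append(g)
    genes.extend(MITO_GENES)
    i = 1
    while len(genes) < p.n_genes:
        genes.append(f"BG{i:04d}")
        i += 1
    return genes[: max(p.n_genes, len(genes))]


def _lineage_means(p: SyntheticCountParams, genes: list[str]) -> dict[str, np.ndarray]:
    """Per-gene NB means for each lineage, mitochondria tuned to the target fraction."""
    mito = np.array([g in MITO_GENES for g in genes])
    means: dict[str, np.ndarray] = {}
    for lineage in p.n_cells_per_lineage:
        mu = np.full(len(genes), p.baseline_mean, dtype=float)
        if lineage in p.marker_programs:
            markers, boost = p.marker_programs[lineage]
            idx = [genes.index(g) for g in markers if g in genes]
            mu[idx] += boost
        mu[mito] = 0.0
        non_mito_total = mu.sum()
        f = p.mito_fraction_mean
        if f > 0 and mito.any():
            mu[mito] = f / (1 - f) * non_mito_total / mito.sum()
        means[lineage] = mu
    return means


def simulate_counts(p: SyntheticCountParams) -> tuple[GeneMatrix, np.ndarray]:
    """Simulate a count matrix with known lineage labels.

    Returns the matrix and one truth label per cell: a lineage name, or
    ``"LOWQ"`` for the injected low-quality cells (high mitochondrial
    load, strongly reduced non-mitochondrial depth).  Reproducible: the
    same params (including seed) give the identical matrix.
    """
    rng = np.random.default_rng(p.seed)
    genes = _gene_universe(p)
    means = _lineage_means(p, genes)
    mito = np.array([g in MITO_GENES for g in genes])

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for lineage in p.n_cells_per_lineage:
        n = int(p.n_cells_per_lineage[lineage])
        mu = np.broadcast_to(means[lineage][:, None], (len(genes), n))
        blocks.append(_nb_sample(rng, mu, p.nb_dispersion))
        labels.extend([lineage] * n)
    if p.n_lowquality_cells:
        base_lineages = list(p.n_cells_per_lineage)
        picks = rng.integers(len(base_lineages), size=p.n_lowquality_cells)
        mu_lq = np.stack([means[base_lineages[i]].copy() for i in picks], axis=1)
        mu_lq[~mito] *= p.lowquality_depth_factor
        non_mito_total = mu_lq[~mito].sum(axis=0)
        f = p.lowquality_mito
        if mito.any() and f > 0:
            mu_lq[mito] = f / (1 - f) * non_mito_total / mito.sum()
        blocks.append(_nb_sample(rng, mu_lq, p.nb_dispersion))
        labels.extend(["LOWQ"] * p.n_lowquality_cells)

    counts = np.concatenate(blocks, axis=1)
    labels_arr = np.asarray(labels, dtype=object)
    n_cells = counts.shape[1]
    perm = rng.permutation(n_cells)
    counts = counts[:, perm]
    labels_arr = labels_arr[perm]

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    embryo_idx = rng.integers(p.n_embryos, size=n_cells)
    stage = np.where(embryo_idx < (p.n_embryos + 1) // 2, 9, 11)
    meta = pd.DataFrame(
        {
            "embryo_id": pd.array([f"E{i + 1:02d}" for i in embryo_idx], dtype="string"),
            "stage_dpf": pd.array(stage, dtype="Int64"),
            "source": pd.array(["synthetic"] * n_cells, dtype="string"),
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    matrix = GeneMatrix(
        gene_ids=genes,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts.astype(np.int64)),
        cell_meta=meta,
    )
    return matrix, labels_arr


@dataclass
class SyntheticGeometryParams:
    """Parameters of the synthetic 3D embryo geometry generator.

    ``concentration_kappa`` controls how strongly marker-positive cells
    concentrate toward ``anterior_direction`` (0 = uniform over the
    hemisphere); ``marker_fraction`` fixes the expected positive fraction
    regardless of kappa.  ``radius_um`` defaults to 50 um, the scale of a
    post-implantation embryo.
    """

    n_epiblast: int = 40
    n_hypoblast: int = 25
    radius_um: float = 50.0
    marker_fraction: float = 0.3
    concentration_kappa: float = 0.0
    anterior_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    marker: str = "CER1"
    embryo_id: str = "E01"
    stage_dpf: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hypoblast <= 0:
            raise ValueError("n_hypoblast must be positive")
        if not 0 <= self.marker_fraction <= 1:
            raise ValueError("marker_fraction must be in [0, 1]")
        if self.concentration_kappa < 0:
            raise ValueError("concentration_kappa must be non-negative")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        a = np.asarray(self.anterior_direction, dtype=float)
        lateral = a - np.array([0.0, 0.0, a[2]])
        if np.linalg.norm(lateral) < 1e-9:
            raise ValueError("anterior_direction must have a lateral (non-distal) component")


def _select_weighted(rng: np.random.Generator, weights: np.ndarray, m: int) -> np.ndarray:
    """Indices of m items sampled without replacement with probability ~ weights."""
    n = len(weights)
    if m <= 0:
        return np.empty(0, dtype=int)
    if m >= n:
        return np.arange(n)
    # Efraimidis-Spirakis exponential-race keys
    keys = rng.exponential(size=n) / weights
    return np.argpartition(keys, m - 1)[:m]


def simulate_geometry(p: SyntheticGeometryParams) -> EmbryoGeometry:
    """Simulate one embryo: epiblast ball, hypoblast hemisphere, marker states.

    Hypoblast cells sit uniformly on the distal hemispherical shell
    (radius ``radius_um``, z >= 0); epiblast cells fill a ball entirely
    proximal of the equatorial plane.  Exactly
    ``round(marker_fraction * n_hypoblast)`` hypoblast cells are marked
    positive, chosen without replacement with weights
    ``exp(kappa * cos(angle to the anterior direction))``, so the marginal
    positive fraction matches ``marker_fraction`` for every kappa while
    kappa sets the angular concentration.
    """
    rng = np.random.default_rng(p.seed)
    R = p.radius_um
    n_hyp = p.n_hypoblast

    z = rng.uniform(0.0, 1.0, size=n_hyp)
    az = rng.uniform(0.0, 2 * np.pi, size=n_hyp)
    s = np.sqrt(1.0 - z**2)
    hyp = R * np.column_stack([s * np.cos(az), s * np.sin(az), z])

    centre = np.array([0.0, 0.0, -0.8 * R])
    direc = rng.normal(size=(p.n_epiblast, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    radii = 0.5 * R * rng.uniform(0.0, 1.0, size=p.n_epiblast) ** (1 / 3)
    epi = centre + direc * radii[:, None]

    a = np.asarray(p.anterior_direction, dtype=float)
    a = a / np.linalg.norm(a)
    cosang = (hyp / R) @ a
    weights = np.exp(p.concentration_kappa * cosang)
    m = int(round(p.marker_fraction * n_hyp))
    marker_pos = np.zeros(n_hyp, dtype=bool)
    marker_pos[_select_weighted(rng, weights, m)] = True

    n = p.n_epiblast + n_hyp
    df = pd.DataFrame(
        {
            "cell_id": [f"{p.embryo_id}_c{i:04d}" for i in range(n)],
            "x_um": np.concatenate([epi[:, 0], hyp[:, 0]]),
            "y_um": np.concatenate([epi[:, 1], hyp[:, 1]]),
            "z_um": np.concatenate([epi[:, 2], hyp[:, 2]]),
            "lineage": ["EPI"] * p.n_epiblast + ["HYP"] * n_hyp,
        }
    )
    for marker in GEOMETRY_MARKERS:
        df[marker] = False
    df.loc[df["lineage"] == "HYP", "GATA6"] = True
    df.loc[df["lineage"] == "EPI", "OCT4"] = True
    df.loc[df.index[p.n_epiblast:], p.marker] = marker_pos
    df["embryo_id"] = p.embryo_id
    df["stage_dpf"] = p.stage_dpf if p.stage_dpf is not None else pd.NA
    return EmbryoGeometry(df)


def simulate_geometry_cohort(
    stage_dpf: int,
    n_embryos: int,
    seed: int = 0,
    n_hypoblast: int = 25,
    n_epiblast: int = 40,
    kappa: float | None = None,
) -> list[EmbryoGeometry]:
    """A cohort of embryos at one stage with between-embryo variability.

    Per-embryo marker fractions are drawn from a Beta law whose mean and
    spread are the stage defaults (:data:`STAGE_GEOMETRY_DEFAULTS`); each
    embryo also receives a random anterior direction in the lateral
    plane.
    """
    if stage_dpf not in STAGE_GEOMETRY_DEFAULTS:
        raise ValueError(f"no geometry defaults for stage {stage_dpf} d.p.f.")
    mean_f, sd_f, stage_kappa = STAGE_GEOMETRY_DEFAULTS[stage_dpf]
    if kappa is None:
        kappa = stage_kappa
    nu = mean_f * (1 - mean_f) / sd_f**2 - 1
    alpha, beta = mean_f * nu, (1 - mean_f) * nu
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_embryos):
        f = float(rng.beta(alpha, beta))
        phi = rng.uniform(0, 2 * np.pi)
        params = SyntheticGeometryParams(
            n_epiblast=n_epiblast,
            n_hypoblast=n_hypoblast,
            marker_fraction=f,
            concentration_kappa=kappa,
            anterior_direction=(np.cos(phi), np.sin(phi), 0.0),
            embryo_id=f"S{stage_dpf}E{i + 1:02d}",
            stage_dpf=stage_dpf,
            seed=int(rng.integers(2**31)),
        )
        cohort.append(simulate_geometry(params))
    return cohort


def _programs_counts(
    rng: np.random.Generator,
    gene_means: Mapping[str, np.ndarray],
    n_per_label: Mapping[str, int],
    dispersion: float,
    genes: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    blocks, labels = [], []
    for label, n in n_per_label.items():
        mu = np.broadcast_to(gene_means[label][:, None], (len(genes), n))
        blocks.append(_nb_sample(rng, mu, dispersion))
        labels.extend([label] * n)
    counts = np.concatenate(blocks, axis=1)
    labels_arr = np.asarray(labels, dtype=object)
    perm = rng.permutation(counts.shape[1])
    return counts[:, perm], labels_arr[perm]


def simulate_stage_counts(
    seed: int = 0,
    n_per_stage: int = 120,
    n_genes: int = 600,
    dispersion: float = 2.0,
) -> tuple[GeneMatrix, np.ndarray]:
    """Epiblast-like cells across four pluripotency stages.

    Naive markers are high pre-implantation and fall after, primed
    markers rise post-implantation, and the core pluripotency genes
    increase monotonically — the transition the stage-projection model is
    meant to separate.
    """
    from .signalling import PLURIPOTENCY_PANELS

    naive = list(PLURIPOTENCY_PANELS["naive"])
    primed = list(PLURIPOTENCY_PANELS["primed"])
    core = list(PLURIPOTENCY_PANELS["core"])
    # each stage also carries a small unique program, as real stages do
    # (e.g. UTF1 rising only post-implantation)
    unique = {
        s: [f"STG{k}M{i}" for i in range(5)] for k, s in enumerate(STAGE_CLASSES)
    }
    genes = naive + primed + core + [g for s in STAGE_CLASSES for g in unique[s]]
    i = 1
    while len(genes) < n_genes:
        genes.append(f"BG{i:04d}")
        i += 1
    naive_boost = {s: b for s, b in zip(STAGE_CLASSES, (8.0, 6.0, 1.0, 0.3))}
    primed_boost = {s: b for s, b in zip(STAGE_CLASSES, (0.3, 1.0, 6.0, 8.0))}
    core_boost = {s: b for s, b in zip(STAGE_CLASSES, (1.0, 2.0, 3.0, 4.0))}
    means: dict[str, np.ndarray] = {}
    for stage in STAGE_CLASSES:
        mu = np.ones(len(genes))
        for g in naive:
            mu[genes.index(g)] += naive_boost[stage]
        for g in primed:
            mu[genes.index(g)] += primed_boost[stage]
        for g in core:
            mu[genes.index(g)] += core_boost[stage]
        for g in unique[stage]:
            mu[genes.index(g)] += 10.0
        means[stage] = mu
    rng = np.random.default_rng(seed)
    counts, labels = _programs_counts(
        rng, means, {s: n_per_stage for s in STAGE_CLASSES}, dispersion, genes
    )
    cell_ids = [f"stagecell{i:05d}" for i in range(counts.shape[1])]
    stage_dpf = {"ICM-5dpf": 5, "preEpi-6-7dpf": 6, "postEpi-9dpf": 9, "postEpi-11dpf": 11}
    meta = pd.DataFrame(
        {
            "embryo_id": pd.array([""] * len(cell_ids), dtype="string"),
            "stage_dpf": pd.array([stage_dpf[l] for l in labels], dtype="Int64"),
            "source": pd.array(["synthetic"] * len(cell_ids), dtype="string"),
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    matrix = GeneMatrix(
        gene_ids=genes, cell_ids=cell_ids, counts=sp.csr_matrix(counts), cell_meta=meta
    )
    return matrix, labels


def simulate_hypoblast_subpops(
    seed: int = 0,
    n_cells: int = 136,
    anterior_fraction: float = 0.3,
    n_genes: int = 300,
    dispersion: float = 2.0,
    boost: float = 12.0,
) -> tuple[GeneMatrix, np.ndarray]:
    """Hypoblast cells with a planted CER1-high anterior subpopulation.

    The anterior subpopulation co-expresses the antagonist program (CER1,
    LEFTY1/2, HHEX, NOG, DKK1/4, SFRP1); the remaining cells split into
    two background subpopulations with their own mild programs.
    """
    anterior_genes = ["CER1", "LEFTY1", "LEFTY2", "HHEX", "NOG", "DKK4", "DKK1", "SFRP1"]
    other1 = ["APOA1", "FN1", "COL4A1"]
    other2 = ["S100A14", "APOA2", "TTR"]
    genes = anterior_genes + other1 + other2 + ["NCLN", "CHRD", "SOSTDC1"]
    i = 1
    while len(genes) < n_genes:
        genes.append(f"BG{i:04d}")
        i += 1
    n_ant = int(round(anterior_fraction * n_cells))
    n_rest = n_cells - n_ant
    sizes = {"sub0": n_ant, "sub1": n_rest // 2, "sub2": n_rest - n_rest // 2}
    means: dict[str, np.ndarray] = {}
    for label, program in (("sub0", anterior_genes), ("sub1", other1), ("sub2", other2)):
        mu = np.ones(len(genes))
        for g in program:
            mu[genes.index(g)] += boost
        means[label] = mu
    rng = np.random.default_rng(seed)
    counts, labels = _programs_counts(rng, means, sizes, dispersion, genes)
    cell_ids = [f"hypcell{i:04d}" for i in range(counts.shape[1])]
    matrix = GeneMatrix(
        gene_ids=genes, cell_ids=cell_ids, counts=sp.csr_matrix(counts), cell_meta=None
    )
    return matrix, labels
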