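"""3D angular quantification of marker-positive hypoblast cells.

The post-implantation embryo is modelled as an epiblast cell mass with a
hypoblast lining its basal/distal side.  A proximal-distal axis is fitted
from the two lineages' centroids, every marker-positive hypoblast cell is
assigned an angle in [0 deg, 180 deg] along the hypoblast hemisphere, and a
label-permutation test asks whether the marker-positive cells concentrate
toward one side (a "localisation bias") rather than spreading evenly.

Angle convention: 0 deg is the side where the majority of marker-positive
cells sit (set by :func:`reference_direction`), 90 deg the distal pole and
180 deg the opposite side.  The bias test itself never uses that reference
direction: its statistic is the mean resultant length of the azimuthal unit
projections of the marker-positive cells, which is rotation-invariant and
therefore free of the circularity of first picking 0 deg from the data and
then testing for asymmetry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree

__all__ = [
    "GEOMETRY_MARKERS",
    "EmbryoGeometry",
    "EmbryoAxis",
    "AngularProfile",
    "DegenerateGeometryError",
    "InsufficientCellsError",
    "fit_axis",
    "reference_direction",
    "cell_angle",
    "angular_profile",
    "bias_test",
    "exhaustive_bias_test",
    "align_profiles",
    "marker_fraction",
    "marker_domain_distance",
]

#: marker channels carried by geometry tables (immunofluorescence panel)
GEOMETRY_MARKERS = ("CER1", "GATA6", "OCT4", "LEFTY1", "pSMAD15")

#: fixed 10-degree binning of the 0-180 degree hemisphere coordinate
BIN_EDGES = np.arange(0.0, 181.0, 10.0)


class DegenerateGeometryError(ValueError):
    """The cell configuration does not define the requested quantity."""


class InsufficientCellsError(ValueError):
    """Too few cells to run the requested test."""


@dataclass
class EmbryoGeometry:
    """Per-cell 3D positions (um) with lineage labels and marker states.

    Backed by a DataFrame with columns ``cell_id, x_um, y_um, z_um,
    lineage, <markers...>, embryo_id, stage_dpf``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        pos = self.positions()
        if not np.all(np.isfinite(pos)):
            raise DegenerateGeometryError("non-finite cell coordinates")

    def positions(self, lineage: str | None = None) -> np.ndarray:
        df = self.data if lineage is None else self.data[self.data["lineage"] == lineage]
        return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    @property
    def lineage(self) -> np.ndarray:
        return self.data["lineage"].to_numpy()

    def marker(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=bool)

    @property
    def embryo_id(self) -> str:
        ids = self.data["embryo_id"].unique()
        return str(ids[0]) if len(ids) == 1 else ""

    def split_by_embryo(self) -> list["EmbryoGeometry"]:
        return [
            EmbryoGeometry(sub.reset_index(drop=True))
            for _, sub in self.data.groupby("embryo_id", sort=True)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "EmbryoGeometry":
        """Apply a rigid transform ``p -> R p + t`` to every cell."""
        df = self.data.copy()
        new = self.positions() @ np.asarray(rotation).T + np.asarray(translation)
        df[["x_um", "y_um", "z_um"]] = new
        return EmbryoGeometry(df)


@dataclass
class EmbryoAxis:
    """Embryo-intrinsic frame: origin, distal unit vector, lateral reference.

    ``origin`` anchors the angle measurement, ``distal`` points from the
    epiblast toward the hypoblast, and ``lateral`` (the 0-degree direction)
    is set by :func:`reference_direction` once a marker is chosen.
    """

    origin: np.ndarray
    distal: np.ndarray
    lateral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if abs(np.linalg.norm(self.distal) - 1.0) > 1e-9:
            raise ValueError("distal vector must be unit length")
        if self.lateral is not None:
            self.lateral = np.asarray(self.lateral, dtype=float)
            if abs(np.linalg.norm(self.lateral) - 1.0) > 1e-9:
                raise ValueError("lateral vector must be unit length")
            if abs(float(self.distal @ self.lateral)) > 1e-9:
                raise ValueError("lateral must be orthogonal to distal")

    @property
    def complete(self) -> bool:
        return self.lateral is not None


@dataclass
class AngularProfile:
    """Angles of marker-positive hypoblast cells in one embryo."""

    embryo_id: str
    angles: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mean_angle: float
    n_marker_pos: int
    bias_p: float | None
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.bin_counts.sum()) != self.n_marker_pos:
            raise ValueError("bin counts do not sum to the marker-positive count")


def _hyp_mask(g: EmbryoGeometry) -> np.ndarray:
    return g.lineage == "HYP"


def fit_axis(g: EmbryoGeometry) -> EmbryoAxis:
    """Fit the proximal-distal axis from lineage centroids.

    The distal direction is the unit vector from the epiblast centroid to
    the hypoblast centroid; the origin is the epiblast centroid, a proxy
    for the middle of the epiblast's proximal surface.  The lateral
    reference is left unset.
    """
    epi = g.positions("EPI")
    hyp = g.positions("HYP")
    if len(epi) < 3 or len(hyp) < 3:
        raise InsufficientCellsError(
            f"need >=3 epiblast and >=3 hypoblast cells, got {len(epi)} and {len(hyp)}"
        )
    c_epi = epi.mean(axis=0)
    delta = hyp.mean(axis=0) - c_epi
    norm = np.linalg.norm(delta)
    if norm < 1e-6:
        raise DegenerateGeometryError("epiblast and hypoblast centroids coincide")
    return EmbryoAxis(origin=c_epi, distal=delta / norm)


def _lateral_components(points: np.ndarray, axis: EmbryoAxis) -> np.ndarray:
    rel = points - axis.origin
    return rel - np.outer(rel @ axis.distal, axis.distal)


def reference_direction(g: EmbryoGeometry, axis: EmbryoAxis, marker: str = "CER1") -> EmbryoAxis:
    """Set the 0-degree direction toward the marker-positive majority side.

    The lateral reference is the normalised mean of the marker-positive
    hypoblast cells' components orthogonal to the distal axis, so the
    marker-positive majority maps near 0 deg.
    """
    sel = _hyp_mask(g) & g.marker(marker)
    if not sel.any():
        raise DegenerateGeometryError("reference undefined: no marker-positive hypoblast cells")
    pts = g.positions()[sel]
    v = _lateral_components(pts, axis).mean(axis=0)
    hyp_radius = np.median(
        np.linalg.norm(g.positions("HYP") - axis.origin, axis=1)
    )
    if np.linalg.norm(v) < 1e-6 * max(hyp_radius, 1.0):
        raise DegenerateGeometryError("degenerate reference: marker-positive cells balance out")
    lateral = v / np.linalg.norm(v)
    # remove any floating-point drift off the orthogonal plane
    lateral -= (lateral @ axis.distal) * axis.distal
    lateral /= np.linalg.norm(lateral)
    return EmbryoAxis(origin=axis.origin, distal=axis.distal, lateral=lateral)


def cell_angle(p: np.ndarray, axis: EmbryoAxis) -> float:
    """Angle of a cell in the 0-180 degree hemisphere coordinate.

    ``theta = arccos(unit(p - origin) . lateral)`` in degrees: 0 deg on the
    majority side, 90 deg anywhere on the plane through the distal axis
    orthogonal to the lateral reference (including the distal pole),
    180 deg opposite the majority side.
    """
    if not axis.complete:
        raise ValueError("axis has no lateral reference; call reference_direction first")
    rel = np.asarray(p, dtype=float) - axis.origin
    norm = np.linalg.norm(rel)
    if norm < 1e-12:
        raise DegenerateGeometryError("undefined angle: cell coincides with the origin")
    cosang = float(rel @ axis.lateral) / norm
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def _angles(points: np.ndarray, axis: EmbryoAxis) -> np.ndarray:
    rel = points - axis.origin
    norms = np.linalg.norm(rel, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("undefined angle: cell coincides with the origin")
    cosang = np.clip((rel @ axis.lateral) / norms, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def bias_test(
    g: EmbryoGeometry,
    axis: EmbryoAxis,
    marker: str = "CER1",
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation test for azimuthal localisation bias of a marker.

    The statistic is the mean resultant length of the unit azimuthal
    projections of the marker-positive hypoblast cells (reference-free).
    The null permutes the marker labels among all hypoblast cells; the
    p-value uses the add-one convention and counts ties as extreme.
    """
    hyp = _hyp_mask(g)
    pos = g.marker(marker) & hyp
    n_pos = int(pos.sum())
    n_neg = int((hyp & ~pos).sum())
    if n_pos < 3 or n_neg < 3:
        if n_pos == int(hyp.sum()) and n_pos >= 3:
            return 1.0  # all hypoblast cells positive: a single distinct relabelling
        raise InsufficientCellsError(
            f"need >=3 marker-positive and >=3 marker-negative hypoblast cells "
            f"(got {n_pos} and {n_neg})"
        )
    lat = _lateral_components(g.positions()[hyp], axis)
    norms = np.linalg.norm(lat, axis=1)
    # cells exactly on the axis carry no azimuthal information
    off_axis = norms > 1e-12
    units = lat[off_axis] / norms[off_axis, None]
    labels = pos[hyp][off_axis]
    m = int(labels.sum())
    n = len(units)
    if m < 3 or n - m < 3:
        raise InsufficientCellsError("too few off-axis cells for the permutation test")
    t_obs = float(np.linalg.norm(units[labels].mean(axis=0)))
    rng = np.random.default_rng(seed)
    # vectorised label permutations: random subsets of size m
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    sums = units[idx].sum(axis=1) / m
    t_perm = np.linalg.norm(sums, axis=1)
    exceed = int(np.sum(t_perm >= t_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def exhaustive_bias_test(g: EmbryoGeometry, axis: EmbryoAxis, marker: str = "CER1") -> float:
    """Exact version of :func:`bias_test` enumerating every label subset.

    Only feasible for small hypoblasts; p is the exact proportion of
    subsets whose statistic is at least the observed one.
    """
    hyp = _hyp_mask(g)
    pos = g.marker(marker) & hyp
    lat = _lateral_components(g.positions()[hyp], axis)
    norms = np.linalg.norm(lat, axis=1)
    off_axis = norms > 1e-12
    units = lat[off_axis] / norms[off_axis, None]
    labels = pos[hyp][off_axis]
    m = int(labels.sum())
    n = len(units)
    if math.comb(n, m) > 2_000_000:
        raise ValueError("too many label subsets to enumerate")
    t_obs = float(np.linalg.norm(units[labels].mean(axis=0)))
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), m):
        t = float(np.linalg.norm(units[list(combo)].mean(axis=0)))
        if t >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def angular_profile(
    g: EmbryoGeometry,
    axis: EmbryoAxis,
    marker: str = "CER1",
    n_perm: int = 10_000,
    seed: int = 0,
) -> AngularProfile:
    """Angles, 10-degree histogram, mean angle and bias p for one embryo.

    Bins are right-open except the last ([170, 180] is closed).  The bias
    p-value is ``None`` when the permutation test is undefined (too few
    positive or negative cells).
    """
    if not axis.complete:
        raise ValueError("axis has no lateral reference; call reference_direction first")
    sel = _hyp_mask(g) & g.marker(marker)
    if not sel.any():
        raise DegenerateGeometryError("no marker-positive hypoblast cells")
    angles = _angles(g.positions()[sel], axis)
    counts, _ = np.histogram(angles, bins=BIN_EDGES)
    try:
        p = bias_test(g, axis, marker=marker, n_perm=n_perm, seed=seed)
    except InsufficientCellsError:
        p = None
    return AngularProfile(
        embryo_id=g.embryo_id,
        angles=angles,
        bin_edges=BIN_EDGES.copy(),
        bin_counts=counts,
        mean_angle=float(angles.mean()),
        n_marker_pos=int(sel.sum()),
        bias_p=p,
        seed=seed,
    )


def align_profiles(profiles: list[AngularProfile], alpha: float = 0.05) -> tuple[np.ndarray, pd.DataFrame]:
    """Pool per-embryo histograms and tabulate per-embryo summaries."""
    if not profiles:
        raise ValueError("no profiles to align")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if not np.array_equal(p.bin_edges, edges):
            raise ValueError("profiles have mismatched bin edges")
    pooled = np.sum([p.bin_counts for p in profiles], axis=0)
    table = pd.DataFrame(
        {
            "embryo_id": [p.embryo_id for p in profiles],
            "n_marker_pos": [p.n_marker_pos for p in profiles],
            "mean_angle": [p.mean_angle for p in profiles],
            "bias_p": [p.bias_p for p in profiles],
            "biased": [
                (p.bias_p is not None and p.bias_p <= alpha) for p in profiles
            ],
        }
    )
    return pooled, table


def marker_fraction(g: EmbryoGeometry, marker: str = "CER1", lineage: str = "HYP") -> float:
    """Fraction of cells of a lineage positive for a marker."""
    denom = g.lineage == lineage
    if not denom.any():
        raise InsufficientCellsError(f"no {lineage} cells in embryo {g.embryo_id!r}")
    return float((g.marker(marker) & denom).sum() / denom.sum())


def marker_domain_distance(
    g: EmbryoGeometry,
    from_marker: str = "pSMAD15",
    from_lineage: str = "EPI",
    to_marker: str = "CER1",
    to_lineage: str = "HYP",
) -> dict:
    """Nearest distance from each source-lineage cell to the target domain.

    Computes the Euclidean nearest-neighbour distance from every
    ``from_lineage`` cell to the set of ``to_marker``-positive
    ``to_lineage`` cells, then compares marker-positive versus
    marker-negative source cells by a two-sided rank-sum test.
    """
    target = (g.lineage == to_lineage) & g.marker(to_marker)
    source = g.lineage == from_lineage
    if not target.any() or not source.any():
        raise InsufficientCellsError("empty marker domain or source lineage")
    tree = cKDTree(g.positions()[target])
    dists, _ = tree.query(g.positions()[source])
    pos = g.marker(from_marker)[source]
    result = {
        "distances_pos": dists[pos],
        "distances_neg": dists[~pos],
        "median_pos": float(np.median(dists[pos])) if pos.any() else float("nan"),
        "median_neg": float(np.median(dists[~pos])) if (~pos).any() else float("nan"),
        "p_ranksum": float("nan"),
    }
    if pos.any() and (~pos).any():
        stat = scipy.stats.mannwhitneyu(dists[pos], dists[~pos], alternative="two-sided")
        result["p_ranksum"] = float(stat.pvalue)
    return result
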