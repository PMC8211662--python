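"""Nonparametric group comparisons for perturbation cell counts.

Per-embryo cell counts under different culture treatments are compared by
the Kruskal-Wallis rank test followed by Dunn's pairwise post-hoc z-tests
(pooled ranks, tie-corrected), with a family-wise adjustment across the
pairs (Holm by default).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["kruskal_wallis", "dunn_posthoc", "iqr_summary"]


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    return arrays


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def _holm(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.maximum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0))
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    adjust: str = "holm",
    control: str | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    ``adjust`` is the family-wise method over the tested pairs
    (``holm``, ``bonferroni`` or ``none``); ``control`` restricts the
    family to comparisons against one named group.
    """
    arrays = _check_groups(groups)
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names and groups differ in length")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    sizes = [g.size for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(arrays)), 2))
    if control is not None:
        if control not in names:
            raise ValueError(f"control group {control!r} not among names")
        ci = list(names).index(control)
        pairs = [(i, j) for i, j in pairs if ci in (i, j)]
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append((names[i], names[j], float(z), float(min(p, 1.0))))
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    p = frame["p_raw"].to_numpy()
    if adjust == "holm":
        frame["p_adj"] = _holm(p)
    elif adjust == "bonferroni":
        frame["p_adj"] = np.minimum(p * len(p), 1.0)
    elif adjust == "none":
        frame["p_adj"] = p
    else:
        raise ValueError(f"unknown adjustment: {adjust}")
    return frame


def iqr_summary(values: Sequence[float]) -> dict[str, float]:
    """Median, quartiles (linear interpolation), mean and range."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
    }
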