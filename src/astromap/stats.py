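"""Shared statistical machinery.

Rank-based tests (Kruskal-Wallis, Dunn's post hoc, two-sample rank-sum),
Benjamini-Hochberg multiplicity correction, and Ward agglomeration with
silhouette-width model selection.  Ties are handled with average ranks
throughout; Dunn's test is two-sided with the pooled-rank tie correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]


@dataclass
class ClusterResult:
    """Labels plus the silhouette profile that selected k."""

    labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    no_substructure: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.k != len(np.unique(self.labels)):
            raise ValueError("k must equal the number of distinct labels")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    Degenerate all-identical input returns H=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis",
                          tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis",
                      tuple(len(g) for g in groups))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled ranks, two-sided, tie-corrected.

    Returns one row per pair with columns ``group1, group2, z, p_value``
    and, when ``adjust`` is set, ``p_adjusted`` (Benjamini-Hochberg across
    all pairs of this family).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels/groups length mismatch")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]: bounds[i + 1]].mean() for i in range(len(groups))
    ]
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_value"])
    if adjust:
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> TestResult:
    """Two-sided two-sample rank-sum (Wilcoxon/Mann-Whitney) test.

    ``asymptotic`` uses the normal approximation with average-rank tie
    correction (the convention used for marker calling); ``exact`` defers
    to scipy's exact Mann-Whitney null distribution (small, tie-free
    samples only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if method == "exact":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "rank-sum-exact", (n1, n2))
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    n = n1 + n2
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return TestResult(0.0, 1.0, "rank-sum-asymptotic", (n1, n2))
    z = (w - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(float(z), float(p), "rank-sum-asymptotic", (n1, n2))


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000).

    A constant vector has no defined W; it is reported with W=NaN, p=0
    (treated as non-normal) and a warning.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        warnings.warn("constant input: Shapiro-Wilk W undefined, "
                      "reporting as non-normal")
        return TestResult(float("nan"), 0.0, "shapiro-wilk", (len(x),))
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk", (len(x),))


def ward_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Euclidean Ward agglomeration into k clusters."""
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(x)


def silhouette_select_k(
    x: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    no_structure_floor: float = 0.15,
) -> ClusterResult:
    """Choose the cluster count by maximum mean silhouette width.

    Ward agglomeration is run for every k in ``k_range`` (values with
    n <= k are skipped); the k with the highest mean silhouette wins,
    ties broken toward smaller k.  When even the best silhouette falls
    below ``no_structure_floor`` the result is flagged as having no
    substructure.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (observations x features)")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    n = x.shape[0]
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 2 or n <= k:
            continue
        lab = ward_labels(x, k)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(x, lab))
        labels_by_k[k] = lab
    if not sil:
        raise ValueError("no feasible k in k_range for n observations")
    best_k = min(sil, key=lambda k: (-sil[k], k))
    return ClusterResult(
        labels=labels_by_k[best_k],
        k=best_k,
        silhouette_by_k=sil,
        no_substructure=sil[best_k] < no_structure_floor,
    )
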