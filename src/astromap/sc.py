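"""Single-cell count-matrix pipeline.

QC floor of 54 transcripts per library, ln-normalization
(ln(1 + 1e4 * count / total)), highly-variable-gene selection by joint
thresholds on ln-mean and ln-variance/mean dispersion, z-scale -> PCA ->
Ward clustering with silhouette-selected k, marker-panel typing of
higher-order cell types, and marker-gene calling with the three stated
criteria (rank-sum p < 0.01, >= 1.28-fold linear overexpression,
expressed in > 25% of subtype cells).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .stats import ClusterResult, bh_adjust, silhouette_select_k

QC_MIN_TOTAL = 54
SCALE_FACTOR = 1e4
#: (ln-mean, dispersion) threshold pairs for the two selection passes
HVG_ALL_CELLS = (0.3, 0.1)
HVG_ASTROCYTES = (0.5, 0.5)


def _dense(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def qc_filter_cells(
    adata: ad.AnnData, min_total: int = QC_MIN_TOTAL
) -> tuple[ad.AnnData, list[str]]:
    """Drop libraries below the minimal total-transcript floor.

    Keeps cells whose total count is >= ``min_total``; returns the kept
    matrix and the discarded cell identifiers (input order preserved on
    both sides).
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    if adata.n_vars == 0:
        raise ValueError("count matrix has no genes")
    totals = _dense(adata).sum(axis=1)
    keep = totals >= min_total
    discarded = list(adata.obs_names[~keep])
    return adata[keep].copy(), discarded


def ln_normalize(adata: ad.AnnData,
                 scale_factor: float = SCALE_FACTOR) -> ad.AnnData:
    """ln(1 + scale_factor * count / cell_total) normalization.

    Zero-preserving and invariant to scaling a cell's counts by any
    positive constant.  Raw counts are kept in ``layers["counts"]``.
    """
    counts = _dense(adata).astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            "zero-total cell encountered; run qc_filter_cells first")
    values = np.log1p(scale_factor * counts / totals[:, None])
    out = adata.copy()
    out.X = values
    out.layers["counts"] = counts.astype(np.int32)
    out.uns["scale_factor"] = scale_factor
    return out


def hvg_stats(norm: ad.AnnData, mean_thr: float,
              disp_thr: float) -> pd.DataFrame:
    """Per-gene ln-mean, dispersion (variance/mean of ln values) and the
    strict-threshold selection flag.  Constant genes have dispersion 0
    and are never selected."""
    if norm.n_obs < 2:
        raise ValueError("need at least 2 cells")
    values = np.asarray(norm.X)
    ln_mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=0)
    var[np.all(values == values[0], axis=0)] = 0.0  # exactly-constant genes
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(ln_mean > 0, var / np.where(ln_mean > 0, ln_mean, 1.0),
                        0.0)
    selected = (ln_mean > mean_thr) & (disp > disp_thr)
    return pd.DataFrame({"ln_mean": ln_mean, "dispersion": disp,
                         "selected": selected}, index=norm.var_names)


def select_hvg(norm: ad.AnnData,
               mean_thr: float = HVG_ASTROCYTES[0],
               disp_thr: float = HVG_ASTROCYTES[1]) -> pd.DataFrame:
    """Highly-variable-gene table at the given strict thresholds."""
    return hvg_stats(norm, mean_thr, disp_thr)


def cluster_cells(
    norm: ad.AnnData,
    hvg: pd.DataFrame,
    k_max: int = 10,
    n_pcs: int = 20,
    no_structure_floor: float = 0.15,
    random_state: int = 0,
) -> ClusterResult:
    """z-scale HVG submatrix -> PCA -> Ward, k by max mean silhouette.

    Deterministic; flags "no substructure" when even the best silhouette
    stays below ``no_structure_floor``.
    """
    genes = hvg.index[hvg["selected"]]
    if len(genes) < 2:
        raise ValueError("need at least 2 selected HVGs for clustering")
    if norm.n_obs < k_max + 1:
        raise ValueError("need more cells than k_max")
    x = np.asarray(norm[:, genes].X, dtype=float)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(n_pcs, z.shape[0] - 1, z.shape[1])
    pcs = PCA(n_components=n_comp, random_state=random_state).fit_transform(z)
    return silhouette_select_k(pcs, range(2, k_max + 1),
                               no_structure_floor=no_structure_floor)


def assign_higher_order_types(
    norm: ad.AnnData,
    panels: Mapping[str, Sequence[str]],
    clusters: ClusterResult,
) -> dict[int, str]:
    """Type each cluster by its best-scoring marker panel.

    The score of a panel in a cluster is the mean ln-expression of the
    panel's genes over the cluster's cells; ties go to the
    lexicographically smallest cell type with a warning.
    """
    if not panels:
        raise ValueError("panels must be non-empty")
    for ct, genes in panels.items():
        missing = [g for g in genes if g not in norm.var_names]
        if missing:
            raise ValueError(f"panel {ct!r} genes absent from matrix: {missing}")
    values = np.asarray(norm.X)
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    assignment: dict[int, str] = {}
    for cl in np.unique(clusters.labels):
        mask = clusters.labels == cl
        scores = {
            ct: float(values[np.ix_(mask, [gene_idx[g] for g in genes])].mean())
            for ct, genes in panels.items()
        }
        best = max(scores.values())
        winners = sorted(ct for ct, s in scores.items() if s == best)
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl}: tie between panels {winners}; "
                "assigning lexicographically smallest")
        assignment[int(cl)] = winners[0]
    return assignment


def extract_type(
    adata: ad.AnnData, clusters: ClusterResult,
    assignment: Mapping[int, str], celltype: str = "astrocyte",
) -> ad.AnnData:
    """Cells belonging to clusters typed as ``celltype``."""
    wanted = {cl for cl, ct in assignment.items() if ct == celltype}
    mask = np.isin(clusters.labels, sorted(wanted))
    return adata[mask].copy()


def _ranksum_matrix(values: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, gene-wise, cluster vs rest.

    Normal approximation with average-rank tie correction.
    """
    n1 = int(in_cluster.sum())
    n2 = len(in_cluster) - n1
    n = n1 + n2
    ranks = sps.rankdata(values, axis=0)
    w = ranks[in_cluster].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # per-gene tie correction: sum(t^3 - t) over tied values
    tie_term = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie_term / (12.0 * n * (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(var), 0.0)
    return np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z)))


def find_markers(
    norm: ad.AnnData,
    labels: ClusterResult | np.ndarray,
    cluster: int | str,
    p_thr: float = 0.01,
    fold_thr: float = 1.28,
    pct_thr: float = 0.25,
    eps: float = 1e-9,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Upregulated marker genes of one cluster vs all other cells.

    Fold change is the linear ratio of de-logged (expm1) mean expression,
    eps-regularized; ``pct_expressing`` is the fraction of cluster cells
    with a nonzero count.  A gene passes when p < ``p_thr`` AND
    fold >= ``fold_thr`` AND pct > ``pct_thr``.  Output is sorted by p
    ascending, then fold descending.
    """
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    in_cluster = lab == cluster
    if not in_cluster.any():
        raise ValueError(f"unknown or empty cluster {cluster!r}")
    if in_cluster.all():
        raise ValueError("cluster complement is empty")
    values = np.asarray(norm.X, dtype=float)
    if method == "asymptotic":
        p = _ranksum_matrix(values, in_cluster)
    elif method == "exact":
        p = np.array([
            sps.mannwhitneyu(values[in_cluster, j], values[~in_cluster, j],
                             alternative="two-sided", method="exact").pvalue
            for j in range(values.shape[1])])
    else:
        raise ValueError(f"unknown method {method!r}")
    mean_in = np.expm1(values[in_cluster]).mean(axis=0)
    mean_out = np.expm1(values[~in_cluster]).mean(axis=0)
    fold = (mean_in + eps) / (mean_out + eps)
    pct = (values[in_cluster] > 0).mean(axis=0)
    up = mean_in > mean_out
    out = pd.DataFrame({
        "gene": np.asarray(norm.var_names),
        "cluster": cluster,
        "p_value": p,
        "fold_change": fold,
        "pct_expressing": pct,
    }).loc[up].copy()
    out["passes"] = ((out["p_value"] < p_thr)
                     & (out["fold_change"] >= fold_thr)
                     & (out["pct_expressing"] > pct_thr))
    out = out.sort_values(["p_value", "fold_change"],
                          ascending=[True, False], kind="mergesort")
    return out.reset_index(drop=True)


def subtype_proportions(
    labels: ClusterResult | Sequence, meta: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-label counts, overall fractions and CX/HP region split."""
    lab = labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)
    ser = pd.Series(lab, name="label")
    counts = ser.value_counts().sort_index()
    out = pd.DataFrame({"count": counts,
                        "fraction": counts / counts.sum()})
    if meta is not None and "region" in meta:
        region = pd.Series(np.asarray(meta["region"]), name="region")
        split = pd.crosstab(ser, region, normalize="columns")
        split.columns = [f"fraction_{c}" for c in split.columns]
        out = out.join(split)
    return out
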