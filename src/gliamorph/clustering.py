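"""Morphological subpopulation analysis.

The pipeline order is fixed: Z-score standardization (pooled over all
cells, never per group), PCA, UMAP embedding of the PC scores, then
K-means in the reduced space. Downstream, cluster frequencies are
compared between treatment groups with a Pearson chi-square, and each
parameter is compared across clusters with either one-way ANOVA +
Bonferroni pairwise tests or Kruskal–Wallis + Dunn's multiple
comparisons, gated by a D'Agostino–Pearson normality test.

Cluster ids are stabilized by relabeling in ascending order of the
cluster-mean PC1 score, so "cluster 1/2/3" means the same thing across
seeds and runs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import PipelineConfig

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureMatrix",
    "ClusterResult",
    "zscore",
    "pca",
    "umap_embed",
    "kmeans",
    "frequency_test",
    "cluster_comparisons",
    "cluster_pipeline",
]

#: The eight morphological parameters used for clustering.
FEATURE_COLUMNS = [
    "cell_volume_um3",
    "territory_um3",
    "ramification_index",
    "branchpoints",
    "endpoints",
    "avg_branch_um",
    "min_branch_um",
    "max_branch_um",
]

META_COLUMNS = ["cell_id", "animal_id", "group"]


@dataclass
class FeatureMatrix:
    """Cells × eight-parameter table with group/animal annotations."""

    values: pd.DataFrame  # feature columns only
    meta: pd.DataFrame  # cell_id, animal_id, group
    standardized: bool = False
    constant_columns: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame, features: list[str] | None = None) -> "FeatureMatrix":
        """Build from a morphometrics table; rows with any missing
        parameter (e.g., degenerate skeletons exported as NaN) are dropped
        with a logged count."""
        features = features or FEATURE_COLUMNS
        missing = [c for c in features if c not in df.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")
        meta = pd.DataFrame(index=df.index)
        for c in META_COLUMNS:
            meta[c] = df[c] if c in df.columns else ""
        vals = df[features].apply(pd.to_numeric, errors="coerce")
        keep = ~vals.isna().any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(f"dropped {dropped} rows with missing parameter values")
        return cls(
            values=vals[keep].reset_index(drop=True),
            meta=meta[keep].reset_index(drop=True),
            standardized=False,
            n_dropped_rows=dropped,
        )

    @property
    def n_cells(self) -> int:
        return len(self.values)


@dataclass
class ClusterResult:
    loading_matrix: pd.DataFrame  # parameters × components
    variance_explained: np.ndarray  # per-component %, sums to 100 over all PCs
    pc_scores: np.ndarray  # cells × components
    embedding: np.ndarray  # cells × 2
    labels: np.ndarray  # cluster ids in 1..k
    centroids: np.ndarray  # k × 2 (in the clustered space)
    frequency_table: pd.DataFrame  # group × cluster counts
    meta: pd.DataFrame
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization and linear reduction


def zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Pooled Z-score standardization: z = (x − μ)/σ per column.

    μ and σ (sample SD, n−1) are computed over all cells pooled, never per
    treatment group. Constant columns (σ = 0) are set to 0 and reported in
    ``constant_columns`` alongside a warning.
    """
    if matrix.n_cells < 2:
        raise ValueError("Z-score standardization needs at least 2 rows")
    mu = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    constant = [c for c in matrix.values.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if constant:
        warnings.warn(f"constant columns standardized to 0: {constant}")
    z = (matrix.values - mu) / sd.replace(0, np.nan)
    z[constant] = 0.0
    return FeatureMatrix(
        values=z,
        meta=matrix.meta,
        standardized=True,
        constant_columns=constant,
        n_dropped_rows=matrix.n_dropped_rows,
    )


def pca(
    matrix: FeatureMatrix, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA via eigen-decomposition of the pooled covariance matrix.

    On standardized input the covariance equals the correlation matrix.
    Components are ordered by decreasing eigenvalue;
    ``variance_explained[i] = 100·λ_i/Σλ`` (Σ over *all* eigenvalues, so
    the full set sums to 100). Sign convention: the largest-magnitude
    entry of each loading vector is positive.

    Returns ``(loading_matrix, variance_explained, pc_scores)``.
    """
    if not matrix.standardized:
        raise ValueError("PCA expects a standardized matrix; run zscore() first")
    x = matrix.values.to_numpy(dtype=np.float64)
    p = x.shape[1]
    if n_components is None:
        n_components = p
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} parameters")
    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    # deterministic sign: largest-|.| entry of each loading vector positive
    for j in range(p):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    var_pct = 100.0 * eigvals / eigvals.sum()
    scores = (x - x.mean(axis=0)) @ eigvecs
    loadings = pd.DataFrame(
        eigvecs[:, :n_components],
        index=matrix.values.columns,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return loadings, var_pct[:n_components], scores[:, :n_components]


# ---------------------------------------------------------------------------
# nonlinear embedding and clustering


def umap_embed(
    pc_scores: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """2D UMAP embedding of the PC scores (deterministic for a fixed seed)."""
    pc_scores = np.asarray(pc_scores, dtype=np.float64)
    if pc_scores.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"UMAP needs at least n_neighbors+1={n_neighbors + 1} rows, got {pc_scores.shape[0]}"
        )
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
        )
        return np.asarray(reducer.fit_transform(pc_scores), dtype=np.float64)


def kmeans(
    embedding: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    order_by: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means in the reduced space; labels are 1..k.

    Best of ``n_init`` random initializations by within-cluster sum of
    squares; deterministic for a fixed seed. Cluster ids are relabeled in
    ascending order of the cluster mean of ``order_by`` (default: the
    first embedding coordinate) so reports are stable across seeds.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    n = embedding.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(embedding)
    key = np.asarray(order_by, dtype=np.float64) if order_by is not None else embedding[:, 0]
    means = np.array([key[raw == j].mean() for j in range(k)])
    rank = np.empty(k, dtype=int)
    rank[np.argsort(means, kind="stable")] = np.arange(1, k + 1)
    labels = rank[raw]
    centroids = km.cluster_centers_[np.argsort(means, kind="stable")]
    return labels, centroids


# ---------------------------------------------------------------------------
# statistics on clusters


def frequency_test(
    labels: np.ndarray, group_labels: np.ndarray | pd.Series
) -> dict:
    """Pearson chi-square on the group × cluster contingency table."""
    labels = np.asarray(labels)
    group_labels = np.asarray(group_labels)
    table = pd.crosstab(pd.Series(group_labels, name="group"), pd.Series(labels, name="cluster"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("frequency test needs >= 2 groups and >= 2 clusters")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("empty group or cluster in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "table": table,
        "expected": pd.DataFrame(expected, index=table.index, columns=table.columns),
        "low_expected_cells": int((expected < 5).sum()),
    }


def _dunn_test(groups: list[np.ndarray]) -> list[dict]:
    """Dunn's post-hoc z-tests on mean ranks with tie correction and
    Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    at = 0
    for g in groups:
        mean_ranks.append(ranks[at : at + len(g)].mean())
        sizes.append(len(g))
        at += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    pairs = []
    comparisons = list(itertools.combinations(range(len(groups)), 2))
    for i, j in comparisons:
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        pairs.append(
            {
                "pair": (i + 1, j + 1),
                "statistic": float(z),
                "p_adjusted": float(min(1.0, p_raw * len(comparisons))),
            }
        )
    return pairs


def _bonferroni_ttests(groups: list[np.ndarray]) -> list[dict]:
    comparisons = list(itertools.combinations(range(len(groups)), 2))
    pairs = []
    for i, j in comparisons:
        t, p_raw = stats.ttest_ind(groups[i], groups[j])
        pairs.append(
            {
                "pair": (i + 1, j + 1),
                "statistic": float(t),
                "p_adjusted": float(min(1.0, p_raw * len(comparisons))),
            }
        )
    return pairs


def cluster_comparisons(
    records: pd.DataFrame,
    labels: np.ndarray,
    parameters: list[str] | None = None,
    alpha: float = 0.05,
    min_cluster_size: int = 3,
) -> dict:
    """Per-parameter comparison across clusters, normality-gated.

    For each parameter a D'Agostino–Pearson test on the pooled values
    chooses the branch: normal → one-way ANOVA with Bonferroni pairwise
    t-tests; non-normal → Kruskal–Wallis with Dunn's multiple
    comparisons. Parameters whose clusters fall below the minimum size,
    or that are constant (normality test degenerate), are flagged and not
    tested.
    """
    parameters = parameters or FEATURE_COLUMNS
    labels = np.asarray(labels)
    cluster_ids = np.unique(labels)
    report: dict[str, dict] = {}
    for param in parameters:
        values = records[param].to_numpy(dtype=np.float64)
        groups = [values[labels == c] for c in cluster_ids]
        entry: dict = {"clusters": [int(c) for c in cluster_ids]}
        if any(len(g) < min_cluster_size for g in groups):
            entry.update(test="none", flagged="cluster below minimum size")
            report[param] = entry
            continue
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            entry.update(test="none", flagged="constant data; normality test degenerate")
            report[param] = entry
            continue
        try:
            _, p_norm = stats.normaltest(pooled)
        except ValueError:
            entry.update(test="none", flagged="normality test degenerate")
            report[param] = entry
            continue
        entry["normality_p"] = float(p_norm)
        if p_norm > alpha:  # consistent with a normal distribution
            stat, p_omni = stats.f_oneway(*groups)
            entry.update(
                test="anova_bonferroni",
                statistic=float(stat),
                p_omnibus=float(p_omni),
                pairwise=_bonferroni_ttests(groups),
            )
        else:
            stat, p_omni = stats.kruskal(*groups)
            entry.update(
                test="kruskal_dunn",
                statistic=float(stat),
                p_omnibus=float(p_omni),
                pairwise=_dunn_test(groups),
            )
        report[param] = entry
    return report


# ---------------------------------------------------------------------------
# full pipeline


def cluster_pipeline(
    df: pd.DataFrame,
    config: PipelineConfig | None = None,
    features: list[str] | None = None,
) -> ClusterResult:
    """Z-score → PCA → UMAP → K-means on a morphometrics table."""
    config = config or PipelineConfig()
    fm = zscore(FeatureMatrix.from_frame(df, features=features))
    loadings, var_pct, scores = pca(fm, n_components=config.n_components)
    embedding = umap_embed(
        scores, n_neighbors=config.n_neighbors, min_dist=config.min_dist, seed=config.seed
    )
    space = embedding if config.cluster_space == "umap" else scores[:, :2]
    labels, centroids = kmeans(
        space, k=config.k, seed=config.seed, n_init=config.n_init, order_by=scores[:, 0]
    )
    groups = fm.meta["group"].to_numpy()
    if len(np.unique(groups[groups != ""])) >= 2 and config.k >= 2:
        freq = pd.crosstab(
            pd.Series(fm.meta["group"], name="group"), pd.Series(labels, name="cluster")
        )
    else:
        freq = pd.crosstab(pd.Series(["all"] * len(labels), name="group"), pd.Series(labels, name="cluster"))
    return ClusterResult(
        loading_matrix=loadings,
        variance_explained=var_pct,
        pc_scores=scores,
        embedding=embedding,
        labels=labels,
        centroids=centroids,
        frequency_table=freq,
        meta=fm.meta,
        params={
            "k": config.k,
            "seed": config.seed,
            "n_init": config.n_init,
            "n_neighbors": config.n_neighbors,
            "min_dist": config.min_dist,
            "n_components": config.n_components,
            "cluster_space": config.cluster_space,
            "dropped_rows": fm.n_dropped_rows,
            "constant_columns": fm.constant_columns,
        },
    )
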