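"""kNN-graph clustering, hybrid reference annotation, cluster composition.

Cells are embedded by PCA of the normalized log expression, connected to
their k nearest neighbors (undirected union graph), and partitioned by
Leiden modularity optimization. Cell types are assigned with a hybrid
two-reference strategy: every cell is correlated (Spearman) against an
immune reference panel and a whole-organism atlas panel, and the best
correlation across the two panels wins. Composition shifts between two
conditions are tested per cluster with a two-sided Fisher's exact test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .qc import NormalizedMatrix
from .scoring import bh_adjust


@dataclass
class ClusterLabels:
    """Per-cell small-integer labels, contiguous from 1."""

    cluster_id: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        labels = np.unique(self.cluster_id)
        if labels.size and (labels[0] != 1 or labels[-1] != labels.size):
            raise ValueError("labels must be contiguous from 1")
        self.n_clusters = int(labels.size)


def pca_embed(matrix: NormalizedMatrix, n_pcs: int = 20) -> np.ndarray:
    """Deterministic PCA scores (cells x n_pcs) of centered log expression."""
    x = matrix.values.T  # cells x genes
    x = x - x.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, *x.shape)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def knn_graph(
    matrix: NormalizedMatrix, n_pcs: int = 20, k: int = 15, seed: int = 0
) -> ig.Graph:
    """Undirected union kNN graph in PC space (Euclidean)."""
    from sklearn.neighbors import NearestNeighbors

    n_cells = matrix.values.shape[1]
    if k >= n_cells:
        raise ValueError(f"k={k} must be below the number of cells {n_cells}")
    emb = pca_embed(matrix, n_pcs)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = set()
    for i in range(n_cells):
        # with tied (duplicate) points the query point need not come first
        neighbors = [int(j) for j in idx[i] if j != i][:k]
        for j in neighbors:
            edges.add((min(i, j), max(i, j)))
    g = ig.Graph(n=n_cells, edges=sorted(edges), directed=False)
    return g


def cluster_cells(graph: ig.Graph, resolution: float = 1.0,
                  seed: int = 0) -> ClusterLabels:
    """Leiden modularity communities; labels contiguous from 1."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership, dtype=int)
    # relabel contiguously from 1, in order of first appearance
    _, inv = np.unique(membership, return_inverse=True)
    order = {}
    labels = np.empty_like(inv)
    nxt = 1
    for i, m in enumerate(inv):
        if m not in order:
            order[m] = nxt
            nxt += 1
        labels[i] = order[m]
    return ClusterLabels(cluster_id=labels, n_clusters=nxt - 1)


@dataclass
class ReferenceProfiles:
    """Mean log-expression profiles per reference cell-type label."""

    labels: list[str]
    profile: pd.DataFrame  # labels x genes
    is_immune_reference: bool = False

    def __post_init__(self) -> None:
        if list(self.profile.index) != list(self.labels):
            self.profile = self.profile.loc[self.labels]


class AnnotationError(ValueError):
    pass


def _spearman_to_profiles(
    values: np.ndarray, gene_ids: list[str], ref: ReferenceProfiles,
    n_top_genes: int,
) -> tuple[np.ndarray, list[str]]:
    """Spearman correlation of every cell against every reference profile."""
    shared = [g for g in gene_ids if g in set(ref.profile.columns)]
    if len(shared) < 50:
        raise AnnotationError(
            f"only {len(shared)} genes shared with reference (need >= 50)"
        )
    prof = ref.profile[shared].to_numpy(dtype=float)
    var = prof.var(axis=0)
    top = np.argsort(-var, kind="stable")[: min(n_top_genes, len(shared))]
    genes_used = [shared[i] for i in top]
    gi = {g: i for i, g in enumerate(gene_ids)}
    q = values[[gi[g] for g in genes_used], :]  # genes x cells
    r = prof[:, top]  # labels x genes
    q_rank = np.apply_along_axis(rankdata, 0, q)
    r_rank = np.apply_along_axis(rankdata, 1, r)
    qz = q_rank - q_rank.mean(axis=0, keepdims=True)
    rz = r_rank - r_rank.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(qz, axis=0)
    rn = np.linalg.norm(rz, axis=1)
    qn[qn == 0] = 1.0
    rn[rn == 0] = 1.0
    corr = (rz @ qz) / (rn[:, None] * qn[None, :])  # labels x cells
    return corr, ref.labels


def annotate_cells(
    matrix: NormalizedMatrix,
    immune_ref: ReferenceProfiles,
    atlas_ref: ReferenceProfiles,
    n_top_genes: int = 500,
    strategy: str = "best_correlation",
) -> list[str]:
    """Hybrid two-reference annotation.

    Per cell, Spearman correlation to every profile over the top
    ``n_top_genes`` most-variable shared reference genes. Under
    ``best_correlation`` (default) the immune label is assigned when the
    best immune correlation exceeds the best atlas correlation, else the
    atlas label; ``immune_first`` assigns the immune label whenever its
    best correlation is positive. Ties break lexicographically.
    """
    if strategy not in ("best_correlation", "immune_first"):
        raise ValueError(f"unknown strategy {strategy!r}")
    corr_imm, labels_imm = _spearman_to_profiles(
        matrix.values, matrix.gene_ids, immune_ref, n_top_genes
    )
    corr_atlas, labels_atlas = _spearman_to_profiles(
        matrix.values, matrix.gene_ids, atlas_ref, n_top_genes
    )

    def best(corr: np.ndarray, labels: list[str], c: int) -> tuple[float, str]:
        col = corr[:, c]
        m = col.max()
        cands = sorted(labels[i] for i in np.flatnonzero(col == m))
        return float(m), cands[0]

    out = []
    for c in range(matrix.values.shape[1]):
        bi, li = best(corr_imm, labels_imm, c)
        ba, la = best(corr_atlas, labels_atlas, c)
        if strategy == "immune_first" and bi > 0:
            out.append(li)
        elif bi > ba or (bi == ba and li <= la):
            out.append(li)
        else:
            out.append(la)
    return out


def cluster_composition(
    labels: ClusterLabels, condition, condition_order: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster 2x2 Fisher tests of membership vs condition.

    Returns one row per cluster with counts, percentages (each condition's
    percentages sum to 100 over clusters), fold change of percentages
    (condition B over A), odds ratio, two-sided Fisher p, BH FDR across
    clusters, and a direction call relative to condition B (``enriched``
    when B's share exceeds A's at FDR <= alpha).
    """
    condition = np.asarray(condition)
    conds = condition_order or sorted(pd.unique(condition).tolist())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    a_mask = condition == conds[0]
    b_mask = condition == conds[1]
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both conditions must be present")
    n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
    rows = []
    for cl in range(1, labels.n_clusters + 1):
        in_cl = labels.cluster_id == cl
        ca = int((in_cl & a_mask).sum())
        cb = int((in_cl & b_mask).sum())
        table = [[ca, n_a - ca], [cb, n_b - cb]]
        odds, p = fisher_exact(table, alternative="two-sided")
        pct_a = 100.0 * ca / n_a
        pct_b = 100.0 * cb / n_b
        fc = pct_b / pct_a if pct_a > 0 else math.inf
        rows.append(
            {
                "cluster_id": cl,
                "n_condition_a": ca,
                "n_condition_b": cb,
                "pct_a": pct_a,
                "pct_b": pct_b,
                "fold_change": fc,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    direction = np.where(
        (df["fdr"] <= alpha) & (df["pct_b"] > df["pct_a"]),
        "enriched",
        np.where(
            (df["fdr"] <= alpha) & (df["pct_b"] < df["pct_a"]),
            "depleted",
            "unchanged",
        ),
    )
    df["direction"] = direction
    return df


def fold_reduction(pct_before: float, pct_after: float) -> float:
    """Fold reduction of a cluster share, rounded to one decimal.

    Returns ``inf`` when the cluster vanishes entirely (pct_after = 0).
    """
    if pct_after < 0 or pct_before < 0:
        raise ValueError("percentages must be non-negative")
    if pct_after == 0:
        return math.inf
    return round(pct_before / pct_after, 1)
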