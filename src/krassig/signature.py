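"""Differential expression and cross-species signature derivation.

Differential expression uses a genewise two-group negative-binomial
likelihood-ratio test: per-gene dispersions are estimated by the method of
moments on size-factor-scaled counts, floored at 1e-8 and shrunk 30%
toward the global median; group means are maximum-likelihood under the
null (one shared mean) and the alternative (one mean per group) at fixed
dispersion; the LRT statistic 2*(ll_alt - ll_null) is referred to a
chi-square with one degree of freedom and Benjamini-Hochberg corrected
across genes. The NB is parameterized mean/dispersion with variance
mu + alpha * mu**2.

The cross-species signature is the set of homolog pairs passing the fold
change (and optionally FDR) thresholds in *both* species' tumor-cluster
versus other-epithelial contrasts — the construction that yields the
published 21-up / 9-down mutant-KRAS-associated marker set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import CountMatrix
from .scoring import bh_adjust
from .simulate import HomologMap

_EPS = 1e-8


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def _nb_mle_mean(y: np.ndarray, s: np.ndarray, r: np.ndarray,
                 n_iter: int = 200, tol: float = 1e-14) -> np.ndarray:
    """MLE of the NB mean per gene under per-cell exposures ``s``.

    Solves the score equation sum_c y_gc / mu = sum_c (y_gc + r_g) s_c /
    (r_g + s_c mu) by the fixed-point iteration
    mu <- sum(y) / sum((y + r) s / (r + s mu)), which is the stationarity
    condition rearranged; it converges monotonically from the
    Poisson start mu0 = sum(y) / sum(s).
    """
    total = y.sum(axis=1)
    s_sum = s.sum()
    mu = total / s_sum
    active = total > 0
    for _ in range(n_iter):
        if not active.any():
            break
        denom = (
            (y[active] + r[active, None]) * s[None, :]
            / (r[active, None] + s[None, :] * mu[active, None])
        ).sum(axis=1)
        new = total[active] / denom
        moved = np.abs(new - mu[active]) > tol * np.maximum(mu[active], 1.0)
        mu[active] = new
        if not moved.any():
            break
    return mu


def _nb_loglik(y: np.ndarray, s: np.ndarray, mu: np.ndarray,
               r: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood at mean ``mu`` (size r = 1/dispersion)."""
    m = s[None, :] * mu[:, None]
    rr = r[:, None]
    p = rr / (rr + m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = stats.nbinom.logpmf(y, rr, p)
    # mu = 0 genes: pmf is a point mass at 0
    ll = np.where((m == 0) & (y == 0), 0.0, ll)
    ll = np.where((m == 0) & (y > 0), -np.inf, ll)
    return ll.sum(axis=1)


def moment_dispersions(y: np.ndarray, s: np.ndarray,
                       shrink: float = 0.3) -> np.ndarray:
    """Method-of-moments NB dispersions on scaled counts, floored at 1e-8
    and shrunk ``shrink`` of the way toward the global median."""
    scaled = y / s[None, :]
    m = scaled.mean(axis=1)
    v = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, _EPS)
    alpha = np.maximum(alpha, _EPS)
    med = float(np.median(alpha))
    return (1.0 - shrink) * alpha + shrink * med


def nb_glm_lrt(
    counts_in_group,
    counts_rest,
    size_factors_in_group,
    size_factors_rest,
    gene_ids=None,
) -> pd.DataFrame:
    """Genewise NB likelihood-ratio test of group-of-interest vs rest.

    Returns a DataFrame with ``gene_id``, ``log2_fc`` (group of interest
    over rest, pseudocount 1e-8 on fitted means), ``p_value``, ``fdr``,
    ``mean_a``, ``mean_b``. Swapping the groups negates ``log2_fc`` and
    leaves p-values unchanged.
    """
    ya, yb = _dense(counts_in_group), _dense(counts_rest)
    sa = np.asarray(size_factors_in_group, dtype=float)
    sb = np.asarray(size_factors_rest, dtype=float)
    if ya.shape[1] < 3 or yb.shape[1] < 3:
        small = "group of interest" if ya.shape[1] < 3 else "rest group"
        raise ValueError(f"{small} has fewer than 3 cells")
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("size factors must be positive")
    if ya.shape[0] != yb.shape[0]:
        raise ValueError("gene dimensions differ between groups")
    n_genes = ya.shape[0]
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(n_genes)]

    y = np.concatenate([ya, yb], axis=1)
    s = np.concatenate([sa, sb])
    alpha = moment_dispersions(y, s)
    r = 1.0 / alpha

    mu_a = _nb_mle_mean(ya, sa, r)
    mu_b = _nb_mle_mean(yb, sb, r)
    mu_0 = _nb_mle_mean(y, s, r)

    ll_alt = _nb_loglik(ya, sa, mu_a, r) + _nb_loglik(yb, sb, mu_b, r)
    ll_null = _nb_loglik(y, s, mu_0, r)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(lrt == 0.0, 1.0, p)

    lfc = np.log2((mu_a + _EPS) / (mu_b + _EPS))
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2_fc": lfc,
            "p_value": p,
            "fdr": bh_adjust(p),
            "mean_a": mu_a,
            "mean_b": mu_b,
        }
    )


def find_cluster_markers(
    matrix: CountMatrix,
    labels,
    size_factors,
    top_n: int = 25,
) -> pd.DataFrame:
    """Top-``top_n`` upregulated one-vs-rest markers per cluster with the
    uniqueness rule.

    For each cluster, NB-LRT of in-cluster vs rest on raw counts keeps the
    upregulated direction only, ranked by p-value then |log2_fc| then gene
    id. The candidate table (``top_n`` rows per cluster) is returned with a
    ``retained`` flag that is False for genes appearing in more than one
    cluster's top list.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    cluster_id = np.asarray(getattr(labels, "cluster_id", labels), dtype=int)
    clusters = np.unique(cluster_id)
    if clusters.size < 2:
        raise ValueError("marker finding needs >= 2 clusters")
    sf = np.asarray(size_factors, dtype=float)
    counts = _dense(matrix.counts)
    frames = []
    for cl in clusters:
        mask = cluster_id == cl
        de = nb_glm_lrt(
            counts[:, mask], counts[:, ~mask], sf[mask], sf[~mask],
            gene_ids=matrix.gene_ids,
        )
        de = de[de["log2_fc"] > 0].copy()
        de["abs_lfc"] = de["log2_fc"].abs()
        de = de.sort_values(
            ["p_value", "abs_lfc", "gene_id"], ascending=[True, False, True],
            kind="stable",
        ).head(top_n)
        de["cluster_id"] = int(cl)
        de["rank"] = np.arange(1, len(de) + 1)
        frames.append(de.drop(columns="abs_lfc"))
    table = pd.concat(frames, ignore_index=True)
    seen = table["gene_id"].value_counts()
    table["retained"] = table["gene_id"].map(seen) == 1
    return table


@dataclass
class SignatureSet:
    """Ordered up/down signature gene lists with derivation thresholds.

    ``up_genes``/``down_genes`` use species-A identifiers;
    ``species_a_ids``/``species_b_ids`` hold the aligned homolog columns
    over the union of both lists (up first).
    """

    up_genes: list[str]
    down_genes: list[str]
    species_a_ids: list[str] = field(default_factory=list)
    species_b_ids: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down signature sets must be disjoint")


def derive_common_signature(
    de_species_a: pd.DataFrame,
    de_species_b: pd.DataFrame,
    homolog_map: HomologMap,
    up_min: float = 1.5,
    down_max: float = -1.5,
    fdr_max: float | None = 0.05,
) -> SignatureSet:
    """Homolog pairs passing thresholds in both species' contrasts.

    Up set: log2_fc >= ``up_min`` (and fdr <= ``fdr_max`` unless disabled
    with ``fdr_max=None``) in both species; down set analogously with
    log2_fc <= ``down_max``. Output ordered by the cross-species mean
    |log2_fc| descending.
    """
    if len(homolog_map) == 0:
        raise ValueError("homolog map is empty")
    a = de_species_a.set_index("gene_id")
    b = de_species_b.set_index("gene_id")
    pairs = homolog_map.to_frame()
    pairs = pairs[
        pairs["species_a_id"].isin(a.index) & pairs["species_b_id"].isin(b.index)
    ]
    lfc_a = a.loc[pairs["species_a_id"], "log2_fc"].to_numpy()
    lfc_b = b.loc[pairs["species_b_id"], "log2_fc"].to_numpy()
    ok = np.ones(len(pairs), dtype=bool)
    if fdr_max is not None:
        ok &= a.loc[pairs["species_a_id"], "fdr"].to_numpy() <= fdr_max
        ok &= b.loc[pairs["species_b_id"], "fdr"].to_numpy() <= fdr_max
    up = ok & (lfc_a >= up_min) & (lfc_b >= up_min)
    down = ok & (lfc_a <= down_max) & (lfc_b <= down_max)
    strength = (np.abs(lfc_a) + np.abs(lfc_b)) / 2.0

    def ordered(mask: np.ndarray) -> pd.DataFrame:
        sub = pairs[mask].assign(strength=strength[mask])
        return sub.sort_values(
            ["strength", "species_a_id"], ascending=[False, True], kind="stable"
        )

    up_df, down_df = ordered(up), ordered(down)
    both = pd.concat([up_df, down_df], ignore_index=True)
    return SignatureSet(
        up_genes=up_df["species_a_id"].tolist(),
        down_genes=down_df["species_a_id"].tolist(),
        species_a_ids=both["species_a_id"].tolist(),
        species_b_ids=both["species_b_id"].tolist(),
        thresholds={
            "up_min": up_min,
            "down_max": down_max,
            "fdr_max": fdr_max,
        },
    )
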