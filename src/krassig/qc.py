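"""Cell-level quality control, filtering and normalization.

The filtering procedure runs five rules in a fixed order:

1. *Trim*: drop cells whose total counts fall below a threshold derived
   from the mode of the per-cell total-count distribution (the piecewise
   rule implemented in :func:`trim_threshold`).
2. Library-size outliers: more than 3 raw MADs below or 6 above the median.
3. Detected-gene outliers: more than 2 MADs below or 5 above the median.
4. Mitochondrial-percentage outliers: more than 6 MADs above the median.
5. Doublets: simulated-doublet kNN score >= 0.99.

MAD statistics (median and MAD per metric) are computed once on the
post-trim population. MAD here is the raw median absolute deviation on the
linear scale, with no Gaussian consistency constant, unless configured
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix


class InsufficientDataError(ValueError):
    pass


MAD_GAUSSIAN_CONSTANT = 1.4826


def estimate_count_mode(total_counts, grid_size: int = 4096) -> float:
    """Mode of the per-cell total-count distribution.

    A Gaussian KDE with Silverman bandwidth is fitted to
    ``log10(total + 1)`` and maximized on a dense grid; the argmax is
    back-transformed to the count scale. Deterministic.
    """
    totals = np.asarray(total_counts, dtype=float)
    if totals.size < 10:
        raise InsufficientDataError(
            f"mode estimation needs >= 10 cells, got {totals.size}"
        )
    x = np.log10(totals + 1.0)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:  # degenerate: all totals equal
        return float(totals[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    return float(10.0 ** grid[int(np.argmax(dens))] - 1.0)


def trim_threshold(
    mode_estimate: float, interpretation: str = "continuous_multiplier"
) -> float:
    """Minimum-counts cutoff from the mode of the total-count distribution.

    The published rule is piecewise in ``mode_estimate`` m:

    * m < 100:        threshold = m * 5.5
    * 100 <= m <= 450: threshold = (-0.01 * m) + 6.5   (as printed)
    * m > 450:        threshold = m * 2

    Read literally, the middle branch yields thresholds of 2-6.5 counts and
    is discontinuous with both flanking branches. Under the default
    ``continuous_multiplier`` interpretation the middle expression is taken
    as a *multiplier* of m — threshold = m * (-0.01 m + 6.5) — which makes
    the rule continuous at m = 100 (550) and m = 450 (900) and strictly
    increasing. ``interpretation="literal"`` evaluates the middle branch
    exactly as printed.
    """
    m = float(mode_estimate)
    if m <= 0:
        raise ValueError("mode_estimate must be positive")
    if interpretation not in ("continuous_multiplier", "literal"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    if m < 100:
        return m * 5.5
    if m > 450:
        return m * 2.0
    middle = -0.01 * m + 6.5
    return middle if interpretation == "literal" else m * middle


@dataclass
class TrimRule:
    mode_estimate: float
    interpretation: str = "continuous_multiplier"
    trim_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.trim_threshold = trim_threshold(
            self.mode_estimate, self.interpretation
        )


def compute_cell_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell totals, detected genes and mito percentage (flags unset).

    ``pct_mito`` of an all-zero cell is defined as 0.
    """
    if matrix.n_genes == 0:
        raise ValueError("matrix has no genes")
    csc = matrix.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    n_genes = np.asarray((csc > 0).sum(axis=0)).ravel().astype(int)
    mito_totals = (
        np.asarray(csc[matrix.mito_flag].sum(axis=0)).ravel().astype(float)
        if matrix.mito_flag.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_totals / totals, 0.0)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "total_counts": totals,
            "n_genes_detected": n_genes,
            "pct_mito": pct,
        }
    )


def mad_outlier_flags(
    values,
    lower_nmads: float | None = None,
    upper_nmads: float | None = None,
    scale: float = 1.0,
) -> np.ndarray:
    """Flag values outside median -/+ nmads * MAD.

    MAD is the raw median absolute deviation (``scale=1.0``); pass
    ``scale=MAD_GAUSSIAN_CONSTANT`` for the Gaussian-consistent variant.
    A ``None`` bound disables that side. With MAD = 0 (constant vector)
    every value differing from the median is flagged; values equal to the
    median are kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("MAD flags need at least 2 values")
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * scale
    flags = np.zeros(v.size, dtype=bool)
    if lower_nmads is not None:
        flags |= v < med - lower_nmads * mad
    if upper_nmads is not None:
        flags |= v > med + upper_nmads * mad
    return flags


def doublet_scores(
    matrix: CountMatrix,
    k: int = 20,
    n_simulated: int | None = None,
    n_pcs: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Simulated-doublet kNN score in [0, 1] per cell.

    ``n_simulated`` artificial doublets (default: one per real cell)
    are formed by summing random distinct cell pairs. All columns, real
    and simulated, are total-count normalized to the median library size
    (so doublets are recognized by their hybrid expression profile, not
    their size, which varies strongly between genuine cells anyway), then
    log1p-transformed and embedded together by PCA. Each real cell's raw
    statistic is the fraction of its k nearest neighbors (self excluded)
    that are simulated doublets; genuine between-population doublets sit in
    hybrid regions populated almost exclusively by simulated doublets and
    rank at the top, while doublets of two same-population cells are not
    separable by construction.

    The returned score is the empirical CDF (average-rank / n) of the
    neighbor fraction across cells, so a cutoff of 0.99 excludes the top
    1% most doublet-like cells. The raw fraction itself cannot support
    such a cutoff: with k neighbors it moves in steps of 1/k, and the
    simulated pool inflates everyone's fraction toward the pool ratio.
    Deterministic under ``seed``.
    """
    n_cells = matrix.n_cells
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than n_cells={n_cells}")
    if n_cells < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} cells, got {n_cells}")
    if n_simulated is None:
        n_simulated = n_cells
    rng = np.random.default_rng(seed)
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    pairs_a = rng.integers(0, n_cells, size=n_simulated)
    pairs_b = (pairs_a + 1 + rng.integers(0, n_cells - 1, size=n_simulated)) % n_cells
    sim = dense[:, pairs_a] + dense[:, pairs_b]
    combined = np.concatenate([dense, sim], axis=1)
    totals = combined.sum(axis=0)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.where(totals > 0, totals, 1.0)
    combined = np.log1p(combined * (target / scale)[None, :]).T  # obs x genes
    combined = combined - combined.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, *combined.shape)
    if min(combined.shape) > 600:
        from sklearn.decomposition import PCA

        emb = PCA(
            n_components=n_pcs, svd_solver="randomized", random_state=seed
        ).fit_transform(combined)
    else:
        u, s, _ = np.linalg.svd(combined, full_matrices=False)
        emb = u[:, :n_pcs] * s[:n_pcs]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_cells])
    # drop self per row; with tied points self need not come first
    frac = np.array([
        np.mean([j >= n_cells for j in row if j != i][:k])
        for i, row in enumerate(idx)
    ])
    from scipy.stats import rankdata

    return rankdata(frac, method="average") / n_cells


@dataclass
class QCConfig:
    """Thresholds for :func:`apply_qc_filters` (published defaults)."""

    trim_interpretation: str = "continuous_multiplier"
    nmads_lib: tuple[float | None, float | None] = (3.0, 6.0)
    nmads_genes: tuple[float | None, float | None] = (2.0, 5.0)
    nmads_mito: tuple[float | None, float | None] = (None, 6.0)
    doublet_cutoff: float = 0.99
    doublet_k: int = 20
    doublet_n_simulated: int | None = None
    mad_scale: float = 1.0
    seed: int = 0


def apply_qc_filters(
    matrix: CountMatrix,
    config: QCConfig | None = None,
    doublet_score: np.ndarray | None = None,
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Run the five filtering rules; return (filtered matrix, QC table, report).

    ``doublet_score`` may be supplied as a full-length vector (e.g.
    precomputed); otherwise scores are computed, with the config's seed, on
    the population that actually reaches the doublet rule — the cells
    surviving the trim and MAD steps — so that simulated doublets are
    formed from plausible cells rather than debris barcodes. Cells removed
    earlier carry NaN scores in the QC table. Filtering is pure column
    selection — surviving counts are never altered. Removing every cell is
    reported as a warning, not an error.
    """
    config = config or QCConfig()
    qc = compute_cell_qc(matrix)
    totals = qc["total_counts"].to_numpy()

    mode = estimate_count_mode(totals)
    threshold = trim_threshold(mode, config.trim_interpretation)
    fail_trim = totals < threshold

    # MAD statistics computed once on the post-trim population
    survivors = ~fail_trim
    fail_lib = np.zeros(len(totals), dtype=bool)
    fail_genes = np.zeros(len(totals), dtype=bool)
    fail_mito = np.zeros(len(totals), dtype=bool)
    if survivors.sum() >= 2:
        for col, bounds, fail in (
            ("total_counts", config.nmads_lib, fail_lib),
            ("n_genes_detected", config.nmads_genes, fail_genes),
            ("pct_mito", config.nmads_mito, fail_mito),
        ):
            v = qc[col].to_numpy(dtype=float)
            flags_sub = mad_outlier_flags(
                v[survivors], bounds[0], bounds[1], scale=config.mad_scale
            )
            fail[np.flatnonzero(survivors)] = flags_sub

    pre_doublet = survivors & ~fail_lib & ~fail_genes & ~fail_mito
    score_warnings = []
    if doublet_score is None:
        doublet_score = np.full(len(totals), np.nan)
        n_pool = int(pre_doublet.sum())
        if n_pool > max(2 * config.doublet_k, config.doublet_k + 1):
            doublet_score[pre_doublet] = doublet_scores(
                matrix.subset_cells(pre_doublet),
                k=config.doublet_k,
                n_simulated=config.doublet_n_simulated,
                seed=config.seed,
            )
        elif n_pool:
            score_warnings.append(
                f"doublet scoring skipped: only {n_pool} cells"
            )
    else:
        doublet_score = np.asarray(doublet_score, dtype=float)
    qc["doublet_score"] = doublet_score
    with np.errstate(invalid="ignore"):
        fail_doublet = (
            pre_doublet
            & ~np.isnan(doublet_score)
            & (doublet_score >= config.doublet_cutoff)
        )

    qc["fail_trim"] = fail_trim
    qc["fail_libsize"] = fail_lib
    qc["fail_ngenes"] = fail_genes
    qc["fail_mito"] = fail_mito
    qc["fail_doublet"] = fail_doublet
    keep = ~(fail_trim | fail_lib | fail_genes | fail_mito | fail_doublet)

    report = {
        "n_input": int(matrix.n_cells),
        "mode_estimate": float(mode),
        "trim_threshold": float(threshold),
        "removed_trim": int(fail_trim.sum()),
        "removed_libsize": int((fail_lib & ~fail_trim).sum()),
        "removed_ngenes": int((fail_genes & ~fail_trim & ~fail_lib).sum()),
        "removed_mito": int(
            (fail_mito & ~fail_trim & ~fail_lib & ~fail_genes).sum()
        ),
        "removed_doublet": int(
            (fail_doublet & ~fail_trim & ~fail_lib & ~fail_genes & ~fail_mito).sum()
        ),
        "n_output": int(keep.sum()),
        "warnings": score_warnings
        + ([] if keep.any() else ["all cells removed"]),
    }
    return matrix.subset_cells(keep), qc, report


def size_factors(matrix: CountMatrix, min_detect_frac: float = 0.5,
                 min_ref_genes: int = 100) -> np.ndarray:
    """Per-cell positive scaling constants, rescaled to mean 1.

    Median-of-ratios against the per-gene mean over genes detected in at
    least ``min_detect_frac`` of cells; falls back to total-count scaling
    when fewer than ``min_ref_genes`` such genes exist.
    """
    csc = matrix.counts.tocsc()
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError(
            "zero-total cells present; run apply_qc_filters first"
        )
    detect_frac = np.asarray((csc > 0).mean(axis=1)).ravel()
    ref_genes = np.flatnonzero(detect_frac >= min_detect_frac)
    if ref_genes.size < min_ref_genes:
        factors = totals / totals.mean()
    else:
        sub = np.asarray(csc[ref_genes].todense(), dtype=float)
        ref = sub.mean(axis=1)
        ratios = sub / ref[:, None]
        factors = np.median(ratios, axis=0)
        if np.any(factors <= 0):  # pathological cells: fall back for those
            factors[factors <= 0] = (totals / totals.mean())[factors <= 0]
    return factors / factors.mean()


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) expression values (genes x cells)."""

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]


def normalize_log(matrix: CountMatrix, factors) -> NormalizedMatrix:
    factors = np.asarray(factors, dtype=float)
    if factors.size != matrix.n_cells:
        raise ValueError("one size factor per cell required")
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    values = np.log2(dense / factors[None, :] + 1.0)
    return NormalizedMatrix(
        values=values,
        size_factors=factors,
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
    )
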