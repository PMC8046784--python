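"""Synthetic data generators for the full pipeline.

Two generators are provided:

* :func:`generate_sc_dataset` draws a multi-cluster single-cell count matrix
  with negative-binomial noise, one planted tumor-specific cluster carrying
  up- and down-regulated signature genes, mitochondrial genes, low-quality
  cells (thinned counts, inflated mito fraction) and doublets (element-wise
  sums of two parent cells).
* :func:`generate_cohort` draws a bulk expression cohort in which mutant
  samples carry the planted signature shift and survival hazard depends on
  the standardized signature score.

The negative binomial is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu**2, the convention the differential-expression
stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


class InvalidConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass
class SimConfig:
    """Conditions for the single-cell generator.

    Defaults emulate the structure of the study system: a handful of
    transcriptional clusters, one of which (the planted tumor-specific
    cluster) carries a 21-up / 9-down signature at |log2FC| = 2, plus
    mitochondrial genes, low-quality barcodes and doublets. Low-quality
    (debris) barcodes form the majority of columns, as in raw
    droplet-based gene-cell matrices before knee-point filtering — the
    regime the mode-based trim rule presupposes, since its threshold is a
    multiple of the total-count density mode and that mode must sit on
    the debris peak for real cells to survive. ``cell_size_sigma`` is the
    coefficient of variation of gamma-distributed per-cell library sizes,
    and ``cluster_size_factors`` gives each cluster its own RNA-content
    scale (real cell types differ in library size; the resulting
    flat-topped composite metric distributions are also what keeps the
    MAD outlier rules from eating the genuine-cell population). Both are
    what makes size-factor estimation meaningful downstream.
    """

    n_genes: int = 5000
    n_clusters: int = 3
    n_cells_per_cluster: Sequence[int] | None = None  # None -> 200 each
    n_mito_genes: int = 20
    baseline_mean: float = 0.4
    dispersion: float = 0.3
    cell_size_sigma: float = 0.15
    cluster_size_factors: Sequence[float] | None = None  # None -> spread
    planted_cluster_index: int = 0
    signature_up_logfc: float = 2.0
    signature_down_logfc: float = -2.0
    n_signature_up: int = 21
    n_signature_down: int = 9
    n_markers_per_cluster: int = 30
    marker_logfc: float = 2.0
    frac_low_quality: float = 0.55
    frac_doublets: float = 0.05
    low_quality_thin: float = 0.15
    low_quality_mito_shift: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_genes,
            self.n_clusters,
            self.n_mito_genes,
            self.n_signature_up,
            self.n_signature_down,
            self.n_markers_per_cluster,
        ]
        if any(c < 0 for c in counts):
            raise InvalidConfigError("counts must be non-negative")
        for frac in (self.frac_low_quality, self.frac_doublets,
                     self.low_quality_thin, self.low_quality_mito_shift):
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError("fractions must lie in [0, 1]")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise InvalidConfigError("dispersion and baseline_mean must be > 0")
        if self.cell_size_sigma < 0:
            raise InvalidConfigError("cell_size_sigma must be >= 0")
        cells = self.cells_per_cluster()
        if self.n_clusters == 0 and sum(cells) > 0:
            raise InvalidConfigError("n_clusters = 0 with nonzero cells")
        if self.n_clusters and not 0 <= self.planted_cluster_index < self.n_clusters:
            raise InvalidConfigError("planted_cluster_index out of range")
        if len(cells) != self.n_clusters:
            raise InvalidConfigError(
                "n_cells_per_cluster length must equal n_clusters"
            )
        if (
            self.cluster_size_factors is not None
            and len(self.cluster_size_factors) != self.n_clusters
        ):
            raise InvalidConfigError(
                "cluster_size_factors length must equal n_clusters"
            )

    def cluster_sizes(self) -> np.ndarray:
        """Per-cluster library-size multipliers (cell types differ in RNA
        content); default spreads clusters geometrically over [0.7, 1.6]."""
        if self.cluster_size_factors is not None:
            return np.asarray(self.cluster_size_factors, dtype=float)
        if self.n_clusters <= 1:
            return np.ones(max(self.n_clusters, 0))
        return np.geomspace(0.7, 1.6, self.n_clusters)

    def cells_per_cluster(self) -> list[int]:
        if self.n_cells_per_cluster is None:
            return [200] * self.n_clusters
        return [int(c) for c in self.n_cells_per_cluster]


@dataclass
class GroundTruth:
    """Per-cell provenance of a simulated matrix.

    ``true_cluster_per_cell`` holds the parent cluster of every column
    (doublets carry the cluster of their first parent);
    ``doublet_parents`` records, for each doublet column, the indices of
    the two summed parent columns.
    """

    true_cluster_per_cell: np.ndarray
    is_doublet: np.ndarray
    is_low_quality: np.ndarray
    signature_up_genes: list[str]
    signature_down_genes: list[str]
    marker_genes: dict[int, list[str]] = field(default_factory=dict)
    doublet_parents: dict[int, tuple[int, int]] = field(default_factory=dict)

    def to_frame(self, cell_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": list(cell_ids),
                "true_cluster": self.true_cluster_per_cell,
                "is_doublet": self.is_doublet,
                "is_low_quality": self.is_low_quality,
            }
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mu, alpha) with variance mu + alpha mu^2 via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_ids(n_genes: int, n_mito: int) -> list[str]:
    ids = [f"G{i + 1:06d}" for i in range(n_genes - n_mito)]
    ids += [f"mt-G{i + 1:04d}" for i in range(n_mito)]
    return ids


def generate_sc_dataset(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a count matrix plus ground truth under ``config``.

    Gene-level baseline means are log-normal around ``baseline_mean``; each
    cluster receives ``n_markers_per_cluster`` private marker genes shifted
    by ``marker_logfc`` (log2); the planted cluster additionally carries the
    up/down signature genes, whose baselines are boosted (6x up, 8x down)
    to well-expressed levels. Mitochondrial genes contribute ~5% of
    counts in healthy cells. Low-quality cells are binomially thinned and
    mito-inflated; doublets are sums of two distinct non-doublet parents
    that remain in the matrix. Same seed, same config: bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    n_mito = min(config.n_mito_genes, n_genes)
    gene_ids = _gene_ids(n_genes, n_mito)
    mito_idx = np.arange(n_genes - n_mito, n_genes)
    nuclear_idx = np.arange(n_genes - n_mito)

    cells_per_cluster = config.cells_per_cluster()
    n_singlets = int(sum(cells_per_cluster))

    # baseline expression per gene
    base = rng.lognormal(np.log(config.baseline_mean), 1.0, size=n_genes)
    if n_mito:
        # pin mito genes so they carry ~5% of a healthy cell's counts
        nuclear_total = base[nuclear_idx].sum()
        base[mito_idx] = 0.05 * nuclear_total / 0.95 / n_mito

    # assign special genes from the nuclear pool
    n_special = (
        config.n_signature_up
        + config.n_signature_down
        + config.n_clusters * config.n_markers_per_cluster
    )
    if n_special > nuclear_idx.size:
        raise InvalidConfigError("not enough nuclear genes for planted effects")
    special = rng.choice(nuclear_idx, size=n_special, replace=False)
    pos = 0
    sig_up = special[pos : pos + config.n_signature_up]
    pos += config.n_signature_up
    sig_down = special[pos : pos + config.n_signature_down]
    pos += config.n_signature_down
    markers: dict[int, np.ndarray] = {}
    for k in range(config.n_clusters):
        markers[k] = special[pos : pos + config.n_markers_per_cluster]
        pos += config.n_markers_per_cluster
    # signature genes get tight, well-expressed baselines: usable markers
    # are never drawn from the barely-detected tail, and repression of a
    # down gene is only measurable from a high baseline (the study's down
    # genes are surfactant-class highly expressed transcripts)
    base[sig_up] = 6.0 * config.baseline_mean * rng.lognormal(
        0.0, 0.25, size=sig_up.size
    )
    base[sig_down] = 16.0 * config.baseline_mean * rng.lognormal(
        0.0, 0.25, size=sig_down.size
    )

    # per-cluster mean profiles
    logfc = np.zeros((config.n_clusters, n_genes))
    for k in range(config.n_clusters):
        logfc[k, markers[k]] += config.marker_logfc
    if config.n_clusters:
        p = config.planted_cluster_index
        logfc[p, sig_up] += config.signature_up_logfc
        logfc[p, sig_down] += config.signature_down_logfc

    columns = []
    clusters = []
    cluster_scale = config.cluster_sizes()
    for k, n_cells in enumerate(cells_per_cluster):
        mean_k = base * 2.0 ** logfc[k] * cluster_scale[k]
        # gamma-distributed relative cell sizes (mean 1, CV = cell_size_sigma):
        # right-skewed like real library sizes but with a lighter upper tail
        # than a log-normal
        if config.cell_size_sigma > 0:
            shape = 1.0 / config.cell_size_sigma**2
            sizes = rng.gamma(shape, config.cell_size_sigma**2, size=n_cells)
        else:
            sizes = np.ones(n_cells)
        block = _nb_draw(
            rng, mean_k[:, None] * sizes[None, :], config.dispersion
        )
        columns.append(block)
        clusters.extend([k] * n_cells)
    counts = (
        np.concatenate(columns, axis=1)
        if columns
        else np.zeros((n_genes, 0), dtype=int)
    )
    clusters = np.asarray(clusters, dtype=int)

    # low-quality cells: thin then reassign a share of counts to mito genes
    n_lq = int(round(config.frac_low_quality * n_singlets))
    lq_idx = rng.choice(n_singlets, size=n_lq, replace=False) if n_lq else []
    is_lq = np.zeros(n_singlets, dtype=bool)
    for c in lq_idx:
        col = rng.binomial(counts[:, c], config.low_quality_thin)
        moved = rng.binomial(col, config.low_quality_mito_shift)
        col = col - moved
        if n_mito and moved.sum():
            add = rng.multinomial(int(moved.sum()), np.full(n_mito, 1.0 / n_mito))
            col[mito_idx] += add
        counts[:, c] = col
        is_lq[c] = True

    # doublets: element-wise sums of two distinct non-doublet parents
    n_doublets = int(round(config.frac_doublets * n_singlets))
    doublet_cols = []
    doublet_parents: dict[int, tuple[int, int]] = {}
    for j in range(n_doublets):
        a, b = rng.choice(n_singlets, size=2, replace=False)
        doublet_cols.append(counts[:, a] + counts[:, b])
        doublet_parents[n_singlets + j] = (int(a), int(b))
    if doublet_cols:
        counts = np.concatenate([counts, np.stack(doublet_cols, axis=1)], axis=1)
    n_total = counts.shape[1]

    true_cluster = np.concatenate(
        [clusters, [clusters[doublet_parents[n_singlets + j][0]]
                    for j in range(n_doublets)]]
    ).astype(int) if n_total else clusters
    is_doublet = np.zeros(n_total, dtype=bool)
    is_doublet[n_singlets:] = True
    is_low_quality = np.concatenate([is_lq, np.zeros(n_doublets, dtype=bool)])

    cell_ids = [f"CELL{i + 1:06d}" for i in range(n_total)]
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
    )
    truth = GroundTruth(
        true_cluster_per_cell=true_cluster,
        is_doublet=is_doublet,
        is_low_quality=is_low_quality,
        signature_up_genes=[gene_ids[i] for i in sig_up],
        signature_down_genes=[gene_ids[i] for i in sig_down],
        marker_genes={k: [gene_ids[i] for i in v] for k, v in markers.items()},
        doublet_parents=doublet_parents,
    )
    return matrix, truth


@dataclass
class HomologMap:
    """One-to-one partial mapping between two species' gene identifiers."""

    species_a: list[str]
    species_b: list[str]

    def __post_init__(self) -> None:
        if len(self.species_a) != len(self.species_b):
            raise InvalidConfigError("homolog columns must align")
        if len(set(self.species_a)) != len(self.species_a) or len(
            set(self.species_b)
        ) != len(self.species_b):
            raise InvalidConfigError("homolog map must be one-to-one")

    def __len__(self) -> int:
        return len(self.species_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_a_id": self.species_a, "species_b_id": self.species_b}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HomologMap":
        return cls(
            species_a=df.iloc[:, 0].astype(str).tolist(),
            species_b=df.iloc[:, 1].astype(str).tolist(),
        )


def generate_homolog_map(
    gene_ids_a: Sequence[str],
    gene_ids_b: Sequence[str],
    fraction_mapped: float,
    seed: int = 0,
) -> HomologMap:
    """Random one-to-one partial homology covering
    ``floor(fraction_mapped * min(|a|, |b|))`` pairs."""
    if not gene_ids_a or not gene_ids_b:
        raise InvalidConfigError("gene lists must be non-empty")
    if not 0.0 <= fraction_mapped <= 1.0:
        raise InvalidConfigError("fraction_mapped must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(np.floor(fraction_mapped * min(len(gene_ids_a), len(gene_ids_b))))
    a = rng.choice(len(gene_ids_a), size=n, replace=False)
    b = rng.choice(len(gene_ids_b), size=n, replace=False)
    return HomologMap(
        species_a=[str(gene_ids_a[i]) for i in a],
        species_b=[str(gene_ids_b[i]) for i in b],
    )


def generate_reference_profiles(
    gene_ids: Sequence[str],
    labels: Sequence[str],
    seed: int = 0,
    scale: float = 1.0,
):
    """Toy reference panel: one mean log-expression profile per label.

    Profiles are independent exponential draws (scale ``scale``) per gene,
    which gives each cell type a distinct sparse-ish expression pattern.
    Returns a labels x genes DataFrame suitable for
    :class:`krassig.cluster.ReferenceProfiles`.
    """
    if not labels:
        raise InvalidConfigError("labels must be non-empty")
    rng = np.random.default_rng(seed)
    values = rng.exponential(scale, size=(len(labels), len(gene_ids)))
    return pd.DataFrame(values, index=list(labels), columns=list(gene_ids))


@dataclass
class CohortConfig:
    """Conditions for the bulk survival cohort generator.

    Defaults mirror the colon-adenocarcinoma cohort structure used to
    validate the signature (100 mutant / 211 wild-type samples) with the
    published 21-up / 9-down signature layout.
    """

    n_mutant: int = 100
    n_wildtype: int = 211
    n_genes: int = 200
    n_signature_up: int = 21
    n_signature_down: int = 9
    score_effect: float = 1.0
    baseline_hazard: float = 0.05
    hazard_ratio_per_score: float = 2.0
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mutant, self.n_wildtype, self.n_genes,
               self.n_signature_up, self.n_signature_down) < 0:
            raise InvalidConfigError("counts must be non-negative")
        if self.baseline_hazard <= 0 or self.hazard_ratio_per_score <= 0:
            raise InvalidConfigError("hazard parameters must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise InvalidConfigError("censor_rate must lie in [0, 1]")
        if self.n_signature_up + self.n_signature_down > self.n_genes:
            raise InvalidConfigError("signature larger than gene panel")


@dataclass
class CohortTable:
    """Bulk cohort: expression (samples x genes), clinical metadata, truth."""

    expression: pd.DataFrame
    clinical: pd.DataFrame  # sample_id, mutation_status, os_time, event
    signature_up: list[str]
    signature_down: list[str]


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a bulk cohort whose mutant samples carry the signature shift.

    Expression is standard normal per gene; mutant samples get +score_effect
    on up-signature genes and -score_effect on down-signature genes.
    Survival times are exponential with hazard
    ``baseline_hazard * hazard_ratio_per_score ** z`` where z is the
    cohort-standardized signature score; a ``censor_rate`` share of samples
    is administratively censored uniformly before their event time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mutant + config.n_wildtype
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    sig_up = genes[: config.n_signature_up]
    sig_down = genes[config.n_signature_up:
                     config.n_signature_up + config.n_signature_down]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    status = np.array(["mutant"] * config.n_mutant
                      + ["wildtype"] * config.n_wildtype)

    expr = rng.normal(size=(n, config.n_genes))
    mut = status == "mutant"
    up_cols = np.arange(config.n_signature_up)
    down_cols = np.arange(config.n_signature_up,
                          config.n_signature_up + config.n_signature_down)
    expr[np.ix_(mut, up_cols)] += config.score_effect
    expr[np.ix_(mut, down_cols)] -= config.score_effect

    if n:
        sig_vals = np.concatenate(
            [expr[:, up_cols], -expr[:, down_cols]], axis=1
        )
        raw_score = sig_vals.mean(axis=1) if sig_vals.shape[1] else np.zeros(n)
        sd = raw_score.std(ddof=1) if n > 1 else 1.0
        z = (raw_score - raw_score.mean()) / (sd if sd > 0 else 1.0)
        hazard = config.baseline_hazard * config.hazard_ratio_per_score ** z
        times = rng.exponential(1.0 / hazard)
        censored = rng.random(n) < config.censor_rate
        obs_times = np.where(censored, rng.uniform(0, times), times)
        events = ~censored
    else:
        obs_times = np.zeros(0)
        events = np.zeros(0, dtype=bool)

    expression = pd.DataFrame(expr, index=sample_ids, columns=genes)
    expression.index.name = "sample_id"
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "mutation_status": status,
            "os_time": obs_times,
            "event": events,
        }
    )
    return CohortTable(
        expression=expression,
        clinical=clinical,
        signature_up=sig_up,
        signature_down=sig_down,
    )
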