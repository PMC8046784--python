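"""Readers and writers for the on-disk formats the pipeline touches.

The canonical single-cell representation on disk is the Matrix Market
coordinate triplet (genes x cells, 1-based indices) flanked by ``genes.tsv``
and ``barcodes.tsv``, the layout produced by inDrop/10x-style pipelines.
Gzip-compressed variants (``matrix.mtx.gz`` ...) are accepted transparently.
Tables travel as CSV/TSV with a mandatory header row; signature sets as JSON;
configuration as YAML.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_MITO_PREFIXES = ("mt-", "MT-")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with identifiers and mito flags.

    ``counts`` is stored genes x cells (CSR), matching the Matrix Market
    orientation; ``mito_flag`` marks mitochondrially encoded genes by name
    prefix.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    mito_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell ids are not unique")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("counts must be non-negative integers")
        self.counts.data = data.astype(np.int64)
        if self.mito_flag is None:
            self.mito_flag = mito_flags(self.gene_ids)
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        if self.mito_flag.shape != (n_genes,):
            raise FormatError("mito_flag length does not match gene count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """Pure column selection; surviving counts are untouched."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            mito_flag=self.mito_flag.copy(),
        )


@dataclass
class PipelineConfig:
    """All stage parameters in one place, defaulting to the published values.

    QC: trim interpretation, MAD bounds per metric (lower, upper; None
    disables a side), doublet cutoff. Clustering: PCs, kNN k, Leiden
    resolution. Signature: fold-change and FDR gates.
    """

    trim_interpretation: str = "continuous_multiplier"
    nmads_lib: tuple = (3.0, 6.0)
    nmads_genes: tuple = (2.0, 5.0)
    nmads_mito: tuple = (None, 6.0)
    doublet_cutoff: float = 0.99
    n_pcs: int = 20
    knn_k: int = 15
    resolution: float = 1.0
    de_fdr_max: float = 0.05
    signature_up_min: float = 1.5
    signature_down_max: float = -1.5
    signature_fdr_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trim_interpretation not in ("continuous_multiplier", "literal"):
            raise ValueError("unknown trim interpretation")
        if not 0.0 <= self.doublet_cutoff <= 1.0:
            raise ValueError("doublet_cutoff must lie in [0, 1]")
        for frac in (self.de_fdr_max, self.signature_fdr_max):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("FDR thresholds must lie in [0, 1]")
        if self.n_pcs < 1 or self.knn_k < 1 or self.resolution <= 0:
            raise ValueError("clustering parameters out of range")
        if self.signature_up_min <= 0 or self.signature_down_max >= 0:
            raise ValueError("signature thresholds have the wrong sign")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("nmads_lib", "nmads_genes", "nmads_mito"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_yaml(self, path) -> Path:
        import dataclasses

        import yaml

        payload = dataclasses.asdict(self)
        for key in ("nmads_lib", "nmads_genes", "nmads_mito"):
            payload[key] = list(payload[key])
        path = Path(path)
        path.write_text(yaml.safe_dump(payload))
        return path


def mito_flags(
    gene_ids: Sequence[str], prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES
) -> np.ndarray:
    return np.array(
        [any(g.startswith(p) for p in prefixes) for g in gene_ids], dtype=bool
    )


def _resolve(directory_or_paths) -> tuple[Path, Path, Path]:
    if isinstance(directory_or_paths, (tuple, list)):
        mtx, genes, barcodes = (Path(p) for p in directory_or_paths)
        return mtx, genes, barcodes
    d = Path(directory_or_paths)
    out = []
    for stem in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        plain, gz = d / stem, d / (stem + ".gz")
        out.append(plain if plain.exists() else gz)
    return tuple(out)  # type: ignore[return-value]


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_count_matrix(
    directory_or_paths, mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES
) -> CountMatrix:
    """Load an MTX + genes.tsv + barcodes.tsv triplet losslessly.

    Raises :class:`FormatError` naming the offending file when the TSV line
    counts disagree with the matrix dimensions or entries are non-integer.
    """
    mtx_path, genes_path, barcodes_path = _resolve(directory_or_paths)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"{mtx_path}: not a valid Matrix Market file ({exc})")
    mat = sp.csr_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{mtx_path}: non-integer entries")
    gene_lines = _read_lines(genes_path)
    barcode_lines = _read_lines(barcodes_path)
    gene_ids = [line.split("\t")[0] for line in gene_lines]
    cell_ids = [line.split("\t")[0] for line in barcode_lines]
    if len(gene_ids) != mat.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(gene_ids)} genes for a {mat.shape[0]}-row matrix"
        )
    if len(cell_ids) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(cell_ids)} barcodes for a "
            f"{mat.shape[1]}-column matrix"
        )
    return CountMatrix(
        counts=mat,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        mito_flag=mito_flags(gene_ids, mito_prefixes),
    )


def write_count_matrix(matrix: CountMatrix, directory) -> Path:
    """Inverse of :func:`read_count_matrix` on valid data."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(d / "matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer"
    )
    (d / "genes.tsv").write_text("".join(g + "\n" for g in matrix.gene_ids))
    (d / "barcodes.tsv").write_text("".join(c + "\n" for c in matrix.cell_ids))
    return d


def write_table(records, path, fmt: str | None = None) -> Path:
    """Write a DataFrame (or record list) as CSV/TSV.

    Header row is always present; floats carry 6 significant digits; row
    order is whatever the caller established (no re-sorting).
    """
    if records is None:
        raise ValueError("records must not be None")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown table format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")
    return path


def read_table(path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    return pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")


def write_signature_json(signature, path) -> Path:
    """Serialize a SignatureSet as {"up": [...], "down": [...], "thresholds": {...}}."""
    payload = {
        "up": list(signature.up_genes),
        "down": list(signature.down_genes),
        "species_a_ids": list(signature.species_a_ids),
        "species_b_ids": list(signature.species_b_ids),
        "thresholds": dict(signature.thresholds),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def read_signature_json(path):
    from .signature import SignatureSet

    payload = json.loads(Path(path).read_text())
    return SignatureSet(
        up_genes=list(payload["up"]),
        down_genes=list(payload["down"]),
        species_a_ids=list(payload.get("species_a_ids", [])),
        species_b_ids=list(payload.get("species_b_ids", [])),
        thresholds=dict(payload.get("thresholds", {})),
    )
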