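"""Dataset-level circRNA filtering, normalization and aggregation.

Filtering follows the whole-dataset rule: a circRNA is kept when its BSJ
reads summed over all cells reach ``min_total`` (default 2), and flagged
high-confidence at ``high_conf_total`` (default 5) supporting reads.

Two normalizations are provided: CPM against a per-cell denominator (by
default the gene library size plus the cell's total BSJ reads, overridable
with externally known mapped-read totals) and size-factor normalization with
library-size factors derived from the gene matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_model import CellAnnotation, CountMatrix

UNITS = ("raw", "cpm", "sf_normalized")


@dataclass
class SizeFactors:
    """Per-cell positive scaling factors with mean exactly 1."""

    cell_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.cell_ids),):
            raise ValueError("size factors / cell ids length mismatch")
        if np.any(self.factors <= 0):
            raise ValueError("size factors must be positive")
        if abs(self.factors.mean() - 1.0) > 1e-12:
            raise ValueError("size factors must average to 1")


@dataclass
class ExpressionMatrix:
    """Non-negative real features x cells matrix with its unit recorded."""

    values: sp.spmatrix | np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    unit: str = "raw"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        shape = self.values.shape
        if shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError("label/shape mismatch in expression matrix")
        mn = self.values.min() if not sp.issparse(self.values) else (
            self.values.data.min() if self.values.nnz else 0.0
        )
        if mn < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_array(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_array(), index=self.feature_ids, columns=self.cell_ids)


def dataset_bsj_filter(
    circ: CountMatrix, min_total: int = 2, high_conf_total: int = 5
) -> tuple[CountMatrix, np.ndarray]:
    """Keep circRNAs with >= ``min_total`` BSJ reads over the whole dataset.

    Returns the filtered matrix and a mask (aligned to it) marking
    high-confidence circRNAs with >= ``high_conf_total`` reads.
    """
    if circ.feature_kind != "circ":
        raise ValueError("dataset_bsj_filter expects a circ count matrix")
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = circ.feature_sums()
    keep = totals >= min_total
    filtered = circ.subset_features(keep)
    high_conf = totals[keep] >= high_conf_total
    return filtered, high_conf


def compute_size_factors(genes: CountMatrix) -> SizeFactors:
    """Library-size factors: per-cell gene total divided by the mean total."""
    lib = genes.cell_sums().astype(float)
    if np.any(lib == 0):
        raise ValueError(
            "zero-library cells present; run QC filtering before size factors"
        )
    return SizeFactors(list(genes.cell_ids), lib / lib.mean())


def cpm_denominators(
    genes: CountMatrix | None,
    circ: CountMatrix | None = None,
    annotations: Sequence[CellAnnotation] | None = None,
) -> pd.Series:
    """Default CPM denominator: gene library size + total BSJ reads per cell.

    Cells with a known ``mapped_reads`` total in their annotation use that
    instead, as the closer analogue of reads "per million mapped".
    """
    if genes is None and circ is None:
        raise ValueError("need at least one count matrix")
    base = genes if genes is not None else circ
    denom = pd.Series(0.0, index=pd.Index(base.cell_ids, name="cell_id"))
    if genes is not None:
        denom += pd.Series(genes.cell_sums().astype(float), index=genes.cell_ids)
    if circ is not None:
        denom = denom.add(
            pd.Series(circ.cell_sums().astype(float), index=circ.cell_ids), fill_value=0.0
        )
    if annotations is not None:
        for a in annotations:
            if a.mapped_reads is not None and a.cell_id in denom.index:
                denom[a.cell_id] = float(a.mapped_reads)
    return denom


def normalize(
    counts: CountMatrix,
    size_factors: SizeFactors | None = None,
    denominators: Mapping[str, float] | pd.Series | None = None,
    mode: str = "cpm",
) -> ExpressionMatrix:
    """Scale raw counts to CPM or size-factor-normalized expression.

    ``mode='cpm'``: value = count / denominator * 1e6, one positive
    denominator per cell.  ``mode='sf'``: value = count / factor.
    """
    if mode == "cpm":
        if denominators is None:
            raise ValueError("mode='cpm' requires per-cell denominators")
        denom = pd.Series(denominators, dtype=float)
        missing = [c for c in counts.cell_ids if c not in denom.index]
        if missing:
            raise ValueError(f"missing CPM denominator for cells {missing[:5]}")
        d = denom.reindex(counts.cell_ids).to_numpy()
        if np.any(d <= 0):
            raise ValueError("CPM denominators must be positive")
        scale = 1e6 / d
        unit = "cpm"
    elif mode == "sf":
        if size_factors is None:
            raise ValueError("mode='sf' requires size factors")
        factor_map = dict(zip(size_factors.cell_ids, size_factors.factors))
        missing = [c for c in counts.cell_ids if c not in factor_map]
        if missing:
            raise ValueError(f"missing size factor for cells {missing[:5]}")
        scale = 1.0 / np.array([factor_map[c] for c in counts.cell_ids])
        unit = "sf_normalized"
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = counts.values.astype(float) @ sp.diags(scale)
    return ExpressionMatrix(
        sp.csr_matrix(values), list(counts.feature_ids), list(counts.cell_ids), unit
    )


def circular_to_linear_ratio(
    circ_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    circ_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """CircRNA expression divided by host-gene expression, cell by cell.

    A zero host value with positive circ value, or 0/0, yields NaN (missing);
    circRNAs without a host-gene mapping are excluded with a warning.
    """
    if circ_expr.unit != gene_expr.unit:
        raise ValueError("circ and gene expression must share a unit")
    if list(circ_expr.cell_ids) != list(gene_expr.cell_ids):
        raise ValueError("circ and gene expression must share cell order")
    gene_frame = gene_expr.to_frame()
    mapped = [
        c
        for c in circ_expr.feature_ids
        if c in circ_to_gene and circ_to_gene[c] in gene_frame.index
    ]
    dropped = set(circ_expr.feature_ids) - set(mapped)
    if dropped:
        warnings.warn(
            f"{len(dropped)} circRNAs without a mapped host gene excluded from ratio",
            stacklevel=2,
        )
    circ_frame = circ_expr.to_frame().loc[mapped]
    host = gene_frame.loc[[circ_to_gene[c] for c in mapped]].to_numpy()
    circ_vals = circ_frame.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(host > 0, circ_vals / np.where(host > 0, host, 1.0), np.nan)
    return pd.DataFrame(ratio, index=mapped, columns=circ_expr.cell_ids)


def pseudobulk_aggregate(
    matrix: CountMatrix | ExpressionMatrix, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Sum expression over the cells of each group (features x groups).

    Every cell must carry a group label; the output has one column per
    distinct label in first-appearance order and conserves the grand total.
    """
    cell_ids = matrix.cell_ids
    unassigned = [c for c in cell_ids if c not in groups]
    if unassigned:
        raise ValueError(f"cells without a group label: {unassigned[:5]}")
    labels: list[str] = []
    for c in cell_ids:
        g = groups[c]
        if g not in labels:
            labels.append(g)
    indicator = sp.csr_matrix(
        (
            np.ones(len(cell_ids)),
            ([labels.index(groups[c]) for c in cell_ids], range(len(cell_ids))),
        ),
        shape=(len(labels), len(cell_ids)),
    )
    values = matrix.values if sp.issparse(matrix.values) else sp.csr_matrix(matrix.values)
    agg = (values @ indicator.T).toarray()
    return pd.DataFrame(agg, index=matrix.feature_ids, columns=labels)
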