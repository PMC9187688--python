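"""Per-cell quality control by MAD (median absolute deviation) outliers.

Cells are summarized by library size, detected-gene count and mitochondrial
read fraction; a cell is removed when any metric is a MAD outlier on the
conventional tail (low library size, few genes, high mito fraction).  The
scale constant 1.4826 makes the MAD a consistent estimator of the standard
deviation under normality, so ``nmads = 3`` corresponds to the usual
3-sigma rule on robustly estimated spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import CountMatrix

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass(frozen=True)
class CellQCMetrics:
    cell_id: str
    library_size: int
    n_features: int
    mito_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_fraction <= 1.0:
            raise ValueError(f"{self.cell_id}: mito_fraction outside [0, 1]")


def compute_qc_metrics(
    genes: CountMatrix, mito_genes: Iterable[str] = ()
) -> list[CellQCMetrics]:
    """Library size, detected genes and mito fraction for every cell.

    Mito gene ids absent from the matrix are ignored with a warning; the mito
    fraction of an all-zero cell is defined as 0 (such cells fall to the
    library-size filter anyway).
    """
    if genes.feature_kind != "gene":
        raise ValueError("compute_qc_metrics expects a gene count matrix")
    mito = set(mito_genes)
    missing = mito - set(genes.feature_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} mito gene ids absent from matrix (ignored)", stacklevel=2
        )
    lib = genes.cell_sums()
    nfeat = genes.cell_nnz()
    mito_idx = [i for i, f in enumerate(genes.feature_ids) if f in mito]
    if mito_idx:
        mito_sum = np.asarray(genes.values[mito_idx, :].sum(axis=0)).ravel()
    else:
        mito_sum = np.zeros(genes.n_cells)
    frac = np.divide(mito_sum, lib, out=np.zeros(genes.n_cells), where=lib > 0)
    return [
        CellQCMetrics(cid, int(lib[j]), int(nfeat[j]), float(frac[j]))
        for j, cid in enumerate(genes.cell_ids)
    ]


def metrics_frame(metrics: Sequence[CellQCMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in metrics],
            "library_size": [m.library_size for m in metrics],
            "n_features": [m.n_features for m in metrics],
            "mito_fraction": [m.mito_fraction for m in metrics],
        }
    ).set_index("cell_id")


def mad_outliers(
    values,
    nmads: float = 3.0,
    tails: str = "both",
    log_transform: bool = False,
) -> np.ndarray:
    """Boolean mask of values beyond ``median +/- nmads * 1.4826 * MAD``.

    With ``log_transform`` the statistic is computed on ``log(x + 1)``.  When
    the MAD is zero the bounds collapse onto the median and only exact ties
    with the median remain inliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_outliers: empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("mad_outliers: values must be finite")
    if nmads <= 0:
        raise ValueError("mad_outliers: nmads must be positive")
    if tails not in ("both", "lower", "upper"):
        raise ValueError(f"mad_outliers: unknown tails {tails!r}")
    if log_transform:
        if np.any(x <= -1):
            raise ValueError("mad_outliers: values must exceed -1 for log transform")
        x = np.log1p(x)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    half_width = nmads * MAD_SCALE * mad
    mask = np.zeros(x.shape, dtype=bool)
    if tails in ("both", "lower"):
        mask |= x < med - half_width
    if tails in ("both", "upper"):
        mask |= x > med + half_width
    return mask


def default_cell_filter(
    genes: CountMatrix,
    mito_genes: Iterable[str] = (),
    nmads: float = 3.0,
) -> pd.DataFrame:
    """QC report with per-criterion outlier flags and a final ``keep`` column.

    Flags cells outlying in log(library_size + 1) (lower tail),
    log(n_features + 1) (lower tail) or mito_fraction (upper tail); the union
    of flags is removed.
    """
    report = metrics_frame(compute_qc_metrics(genes, mito_genes))
    report["low_library_size"] = mad_outliers(
        report["library_size"], nmads=nmads, tails="lower", log_transform=True
    )
    report["low_n_features"] = mad_outliers(
        report["n_features"], nmads=nmads, tails="lower", log_transform=True
    )
    report["high_mito_fraction"] = mad_outliers(
        report["mito_fraction"], nmads=nmads, tails="upper"
    )
    report["keep"] = ~(
        report["low_library_size"]
        | report["low_n_features"]
        | report["high_mito_fraction"]
    )
    return report


def apply_cell_filter(
    matrices: Sequence[CountMatrix], keep
) -> list[CountMatrix]:
    """Subset the same cells jointly out of one or more matrices."""
    keep = np.asarray(keep, dtype=bool)
    out = []
    for m in matrices:
        if keep.shape != (m.n_cells,):
            raise ValueError(
                f"mask length {keep.size} does not match matrix with {m.n_cells} cells"
            )
        out.append(m.subset_cells(keep))
    if not keep.any():
        warnings.warn("cell filter removed every cell", stacklevel=2)
    return out
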