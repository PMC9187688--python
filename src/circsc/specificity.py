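"""Tau specificity, expression-pattern classification and marker detection.

The Tau index summarizes how concentrated a feature's mean expression profile
``x = (x_1 .. x_n)`` over n groups (cell types or tissues) is::

    T = sum_i (1 - x_i / max(x)) / (n - 1)

T = 0 for a perfectly uniform profile and T = 1 when expression is confined
to a single group.  It is computed on linear-scale group means.

Detected circRNAs are classified into five expression patterns by detection
breadth, first matching rule wins:

1. detected in exactly one cell            -> lowly_expressed
2. all detecting cells share one cell type -> cell_type_enriched
3. multiple cell types but one tissue      -> tissue_enriched
4. detected in > 50% of all cells          -> general_enriched
5. otherwise                               -> group_enriched

Markers are found per cell type with a two-sided Wilcoxon rank-sum test
(target cells vs all others), Benjamini-Hochberg adjustment across all
(feature, type) tests, and a fold-change criterion against the best other
cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import CellAnnotation, CountMatrix
from .quantify import ExpressionMatrix

PATTERN_CATEGORIES = (
    "lowly_expressed",
    "cell_type_enriched",
    "tissue_enriched",
    "group_enriched",
    "general_enriched",
)

EXACT_RANKSUM_MAX_N = 25  # combined group size for the exact null distribution


@dataclass(frozen=True)
class MarkerResult:
    feature_id: str
    target_cell_type: str
    p_value: float
    adjusted_p: float
    fold_change: float
    is_marker: bool


def group_mean_profile(
    expr: ExpressionMatrix, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean expression per group (features x groups)."""
    unassigned = [c for c in expr.cell_ids if c not in groups]
    if unassigned:
        raise ValueError(f"cells without a group label: {unassigned[:5]}")
    labels: list[str] = []
    for c in expr.cell_ids:
        if groups[c] not in labels:
            labels.append(groups[c])
    n_cells = len(expr.cell_ids)
    col = [labels.index(groups[c]) for c in expr.cell_ids]
    indicator = sp.csr_matrix(
        (np.ones(n_cells), (range(n_cells), col)), shape=(n_cells, len(labels))
    )
    sizes = np.asarray(indicator.sum(axis=0)).ravel()
    values = expr.values if sp.issparse(expr.values) else sp.csr_matrix(expr.values)
    sums = (values @ indicator).toarray()
    return pd.DataFrame(sums / sizes, index=expr.feature_ids, columns=labels)


def tau_specificity(profile) -> float:
    """Tau of one mean-expression profile over >= 2 groups; NaN if all-zero."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-d profile over at least 2 groups")
    if np.any(x < 0):
        raise ValueError("tau requires non-negative expression values")
    top = x.max()
    if top == 0:
        return float("nan")
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tau_table(profiles: pd.DataFrame) -> pd.Series:
    """Vectorized Tau per feature for a features x groups mean matrix."""
    x = profiles.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("tau requires at least 2 groups")
    if np.any(x < 0):
        raise ValueError("tau requires non-negative expression values")
    top = x.max(axis=1)
    ok = top > 0
    tau = np.full(x.shape[0], np.nan)
    tau[ok] = np.sum(1.0 - x[ok] / top[ok, None], axis=1) / (x.shape[1] - 1)
    return pd.Series(tau, index=profiles.index, name="tau")


def classify_pattern(
    circ: CountMatrix, annotations: Sequence[CellAnnotation]
) -> pd.DataFrame:
    """Five-way expression-pattern category per detected circRNA.

    Every feature must be detected in at least one cell (apply the dataset
    BSJ filter first); categories partition the detected features.
    """
    ann = {a.cell_id: a for a in annotations}
    missing = [c for c in circ.cell_ids if c not in ann]
    if missing:
        raise ValueError(f"cells without annotation: {missing[:5]}")
    types = np.array([ann[c].cell_type for c in circ.cell_ids])
    tissues = np.array([ann[c].tissue for c in circ.cell_ids])
    n_cells = circ.n_cells
    csr = circ.values.tocsr()
    rows = []
    for i, fid in enumerate(circ.feature_ids):
        cols = csr.indices[csr.indptr[i] : csr.indptr[i + 1]]
        n_det = cols.size
        if n_det == 0:
            raise ValueError(
                f"feature {fid!r} detected in no cell; filter undetected features first"
            )
        det_types = set(types[cols])
        det_tissues = set(tissues[cols])
        if n_det == 1:
            cat = "lowly_expressed"
        elif len(det_types) == 1:
            cat = "cell_type_enriched"
        elif len(det_tissues) == 1:
            cat = "tissue_enriched"
        elif n_det > 0.5 * n_cells:
            cat = "general_enriched"
        else:
            cat = "group_enriched"
        rows.append(
            {
                "feature_id": fid,
                "n_cells_detected": int(n_det),
                "n_cell_types": len(det_types),
                "n_tissues": len(det_tissues),
                "category": cat,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def specificity_table(
    circ: CountMatrix,
    annotations: Sequence[CellAnnotation],
    expr: ExpressionMatrix | None = None,
    group_by: str = "cell_type",
) -> pd.DataFrame:
    """Detection-pattern categories joined with Tau over cell-type means."""
    table = classify_pattern(circ, annotations)
    if expr is not None:
        groups = {a.cell_id: getattr(a, group_by) for a in annotations}
        profiles = group_mean_profile(expr, groups)
        table = table.join(tau_table(profiles))
    return table


def _ranksum_pvalues(target: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per feature row; exact for small tie-free groups."""
    n1, n2 = target.shape[1], rest.shape[1]
    n_features = target.shape[0]
    pvals = np.ones(n_features)
    all_tied = np.all(
        np.concatenate([target, rest], axis=1)
        == np.concatenate([target, rest], axis=1)[:, :1],
        axis=1,
    )
    live = ~all_tied
    if not live.any():
        return pvals
    method = "exact" if n1 + n2 <= EXACT_RANKSUM_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(
        target[live], rest[live], alternative="two-sided", method=method, axis=1
    )
    pvals[live] = np.nan_to_num(np.minimum(np.atleast_1d(res.pvalue), 1.0), nan=1.0)
    return pvals


def find_markers(
    expr: ExpressionMatrix,
    cell_types: Mapping[str, str],
    min_fold: float = 3.0,
    alpha: float = 0.05,
    epsilon: float = 0.01,
) -> list[MarkerResult]:
    """One-vs-rest rank-sum marker test for every (feature, cell type) pair.

    ``fold_change`` compares the target cell-type mean with the best other
    type's mean, both shifted by the ``epsilon`` pseudocount; ``is_marker``
    requires BH-adjusted p < ``alpha`` and fold_change >= ``min_fold``.
    """
    labels = pd.Series({c: cell_types[c] for c in expr.cell_ids})
    types = list(dict.fromkeys(labels[c] for c in expr.cell_ids))
    if len(types) < 2:
        raise ValueError("marker detection requires at least 2 cell types")
    X = expr.to_array()
    type_means = group_mean_profile(expr, dict(labels)).to_numpy()
    results: list[dict] = []
    for t_idx, t in enumerate(types):
        in_type = (labels.reindex(expr.cell_ids) == t).to_numpy()
        pvals = _ranksum_pvalues(X[:, in_type], X[:, ~in_type])
        others = np.delete(type_means, t_idx, axis=1)
        fold = (type_means[:, t_idx] + epsilon) / (others.max(axis=1) + epsilon)
        for i, fid in enumerate(expr.feature_ids):
            results.append(
                {
                    "feature_id": fid,
                    "target_cell_type": t,
                    "p_value": float(pvals[i]),
                    "fold_change": float(fold[i]),
                }
            )
    frame = pd.DataFrame(results)
    _, adj, _, _ = multipletests(frame["p_value"], method="fdr_bh")
    frame["adjusted_p"] = adj
    frame["is_marker"] = (frame["adjusted_p"] < alpha) & (frame["fold_change"] >= min_fold)
    return [
        MarkerResult(
            r.feature_id,
            r.target_cell_type,
            r.p_value,
            r.adjusted_p,
            r.fold_change,
            bool(r.is_marker),
        )
        for r in frame.itertuples(index=False)
    ]


def markers_frame(markers: Sequence[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [m.feature_id for m in markers],
            "cell_type": [m.target_cell_type for m in markers],
            "p_value": [m.p_value for m in markers],
            "adjusted_p": [m.adjusted_p for m in markers],
            "fold_change": [m.fold_change for m in markers],
            "is_marker": [m.is_marker for m in markers],
        }
    )


def feature_correlation(x, y, method: str = "pearson") -> np.ndarray:
    """Row-wise correlation between paired expression vectors.

    ``x`` and ``y`` are arrays/DataFrames of shape (n_pairs, n_observations)
    over the same cells or stages; rows with zero variance give NaN with a
    warning.  Spearman uses average ranks for ties.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError("paired inputs must share shape")
    if X.shape[1] < 3:
        raise ValueError("correlation requires vectors of length >= 3")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    bad = (sx == 0) | (sy == 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance vectors yield missing correlations",
            stacklevel=2,
        )
    denom = np.where(bad, 1.0, sx * sy)
    r = np.where(bad, np.nan, (Xc * Yc).sum(axis=1) / denom)
    return r if np.asarray(x).ndim > 1 else float(r[0])
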