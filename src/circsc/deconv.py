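"""Cell-composition deconvolution from circRNA signature matrices.

A signature matrix S (marker features x cell types, mean CPM per type) is
built from annotated single cells under two criteria: the feature is
detected in at least two cell types, and it is a significant marker
(rank-sum BH-adjusted p below alpha with >= ``min_fold`` higher expression)
of exactly one cell type.  Cell-type fractions f in a bulk profile b are
estimated by non-negative least squares::

    minimize ||S f - b||^2  subject to  f >= 0,

renormalized to sum to one; a nu-support-vector-regression mode (linear
kernel, nu in {0.25, 0.5, 0.75}, best by reconstruction RMSE) is provided
for fidelity to signature-based immune deconvolution tools.  Fit quality is
the RMSE between the standardized reconstruction S f and the standardized
bulk profile, plus the Pearson correlation on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .quantify import ExpressionMatrix
from .specificity import MarkerResult, group_mean_profile

DEFAULT_IMMUNE_TYPES = (
    "macrophages",
    "monocytes",
    "T cells",
    "mast cells",
    "dendritic cells",
    "B-cell",
    "NK cells",
    "neutrophils",
    "eosinophils",
    "plasma cells",
)

SVR_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class SignatureMatrix:
    """Marker features x cell types mean-expression reference."""

    values: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate features in signature")
        if (self.values.to_numpy().sum(axis=1) == 0).any():
            raise ValueError("all-zero feature rows in signature")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class MixtureResult:
    sample_id: str
    fractions: pd.Series
    rmse: float
    pearson_r: float

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")


def build_signature(
    expr: ExpressionMatrix,
    cell_types: Mapping[str, str],
    markers: Sequence[MarkerResult],
    min_types_detected: int = 2,
    min_fold: float = 3.0,
) -> SignatureMatrix:
    """Filter markers into a deconvolution signature.

    Retains features (1) detected in >= ``min_types_detected`` cell types and
    (2) flagged as a marker with fold change >= ``min_fold`` for exactly one
    cell type; features claimed by multiple types are ambiguous and dropped.
    """
    profiles = group_mean_profile(expr, dict(cell_types))
    detection = group_mean_profile(
        ExpressionMatrix(
            (expr.values > 0).astype(float), expr.feature_ids, expr.cell_ids, expr.unit
        ),
        dict(cell_types),
    )
    n_types_detected = (detection > 0).sum(axis=1)
    marker_types: dict[str, list[str]] = {}
    for m in markers:
        if m.is_marker and m.fold_change >= min_fold:
            marker_types.setdefault(m.feature_id, []).append(m.target_cell_type)
    keep = [
        f
        for f in profiles.index
        if n_types_detected.get(f, 0) >= min_types_detected
        and len(marker_types.get(f, [])) == 1
    ]
    values = profiles.loc[keep]
    values = values.loc[values.sum(axis=1) > 0]
    if values.shape[0] < values.shape[1]:
        raise ValueError(
            f"signature with {values.shape[0]} features over {values.shape[1]} cell "
            "types is unidentifiable"
        )
    return SignatureMatrix(
        values,
        provenance={
            "min_types_detected": min_types_detected,
            "min_fold": min_fold,
            "n_candidate_markers": len(marker_types),
        },
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    # population sd; a constant vector is left unchanged (degenerate convention)
    sd = v.std()
    if sd == 0:
        return v.copy()
    return (v - v.mean()) / sd


def evaluate_fit(
    signature: SignatureMatrix | pd.DataFrame, fractions, bulk
) -> tuple[float, float]:
    """Reconstruction RMSE (standardized scale) and raw-scale Pearson r."""
    S = signature.values if isinstance(signature, SignatureMatrix) else signature
    f = np.asarray(pd.Series(fractions).reindex(S.columns), dtype=float)
    b = np.asarray(pd.Series(bulk).reindex(S.index), dtype=float)
    yhat = S.to_numpy() @ f
    rmse = float(np.sqrt(np.mean((_standardize(yhat) - _standardize(b)) ** 2)))
    if b.std() == 0 or yhat.std() == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(stats.pearsonr(yhat, b)[0])
    return rmse, r


def _solve_nnls(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    f, _ = nnls(S, b)
    total = f.sum()
    if total == 0:
        warnings.warn("NNLS returned the zero vector; falling back to uniform fractions")
        return np.full(S.shape[1], 1.0 / S.shape[1])
    return f / total


def _solve_svr(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    from sklearn.svm import NuSVR

    # z-score features jointly, as signature-based SVR deconvolution does;
    # the linear-kernel coefficients are then proportional to the fractions
    Sz = (S - S.mean()) / S.std()
    bz = (b - b.mean()) / b.std() if b.std() > 0 else b - b.mean()
    best: np.ndarray | None = None
    best_rmse = np.inf
    for nu in SVR_NU_GRID:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(Sz, bz)
        coef = np.clip(model.coef_.ravel(), 0.0, None)
        if coef.sum() == 0:
            continue
        f = coef / coef.sum()
        rmse = float(
            np.sqrt(np.mean((_standardize(S @ f) - _standardize(b)) ** 2))
        )
        if rmse < best_rmse:
            best_rmse, best = rmse, f
    if best is None:
        warnings.warn("nu-SVR produced no usable solution; falling back to NNLS")
        return _solve_nnls(S, b)
    return best


def deconvolve(
    signature: SignatureMatrix,
    bulk: pd.DataFrame | pd.Series,
    method: str = "nnls",
) -> list[MixtureResult]:
    """Estimate cell-type fractions for each bulk sample.

    ``bulk`` is a features x samples frame (or a single series); it is
    restricted to the signature's features, with absent features imputed as
    zero (warned).  The result carries renormalized fractions plus the
    standardized-RMSE and Pearson-r fit statistics per sample.
    """
    if method not in ("nnls", "svr"):
        raise ValueError(f"unknown deconvolution method {method!r}")
    frame = bulk.to_frame() if isinstance(bulk, pd.Series) else bulk
    S = signature.values
    missing = S.index.difference(frame.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} signature features absent from bulk; imputed as 0",
            stacklevel=2,
        )
    aligned = frame.reindex(S.index).fillna(0.0)
    Sm = S.to_numpy(dtype=float)
    results = []
    for sample in aligned.columns:
        b = aligned[sample].to_numpy(dtype=float)
        if not b.any():
            raise ValueError(f"bulk sample {sample!r} is all zero")
        f = _solve_nnls(Sm, b) if method == "nnls" else _solve_svr(Sm, b)
        fractions = pd.Series(f, index=S.columns, name=sample)
        rmse, r = evaluate_fit(signature, fractions, aligned[sample])
        results.append(MixtureResult(str(sample), fractions, rmse, r))
    return results


def mixtures_frame(results: Sequence[MixtureResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for cell_type, frac in res.fractions.items():
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "cell_type": cell_type,
                    "fraction": frac,
                    "rmse": res.rmse,
                    "pearson_r": res.pearson_r,
                }
            )
    return pd.DataFrame(rows)


def aggregate_types(fractions, mapping: Mapping[str, str]) -> pd.Series:
    """Sum fine-grained fractions into coarse cell types (total preserved)."""
    f = pd.Series(fractions, dtype=float)
    unmapped = [t for t in f.index if t not in mapping]
    if unmapped:
        raise ValueError(f"fine cell types without a coarse mapping: {unmapped}")
    coarse = f.groupby(f.index.map(mapping)).sum()
    return coarse
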