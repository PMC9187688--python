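"""Temporal expression dynamics across the maternal-to-zygotic transition.

Embryo cells are grouped into four ordered time points — totipotent
blastomeres (TB), first lineage (TE/ICM), second lineage (EPI/PE) and the
implanted embryo — and each feature's mean profile over those points is
row-standardized and soft-clustered with fuzzy c-means (c = 5 by default,
fuzzifier m = 1.25).  Clusters whose centroid peaks at the first time point
and ends below its start are labeled maternal; the rest zygotic.  Stage
read composition then attributes each stage's BSJ reads to maternal vs
zygotic features.

The fuzzy c-means updates are the classical alternating optimization:

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1))        (memberships)
    v_j  = sum_i u_ij^m x_i / sum_i u_ij^m           (centroids)

with squared Euclidean distances d^2; the objective sum_ij u_ij^m d_ij^2 is
non-increasing across iterations.  A feature exactly coincident with a
centroid receives crisp membership in that cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io_model import CountMatrix
from .quantify import ExpressionMatrix

DEFAULT_STAGES = ("TB", "TE/ICM", "EPI/PE", "implanted")


@dataclass
class StageProfileMatrix:
    """Mean expression per ordered time point (features x stages)."""

    values: pd.DataFrame
    stage_order: list[str]

    def __post_init__(self) -> None:
        self.stage_order = list(self.stage_order)
        if len(self.stage_order) < 2:
            raise ValueError("need at least 2 time points")
        if list(self.values.columns) != self.stage_order:
            self.values = self.values.loc[:, self.stage_order]


@dataclass
class FuzzyClusters:
    """Soft clustering result: memberships sum to 1 per feature."""

    memberships: pd.DataFrame  # features x clusters (columns 1..c)
    centroids: pd.DataFrame  # clusters x time points
    m: float
    objective_path: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        rows = self.memberships.to_numpy().sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def c(self) -> int:
        return self.memberships.shape[1]

    def hard_assignments(self) -> pd.Series:
        """Argmax cluster per feature; ties break to the lowest cluster index."""
        idx = np.argmax(self.memberships.to_numpy(), axis=1)
        clusters = np.asarray(self.memberships.columns)[idx]
        return pd.Series(clusters, index=self.memberships.index, name="cluster")


def stage_profiles(
    expr: ExpressionMatrix,
    stages: Mapping[str, str],
    stage_order: Sequence[str] = DEFAULT_STAGES,
    min_stages_detected: int = 2,
) -> StageProfileMatrix:
    """Per-feature mean expression per stage, dropping sporadic features.

    Features detected (mean > 0) in fewer than ``min_stages_detected`` stages
    are removed, damping one-off detections before clustering.
    """
    stage_order = list(stage_order)
    unknown = sorted({s for s in (stages[c] for c in expr.cell_ids) if s not in stage_order})
    if unknown:
        raise ValueError(f"unknown stage labels: {unknown}")
    frame = expr.to_frame()
    stage_of = pd.Series({c: stages[c] for c in expr.cell_ids})
    means = frame.T.groupby(stage_of).mean().T.reindex(columns=stage_order)
    if means.isna().any().any():
        empty = [s for s in stage_order if means[s].isna().all()]
        raise ValueError(f"stages with no cells: {empty}")
    detected = (means > 0).sum(axis=1)
    return StageProfileMatrix(means.loc[detected >= min_stages_detected], stage_order)


def standardize_rows(profiles: StageProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Transform each row to mean 0, sample standard deviation 1.

    Constant rows cannot be standardized and are removed with a warning.
    """
    frame = profiles.values if isinstance(profiles, StageProfileMatrix) else profiles
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant rows removed before standardization",
            stacklevel=2,
        )
    keep = ~constant
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=frame.index[keep], columns=frame.columns)


def fuzzy_cmeans(
    data: pd.DataFrame | np.ndarray,
    c: int = 5,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> FuzzyClusters:
    """Fuzzy c-means on row-standardized profiles.

    Memberships initialize from a symmetric Dirichlet(1) draw (seeded);
    iteration stops when the maximum centroid displacement falls below
    ``tol`` or after ``max_iter`` rounds.
    """
    frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= c <= n features, got c={c}, n={n}")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(c), size=n)
    V = np.zeros((c, X.shape[1]))
    objective: list[float] = []
    n_iter = 0
    exponent = 1.0 / (m - 1.0)
    for n_iter in range(1, max_iter + 1):
        W = U**m
        weights = W.sum(axis=0)
        # an (almost) empty cluster keeps its previous centroid
        V_new = np.where(
            weights[:, None] > 0, (W.T @ X) / np.maximum(weights, 1e-300)[:, None], V
        )
        shift = np.abs(V_new - V).max() if n_iter > 1 else np.inf
        V = V_new
        D2 = cdist(X, V, metric="sqeuclidean")
        # d below 1e-6 counts as coincident; avoids overflow in D2**-1/(m-1)
        coincident = D2 <= 1e-12
        with np.errstate(divide="ignore"):
            inv = np.where(coincident, 1.0, D2) ** -exponent
            inv[coincident] = 0.0
        U = np.where(
            coincident.any(axis=1, keepdims=True),
            coincident / np.maximum(coincident.sum(axis=1, keepdims=True), 1),
            inv / np.where(inv.sum(axis=1, keepdims=True) == 0, 1, inv.sum(axis=1, keepdims=True)),
        )
        objective.append(float(((U**m) * D2).sum()))
        if shift < tol:
            break
    cluster_ids = list(range(1, c + 1))
    return FuzzyClusters(
        memberships=pd.DataFrame(U, index=frame.index, columns=cluster_ids),
        centroids=pd.DataFrame(V, index=cluster_ids, columns=frame.columns),
        m=m,
        objective_path=np.asarray(objective),
        n_iter=n_iter,
    )


def label_maternal_zygotic(
    clusters: FuzzyClusters, override: Mapping[int, str] | None = None
) -> dict[int, str]:
    """Maternal iff the centroid peaks at the first time point and decays.

    A cluster is maternal when its centroid attains its maximum at the first
    ordered time point and its final value lies below its first; otherwise
    zygotic.  ``override`` replaces individual automatic labels (the mapping
    mirrors a by-eye assignment of cluster trajectories).
    """
    labels: dict[int, str] = {}
    V = clusters.centroids.to_numpy()
    for k, cid in enumerate(clusters.centroids.index):
        maternal = int(np.argmax(V[k])) == 0 and V[k, -1] < V[k, 0]
        labels[cid] = "maternal" if maternal else "zygotic"
    if override:
        for cid, lab in override.items():
            if lab not in ("maternal", "zygotic"):
                raise ValueError(f"label must be maternal or zygotic, got {lab!r}")
            labels[cid] = lab
    clusters.labels = labels
    return labels


def stage_composition(
    counts: CountMatrix | pd.DataFrame,
    clusters: FuzzyClusters,
    stages: Mapping[str, str] | None = None,
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-stage fraction of BSJ reads from maternal vs zygotic features.

    ``counts`` columns are cells or stage pseudobulks; ``stages`` maps each
    column to its stage (identity if omitted).  Fractions sum to 1 per stage
    among labeled features; a stage with zero labeled reads reports NaN.
    """
    if clusters.labels is None:
        raise ValueError("label clusters first (label_maternal_zygotic)")
    frame = counts.to_frame() if isinstance(counts, CountMatrix) else counts
    feat_label = clusters.hard_assignments().map(clusters.labels)
    common = frame.index.intersection(feat_label.index)
    frame = frame.loc[common]
    feat_label = feat_label.loc[common]
    if stages is None:
        stages = {c: c for c in frame.columns}
    col_stage = pd.Series({c: stages[c] for c in frame.columns})
    if stage_order is None:
        stage_order = list(dict.fromkeys(col_stage))
    totals = frame.groupby(feat_label).sum().T.groupby(col_stage).sum()
    totals = totals.reindex(index=stage_order, columns=["maternal", "zygotic"], fill_value=0.0)
    grand = totals.sum(axis=1)
    if (grand == 0).any():
        warnings.warn("stages with zero labeled reads report missing fractions", stacklevel=2)
    frac = totals.div(grand.where(grand > 0), axis=0)
    frac.index.name = "stage"
    return frac


def stage_correlation(profiles: StageProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between stage columns over features."""
    frame = profiles.values if isinstance(profiles, StageProfileMatrix) else profiles
    if frame.shape[0] < 2:
        raise ValueError("stage correlation requires >= 2 features")
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance stage columns yield missing correlations", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[np.ix_(sd == 0, np.ones(len(sd), dtype=bool))] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=frame.columns, columns=frame.columns)


def cluster_concordance(a: Mapping[str, object], b: Mapping[str, object]) -> pd.DataFrame:
    """Contingency table of two hard clusterings over their shared features."""
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("clusterings share no features")
    sa = pd.Series({f: a[f] for f in shared}, name="a")
    sb = pd.Series({f: b[f] for f in shared}, name="b")
    return pd.crosstab(sa, sb)
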