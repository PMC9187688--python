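"""Seeded generators for synthetic single-cell circRNA data.

These generators emulate the statistical structure the downstream analysis
assumes: sparse, low-count BSJ matrices in which most circRNAs appear in few
cells; planted expression-pattern categories (one cell / one cell type / one
tissue / majority of cells / multi-type residual); gene counts correlated
with host-circRNA activity; four-stage embryo time courses with maternal
decay and zygotic activation; and pseudo-bulk mixtures with known cell-type
fractions.  Every generator is a pure function of its parameters and seed
(independent named substreams per matrix), and returns ground-truth tables
for every planted parameter.

Per-cell BSJ counts are Poisson by default: observed single-cell BSJ counts
are near-binary, leaving negative-binomial overdispersion unidentifiable; an
NB option exists for the gene matrix, where depth and burstiness are real.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dynamics import DEFAULT_STAGES, StageProfileMatrix
from .io_model import CellAnnotation, CountMatrix

PATTERN_CATEGORIES = (
    "lowly_expressed",
    "cell_type_enriched",
    "tissue_enriched",
    "group_enriched",
    "general_enriched",
)

# (cell type, tissue, proportion) of the simulated population
DEFAULT_CELL_TYPE_SPEC = (
    ("T cells", "blood", 0.20),
    ("B-cell", "blood", 0.15),
    ("NK cells", "blood", 0.10),
    ("GABAergic neurons", "brain", 0.20),
    ("microglia", "brain", 0.15),
    ("hepatocytes", "liver", 0.20),
)

# Mixture over the five detection-pattern categories: most circRNAs are
# sporadic single-cell detections, a large minority confined to one cell
# type, a housekeeping-like tail detected in most cells.
DEFAULT_CATEGORY_MIX = {
    "lowly_expressed": 0.35,
    "cell_type_enriched": 0.20,
    "tissue_enriched": 0.10,
    "group_enriched": 0.15,
    "general_enriched": 0.20,
}

# Five temporal archetypes over the four MZT time points (raw expression
# units before depth scaling): two maternal decay shapes and three zygotic
# activation shapes peaking at successive time points.
DEFAULT_ARCHETYPES = (
    ("maternal_sharp", (10.0, 1.0, 1.0, 1.0), "maternal"),
    ("maternal_slow", (8.0, 7.0, 5.0, 1.0), "maternal"),
    ("zygotic_first_lineage", (1.0, 10.0, 2.0, 1.0), "zygotic"),
    ("zygotic_second_lineage", (1.0, 2.0, 10.0, 3.0), "zygotic"),
    ("zygotic_implanted", (1.0, 1.0, 2.0, 10.0), "zygotic"),
)


@dataclass
class SimulationTruth:
    """Ground truth for every planted feature, cell, cluster and mixture."""

    seed: int
    circ_truth: pd.DataFrame | None = None
    cell_truth: pd.DataFrame | None = None
    archetype_truth: pd.DataFrame | None = None
    mixture_truth: pd.DataFrame | None = None


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` items matching ``proportions``."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def simulate_cell_population(
    n_cells: int = 5000,
    cell_type_spec: Sequence[tuple[str, str, float]] = DEFAULT_CELL_TYPE_SPEC,
    n_genes: int = 2000,
    n_circ: int = 2000,
    category_mix: Mapping[str, float] = DEFAULT_CATEGORY_MIX,
    mean_bsj: float = 0.5,
    marker_fold: float = 6.0,
    gene_mean: float = 5.0,
    gene_dispersion: float = 0.5,
    host_boost: float = 5.0,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix, list[CellAnnotation], SimulationTruth]:
    """Simulate a cell population with planted circRNA expression patterns.

    Gene counts are negative binomial with type-specific means; host genes
    gain rate proportional to their circRNA's activity.  Circ BSJ counts are
    Poisson with rate ``mean_bsj`` on the category's detection mask:
    ``lowly_expressed`` plants 1 + Poisson reads in a single cell;
    ``cell_type_enriched`` one cell type; ``tissue_enriched`` one tissue;
    ``general_enriched`` all cells at a rate giving ~70% detection;
    ``group_enriched`` two cell types in different tissues, with a
    ``marker_fold``-times higher rate in the first — these are the
    signature-grade circRNAs: detected in multiple cell types yet clearly
    enriched in one.
    """
    props = np.array([p for _, _, p in cell_type_spec], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("cell type proportions must sum to 1")
    mix = {k: category_mix.get(k, 0.0) for k in PATTERN_CATEGORIES}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("category proportions must sum to 1")
    if mean_bsj <= 0:
        raise ValueError("mean_bsj must be positive")
    rng_cells, rng_assign, rng_circ, rng_genes = _substreams(seed, 4)

    # --- cells
    type_names = [t for t, _, _ in cell_type_spec]
    tissue_of = {t: tis for t, tis, _ in cell_type_spec}
    counts_per_type = _largest_remainder(props, n_cells)
    type_idx = np.repeat(np.arange(len(type_names)), counts_per_type)
    rng_cells.shuffle(type_idx)
    cell_ids = [f"cell{j:05d}" for j in range(n_cells)]
    annotations = [
        CellAnnotation(
            cell_id=cell_ids[j],
            study_id="sim_study",
            tissue=tissue_of[type_names[type_idx[j]]],
            cell_type=type_names[type_idx[j]],
            tumor_status="normal",
        )
        for j in range(n_cells)
    ]
    cells_of_type = {
        t: np.flatnonzero(type_idx == k) for k, t in enumerate(type_names)
    }
    cells_of_tissue: dict[str, np.ndarray] = {}
    for t, tis in tissue_of.items():
        cells_of_tissue.setdefault(tis, np.array([], dtype=int))
        cells_of_tissue[tis] = np.concatenate([cells_of_tissue[tis], cells_of_type[t]])
    multi_type_tissues = [
        tis for tis in cells_of_tissue if sum(tissue_of[t] == tis for t in type_names) >= 2
    ]

    # --- circRNAs
    circ_ids = [f"circ{i:05d}" for i in range(n_circ)]
    cat_counts = _largest_remainder(
        np.array([mix[c] for c in PATTERN_CATEGORIES]), n_circ
    )
    categories = np.repeat(PATTERN_CATEGORIES, cat_counts)
    rng_assign.shuffle(categories)
    general_rate = -np.log(0.3)  # ~70% per-cell detection probability
    rows, cols, vals = [], [], []
    circ_rates = np.zeros((n_circ, n_cells))  # per-cell rate, reused for host genes
    targets: list[str] = []
    marker_types: list[str] = []
    for i in range(n_circ):
        cat = categories[i]
        if cat == "lowly_expressed":
            j = int(rng_assign.integers(n_cells))
            member = np.array([j])
            draws = np.array([1 + rng_circ.poisson(mean_bsj)])
            targets.append(cell_ids[j])
            marker_types.append("")
            circ_rates[i, j] = mean_bsj
        else:
            if cat == "cell_type_enriched":
                t = type_names[int(rng_assign.integers(len(type_names)))]
                member = cells_of_type[t]
                rate = mean_bsj
                targets.append(t)
                marker_types.append("")
            elif cat == "tissue_enriched":
                tis = multi_type_tissues[int(rng_assign.integers(len(multi_type_tissues)))]
                member = cells_of_tissue[tis]
                rate = mean_bsj
                targets.append(tis)
                marker_types.append("")
            elif cat == "general_enriched":
                member = np.arange(n_cells)
                rate = general_rate
                targets.append("all")
                marker_types.append("")
            else:  # group_enriched: strong in one type, weak in a second tissue's type
                tissues = list(cells_of_tissue)
                t1_tis, t2_tis = rng_assign.choice(len(tissues), size=2, replace=False)
                def pick(tis):
                    members = [t for t in type_names if tissue_of[t] == tis]
                    return members[int(rng_assign.integers(len(members)))]
                t1 = pick(tissues[t1_tis])
                t2 = pick(tissues[t2_tis])
                member = np.concatenate([cells_of_type[t1], cells_of_type[t2]])
                rate = np.concatenate(
                    [
                        np.full(cells_of_type[t1].size, marker_fold * mean_bsj),
                        np.full(cells_of_type[t2].size, mean_bsj),
                    ]
                )
                targets.append(f"{t1}|{t2}")
                marker_types.append(t1)
            draws = rng_circ.poisson(rate, size=member.size)
            circ_rates[i, member] = rate
        nz = draws > 0
        rows.extend([i] * int(nz.sum()))
        cols.extend(member[nz].tolist())
        vals.extend(draws[nz].tolist())
    circ_matrix = CountMatrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n_circ, n_cells), dtype=np.int64).tocsr(),
        circ_ids,
        cell_ids,
        feature_kind="circ",
    )

    # --- genes (NB with type effects; host genes track their circ's rate)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    base = rng_genes.lognormal(mean=np.log(gene_mean), sigma=0.6, size=n_genes)
    type_effect = rng_genes.lognormal(mean=0.0, sigma=0.4, size=(n_genes, len(type_names)))
    means = base[:, None] * type_effect[:, type_idx]
    host_of = rng_assign.choice(
        n_genes, size=n_circ, replace=n_circ > n_genes
    )
    for i in range(n_circ):
        means[host_of[i]] += host_boost * circ_rates[i]
    r = 1.0 / gene_dispersion
    p = r / (r + means)
    gene_counts = rng_genes.negative_binomial(r, p)
    gene_matrix = CountMatrix(
        sp.csr_matrix(gene_counts.astype(np.int64)), gene_ids, cell_ids, feature_kind="gene"
    )

    truth = SimulationTruth(
        seed=seed,
        circ_truth=pd.DataFrame(
            {
                "circ_id": circ_ids,
                "category": categories,
                "host_gene": [gene_ids[h] for h in host_of],
                "target": targets,
                "marker_type": marker_types,
                "planted_fold": [
                    marker_fold if c == "group_enriched" else np.nan for c in categories
                ],
                "planted_rate": [
                    general_rate if c == "general_enriched" else mean_bsj
                    for c in categories
                ],
            }
        ).set_index("circ_id"),
        cell_truth=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cell_type": [type_names[k] for k in type_idx],
                "tissue": [tissue_of[type_names[k]] for k in type_idx],
            }
        ).set_index("cell_id"),
    )
    return gene_matrix, circ_matrix, annotations, truth


def simulate_embryo_time_course(
    n_features: int = 1000,
    time_points: Sequence[str] = DEFAULT_STAGES,
    archetypes: Sequence[tuple[str, Sequence[float], str]] = DEFAULT_ARCHETYPES,
    noise_sd: float = 0.5,
    depth: float = 10.0,
    seed: int = 0,
) -> tuple[StageProfileMatrix, SimulationTruth]:
    """Stage-level BSJ counts following maternal/zygotic temporal archetypes.

    Each feature draws an archetype uniformly; its stage means are
    ``depth * max(archetype + N(0, noise_sd), 0.05)`` and counts are Poisson
    around those means.  At least one decreasing (maternal) archetype is
    required.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if len(archetypes) < 2 or not any(lab == "maternal" for _, _, lab in archetypes):
        raise ValueError("need >= 2 archetypes including a maternal (decreasing) one")
    time_points = list(time_points)
    shapes = np.array([list(v) for _, v, _ in archetypes], dtype=float)
    if shapes.shape[1] != len(time_points):
        raise ValueError("archetype length must match the number of time points")
    rng_assign, rng_noise = _substreams(seed, 2)
    assignment = rng_assign.integers(len(archetypes), size=n_features)
    means = depth * np.clip(
        shapes[assignment] + rng_noise.normal(0.0, noise_sd, size=(n_features, len(time_points))),
        0.05,
        None,
    )
    counts = rng_noise.poisson(means)
    feature_ids = [f"feat{i:05d}" for i in range(n_features)]
    profile = StageProfileMatrix(
        pd.DataFrame(counts.astype(float), index=feature_ids, columns=time_points),
        time_points,
    )
    truth = SimulationTruth(
        seed=seed,
        archetype_truth=pd.DataFrame(
            {
                "feature_id": feature_ids,
                "archetype": [archetypes[a][0] for a in assignment],
                "label": [archetypes[a][2] for a in assignment],
            }
        ).set_index("feature_id"),
    )
    return profile, truth


def simulate_archetype_profiles(
    archetypes: Sequence[tuple[str, Sequence[float], str]] = DEFAULT_ARCHETYPES,
    n_per_archetype: int = 200,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Row-standardized archetype profiles plus Gaussian noise.

    Convenience surface for clustering benchmarks: each archetype shape is
    standardized to mean 0 / sd 1 and replicated with additive noise on that
    standardized scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    shapes = np.array([list(v) for _, v, _ in archetypes], dtype=float)
    z = (shapes - shapes.mean(axis=1, keepdims=True)) / shapes.std(axis=1, ddof=1, keepdims=True)
    n_arch, n_tp = z.shape
    assignment = np.repeat(np.arange(n_arch), n_per_archetype)
    data = z[assignment] + rng.normal(0.0, noise_sd, size=(assignment.size, n_tp))
    feature_ids = [f"feat{i:05d}" for i in range(assignment.size)]
    frame = pd.DataFrame(data, index=feature_ids, columns=[f"t{j}" for j in range(n_tp)])
    truth = SimulationTruth(
        seed=seed,
        archetype_truth=pd.DataFrame(
            {
                "feature_id": feature_ids,
                "archetype": [archetypes[a][0] for a in assignment],
                "label": [archetypes[a][2] for a in assignment],
            }
        ).set_index("feature_id"),
    )
    return frame, truth


def simulate_marker_profiles(
    cell_types: Sequence[str],
    n_markers_per_type: int = 20,
    marker_expr: float = 10.0,
    background_expr: float = 0.5,
    prefix: str = "circ",
) -> pd.DataFrame:
    """Deterministic per-type mean profiles with one marker block per type.

    The ratio ``marker_expr / background_expr`` controls both the planted
    fold change and Tau: near-zero background gives Tau near 1 (circRNA-like
    markers), a high background gives low Tau (gene-like markers).
    """
    if marker_expr <= background_expr:
        raise ValueError("marker_expr must exceed background_expr")
    n_types = len(cell_types)
    values = np.full((n_types * n_markers_per_type, n_types), background_expr)
    for k in range(n_types):
        values[k * n_markers_per_type : (k + 1) * n_markers_per_type, k] = marker_expr
    index = [
        f"{prefix}_{cell_types[k].replace(' ', '_')}_{i:03d}"
        for k in range(n_types)
        for i in range(n_markers_per_type)
    ]
    return pd.DataFrame(values, index=index, columns=list(cell_types))


def simulate_bulk_mixtures(
    signature_truth: pd.DataFrame,
    n_samples: int = 50,
    dirichlet_alpha: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk profiles mixed from per-type means with known fractions.

    Fractions draw from a symmetric Dirichlet; each bulk entry is the
    fraction-weighted profile value times multiplicative lognormal noise
    (sigma = ``noise_sd`` on the log scale).  Returns (bulk features x
    samples, true fractions samples x types).
    """
    if signature_truth.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if dirichlet_alpha <= 0:
        raise ValueError("dirichlet_alpha must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_types = signature_truth.shape[1]
    fractions = rng.dirichlet(np.full(n_types, dirichlet_alpha), size=n_samples)
    clean = signature_truth.to_numpy() @ fractions.T
    if noise_sd > 0:
        clean = clean * rng.lognormal(0.0, noise_sd, size=clean.shape)
    sample_ids = [f"sample{s:03d}" for s in range(n_samples)]
    bulk = pd.DataFrame(clean, index=signature_truth.index, columns=sample_ids)
    truth = pd.DataFrame(fractions, index=sample_ids, columns=signature_truth.columns)
    return bulk, truth
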