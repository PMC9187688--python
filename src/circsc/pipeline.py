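"""Configuration-driven orchestration of the analysis stages.

Stage order mirrors the analysis flow: (simulate or load) -> cell QC ->
circRNA filtering and normalization -> specificity/markers -> embryo
dynamics -> deconvolution.  Every stage writes its TSV outputs before the
next starts, and a JSON manifest records versions, the effective config,
the seed and per-stage dimensions, so a run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy

from . import __version__, deconv, dynamics, qc, quantify, specificity, synthetic
from .config import load_config
from .io_model import read_annotations, read_matrix, write_annotations, write_matrix

log = logging.getLogger("circsc")


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute the configured stages; returns the run manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict[str, Any] = {
        "versions": {
            "circsc": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "config": config,
        "seed": seed,
        "stages": {},
    }

    # ---- inputs
    inputs = config["inputs"]
    if inputs["genes_mtx"]:
        genes = read_matrix(inputs["genes_mtx"], format="mtx", feature_kind="gene")
        circ = read_matrix(inputs["circ_mtx"], format="mtx", feature_kind="circ")
        annotations = read_annotations(inputs["annotations"])
        truth = None
    else:
        sim = config["simulate"]
        genes, circ, annotations, truth = synthetic.simulate_cell_population(
            n_cells=sim["n_cells"],
            n_genes=sim["n_genes"],
            n_circ=sim["n_circ"],
            mean_bsj=sim["mean_bsj"],
            seed=seed,
        )
        write_matrix(genes, outdir / "genes", format="mtx")
        write_matrix(circ, outdir / "circ", format="mtx")
        write_annotations(annotations, outdir / "cells.tsv")
        truth.circ_truth.to_csv(outdir / "truth_circ.tsv", sep="\t")
        truth.cell_truth.to_csv(outdir / "truth_cells.tsv", sep="\t")
    manifest["stages"]["input"] = {
        "n_cells": genes.n_cells,
        "n_genes": genes.n_features,
        "n_circ": circ.n_features,
        "simulated": truth is not None,
    }
    log.info("input: %d cells, %d genes, %d circRNAs", genes.n_cells,
             genes.n_features, circ.n_features)

    # ---- QC
    if config["stages"]["qc"]:
        report = qc.default_cell_filter(genes, nmads=config["qc"]["nmads"])
        report.to_csv(outdir / "qc_report.tsv", sep="\t")
        keep = report["keep"].to_numpy()
        genes, circ = qc.apply_cell_filter([genes, circ], keep)
        ann_by_id = {a.cell_id: a for a in annotations}
        annotations = [ann_by_id[c] for c in genes.cell_ids]
        manifest["stages"]["qc"] = {
            "n_cells_kept": int(keep.sum()),
            "n_cells_removed": int((~keep).sum()),
        }
        log.info("qc: kept %d cells", int(keep.sum()))

    # ---- quantify
    circ_cpm = gene_cpm = None
    if config["stages"]["quantify"]:
        qcfg = config["quantify"]
        circ, high_conf = quantify.dataset_bsj_filter(
            circ, min_total=qcfg["min_total"], high_conf_total=qcfg["high_conf_total"]
        )
        denom = quantify.cpm_denominators(genes, circ, annotations)
        circ_cpm = quantify.normalize(circ, denominators=denom, mode="cpm")
        gene_cpm = quantify.normalize(genes, denominators=denom, mode="cpm")
        factors = quantify.compute_size_factors(genes)
        pd.DataFrame(
            {"cell_id": factors.cell_ids, "size_factor": factors.factors}
        ).to_csv(outdir / "size_factors.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "circ_id": circ.feature_ids,
                "total_bsj_reads": circ.feature_sums(),
                "high_confidence": high_conf,
            }
        ).to_csv(outdir / "circ_filter.tsv", sep="\t", index=False)
        manifest["stages"]["quantify"] = {
            "n_circ_kept": circ.n_features,
            "n_high_confidence": int(high_conf.sum()),
        }
        log.info("quantify: %d circRNAs kept (%d high-confidence)",
                 circ.n_features, int(high_conf.sum()))

    # ---- specificity
    markers = None
    if config["stages"]["specificity"]:
        if circ_cpm is None:
            raise RuntimeError("specificity stage requires the quantify stage")
        table = specificity.specificity_table(circ, annotations, expr=circ_cpm)
        table.to_csv(outdir / "specificity.tsv", sep="\t")
        cell_types = {a.cell_id: a.cell_type for a in annotations}
        mcfg = config["markers"]
        markers = specificity.find_markers(
            circ_cpm,
            cell_types,
            min_fold=mcfg["min_fold"],
            alpha=mcfg["alpha"],
            epsilon=mcfg["epsilon"],
        )
        specificity.markers_frame(markers).to_csv(
            outdir / "markers.tsv", sep="\t", index=False
        )
        manifest["stages"]["specificity"] = {
            "n_features": int(table.shape[0]),
            "n_marker_calls": int(sum(m.is_marker for m in markers)),
            "category_counts": table["category"].value_counts().to_dict(),
        }
        log.info("specificity: %d features classified", table.shape[0])

    # ---- dynamics (embryo time course, simulated study conditions)
    if config["stages"]["dynamics"]:
        dcfg = config["dynamics"]
        sim = config["simulate"]
        profile, emb_truth = synthetic.simulate_embryo_time_course(
            n_features=sim["embryo_features"],
            noise_sd=sim["embryo_noise_sd"],
            seed=seed,
        )
        kept = profile.values.loc[(profile.values > 0).sum(axis=1) >= dcfg["min_stages"]]
        standardized = dynamics.standardize_rows(kept)
        clusters = dynamics.fuzzy_cmeans(
            standardized, c=dcfg["c"], m=dcfg["m"], tol=dcfg["tol"], seed=dcfg["seed"]
        )
        labels = dynamics.label_maternal_zygotic(clusters)
        hard = clusters.hard_assignments()
        out = clusters.memberships.copy()
        out.columns = [f"membership_{c}" for c in out.columns]
        out["cluster"] = hard
        out["label"] = hard.map(labels)
        out.to_csv(outdir / "clusters.tsv", sep="\t")
        clusters.centroids.to_csv(outdir / "centroids.tsv", sep="\t")
        composition = dynamics.stage_composition(kept, clusters)
        composition.to_csv(outdir / "composition.tsv", sep="\t")
        manifest["stages"]["dynamics"] = {
            "n_features_clustered": int(standardized.shape[0]),
            "cluster_labels": {str(k): v for k, v in labels.items()},
            "n_iterations": clusters.n_iter,
        }
        log.info("dynamics: %d features in %d clusters", standardized.shape[0], dcfg["c"])

    # ---- deconvolution
    if config["stages"]["deconv"]:
        if circ_cpm is None or markers is None:
            raise RuntimeError("deconv stage requires quantify and specificity stages")
        vcfg = config["deconv"]
        cell_types = {a.cell_id: a.cell_type for a in annotations}
        signature = deconv.build_signature(
            circ_cpm,
            cell_types,
            markers,
            min_types_detected=vcfg["min_types_detected"],
            min_fold=vcfg["min_fold"],
        )
        signature.values.to_csv(outdir / "signature.tsv", sep="\t")
        if config["inputs"]["bulk"]:
            bulk = pd.read_csv(config["inputs"]["bulk"], sep="\t", index_col=0)
            mix_truth = None
        else:
            sim = config["simulate"]
            bulk, mix_truth = synthetic.simulate_bulk_mixtures(
                signature.values,
                n_samples=sim["mixtures"],
                noise_sd=sim["mixture_noise_sd"],
                seed=seed,
            )
            mix_truth.to_csv(outdir / "truth_fractions.tsv", sep="\t")
        results = deconv.deconvolve(signature, bulk, method=vcfg["method"])
        deconv.mixtures_frame(results).to_csv(
            outdir / "fractions.tsv", sep="\t", index=False
        )
        manifest["stages"]["deconv"] = {
            "n_signature_features": len(signature.feature_ids),
            "n_cell_types": len(signature.cell_types),
            "n_samples": len(results),
            "median_rmse": float(np.median([r.rmse for r in results])),
        }
        if mix_truth is not None:
            est = pd.DataFrame(
                {r.sample_id: r.fractions for r in results}
            ).T.reindex(columns=mix_truth.columns)
            r_overall = float(
                np.corrcoef(est.to_numpy().ravel(), mix_truth.to_numpy().ravel())[0, 1]
            )
            manifest["stages"]["deconv"]["fraction_recovery_r"] = r_overall
        log.info("deconv: %d samples decomposed over %d types",
                 len(results), len(signature.cell_types))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_from_files(config_path=None, overrides: dict | None = None) -> dict:
    return run_pipeline(load_config(config_path, overrides))
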