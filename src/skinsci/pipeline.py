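"""End-to-end pipeline: simulate -> QC -> embed -> signatures -> comparisons.

One YAML-able config drives the whole chain on simulated data; every
stage seed is derived deterministically from the master seed, all
thresholds are echoed into a manifest, and every per-cell output table
is keyed by barcode.  Rerunning with the same config yields
byte-identical tables.
"""

from __future__ import annotations

import logging
import os
import zlib
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import comparative, embed, programs, qc, synthetic, trajectory
from .io import write_mtx_bundle

__all__ = ["default_config", "validate_config", "stage_seed", "run_pipeline"]

logger = logging.getLogger("skinsci.pipeline")


def default_config(seed: int = 0) -> dict:
    """A small four-genotype demo configuration.

    One pooled sample per genotype (genotypes are distinguished by RT
    index in this assay design, so each genotype is one library).  The
    mutant genotype loses two cell types almost entirely and
    down-regulates one ligand-like marker gene in the first cell type.
    """
    return {
        "seed": seed,
        "simulation": {
            "n_types": 8,
            "n_genes": 400,
            "n_markers_per_type": 12,
            "marker_boost": 8.0,
            "cells_per_sample": 1500,
            "empty_per_sample": 400,
            "ambient_fraction": 0.15,
            "doublet_rate": 0.11,
            "genotypes": ["wildtype", "eda_mut", "bnc2_mut", "hypoTH"],
            "lost_types": {"bnc2_mut": ["type06", "type07"]},
            "de": [
                {"gene_index": 0, "cell_type": "type00",
                 "genotype": "hypoTH", "fold_change": 0.25},
            ],
        },
        "qc": {"min_umi": 600, "max_umi": 6000, "background_max_umi": 15,
               "doublet_rate_prior": 0.11, "knn_k": 30},
        "embed": {"n_pcs": 50, "n_neighbors": 20, "min_dist": 0.15,
                  "cluster_resolution": 1e-4, "knn_for_clustering": 20,
                  "mnn_k": 20, "mnn_sigma": 20.0},
        "signatures": {"numerator_type": "type01", "denominator_type": "type02",
                       "min_specificity": 0.1},
        "abundance": {"reference_sample": "wildtype", "pseudocount": 1},
        "de": {"contrast": ["wildtype", "hypoTH"], "target_type": "type00",
               "q_significant": 0.05, "q_stringent": 0.01,
               "min_fold_change": 2.0, "min_cells_expressing": 10},
        "fractions": {"n_boot": 100, "min_total_umi": 1},
        "umap": False,
    }


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic, stage-specific 31-bit seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def validate_config(config: dict) -> list[str]:
    """Pure config check; an empty list means the config is runnable."""
    problems: list[str] = []
    if not isinstance(config.get("seed"), int) or config.get("seed", -1) < 0:
        problems.append("seed must be a nonnegative integer")
    qc_cfg = config.get("qc", {})
    try:
        qc.QCThresholds(**qc_cfg)
    except (TypeError, ValueError) as exc:
        problems.append(f"qc: {exc}")
    try:
        embed.EmbedConfig(**config.get("embed", {}))
    except (TypeError, ValueError) as exc:
        problems.append(f"embed: {exc}")
    sim = config.get("simulation")
    if not sim:
        problems.append("simulation section is required")
    else:
        if sim.get("n_types", 0) < 2:
            problems.append("simulation.n_types must be >= 2")
        if sim.get("n_markers_per_type", 0) * sim.get("n_types", 0) > sim.get("n_genes", 0):
            problems.append("simulation: marker budget exceeds n_genes")
        if not 0 <= sim.get("doublet_rate", 0.0) < 0.5:
            problems.append("simulation.doublet_rate must be in [0, 0.5)")
    sig = config.get("signatures", {})
    for key in ("numerator_type", "denominator_type"):
        t = sig.get(key)
        if sim and t is not None and not str(t).startswith("type"):
            problems.append(f"signatures.{key} must name a simulated type")
    sig_file = sig.get("file")
    if sig_file and not os.path.exists(sig_file):
        problems.append(f"signatures.file not found: {sig_file}")
    return problems


def _build_sim_config(sim: dict, seed: int) -> synthetic.SimConfig:
    ps = synthetic.make_programs(
        n_types=sim["n_types"],
        n_genes=sim["n_genes"],
        n_markers_per_type=sim["n_markers_per_type"],
        marker_boost=sim["marker_boost"],
        seed=seed,
    )
    genotypes = sim["genotypes"]
    samples = [
        synthetic.SampleSpec(
            sample_id=g,
            genotype=g,
            n_cells=sim["cells_per_sample"],
            ambient_fraction=sim.get("ambient_fraction", 0.0),
            n_empty_barcodes=sim.get("empty_per_sample", 0),
        )
        for g in genotypes
    ]
    mult = np.ones((len(samples), ps.n_types))
    # unequal baseline abundances: geometric decay across types
    base = 0.8 ** np.arange(ps.n_types)
    for g, lost in sim.get("lost_types", {}).items():
        si = genotypes.index(g)
        for t in lost:
            mult[si, ps.type_names.index(t)] = 1e-3
    de_spec = [
        synthetic.DESpec(
            gene=d["gene_index"], cell_type=d["cell_type"],
            genotype=d["genotype"], fold_change=d["fold_change"],
        )
        for d in sim.get("de", [])
    ]
    traj = None
    if "trajectory" in sim:
        t = sim["trajectory"]
        traj = synthetic.TrajectorySpec(
            start_type=t["start_type"], end_type=t["end_type"],
            n_cells=t["n_cells"], sample_id=t.get("sample_id"),
        )
    return synthetic.SimConfig(
        programs=ps,
        samples=samples,
        abundance_multipliers=mult,
        base_abundance=base,
        de_spec=de_spec,
        doublet_rate=sim.get("doublet_rate", 0.0),
        trajectory=traj,
        seed=seed,
    )


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages; returns the manifest dict (also written as YAML).

    Stage order is fixed: simulate, qc, embed+cluster, signatures,
    abundance, differential expression, optional trajectory.  A stage
    failure aborts with the stage name attached.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"seed": config["seed"], "stages": {}, "thresholds": {
        "qc": dict(config.get("qc", {})),
        "embed": dict(config.get("embed", {})),
        "de": dict(config.get("de", {})),
        "fractions": dict(config.get("fractions", {})),
    }}
    stage = "simulate"
    try:
        sim_cfg = _build_sim_config(config["simulation"], stage_seed(config["seed"], stage))
        cm, truth = synthetic.simulate_dataset(sim_cfg)
        write_mtx_bundle(cm, os.path.join(out_dir, "counts"), force=True)
        truth.to_tsv(os.path.join(out_dir, "truth_barcodes.tsv"))
        manifest["stages"][stage] = {"n_barcodes": cm.n_cells, "n_genes": cm.n_genes}
        logger.info("simulated %d barcodes x %d genes", cm.n_cells, cm.n_genes)

        stage = "qc"
        thresholds = qc.QCThresholds(**config.get("qc", {}))
        kept, high = qc.filter_barcodes(cm, thresholds)
        background = qc.split_background(cm, thresholds)
        qc.knee_curve(cm.total_umis).to_csv(
            os.path.join(out_dir, "knee.tsv"), sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "kept": kept.n_cells,
            "discarded_high": high.n_cells,
            "background": {s: g.n_cells for s, g in background.items()},
        }

        stage = "embed"
        ecfg = embed.EmbedConfig(
            **config.get("embed", {}), seed=stage_seed(config["seed"], stage)
        )
        state = embed.embed_pipeline(kept, background, ecfg, with_umap=False)
        scores, flags = qc.doublet_scores(
            state.pca_corrected, thresholds, seed=stage_seed(config["seed"], "doublets")
        )
        kept = kept.subset_cells(~flags)
        state = embed.embed_pipeline(
            kept, background, ecfg, with_umap=bool(config.get("umap", False))
        )
        coords = pd.DataFrame(
            state.pca_aligned,
            columns=[f"PC{i + 1}" for i in range(state.pca_aligned.shape[1])],
        )
        coords.insert(0, "barcode", state.barcodes)
        coords["cluster"] = state.clusters
        if state.umap2d is not None:
            coords["umap1"], coords["umap2"] = state.umap2d[:, 0], state.umap2d[:, 1]
        coords.to_csv(os.path.join(out_dir, "embedding.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_cells": kept.n_cells,
            "n_doublets_flagged": int(flags.sum()),
            "n_clusters": int(state.clusters.max()) + 1,
            "n_loading_columns": 0 if state.loadings is None else state.loadings.shape[1],
        }

        stage = "signatures"
        sig_cfg = config.get("signatures", {})
        spec = programs.specificity_scores(state.normalized, state.clusters)
        spec_out = spec.copy()
        spec_out.insert(0, "gene_id", kept.genes["gene_id"])
        spec_out.to_csv(os.path.join(out_dir, "specificity.tsv"), sep="\t", index=False)
        gene_ids = kept.genes["gene_id"].tolist()
        truth_types = truth.barcodes.set_index("barcode")["true_type"]
        kept_types = truth_types.loc[state.barcodes].to_numpy()

        def marker_signature(type_name: str) -> programs.GeneSignature:
            k = sim_cfg.programs.type_names.index(type_name)
            return programs.GeneSignature(
                name=f"{type_name}_markers",
                gene_ids=[gene_ids[g] for g in sim_cfg.programs.markers[k]],
                min_specificity=sig_cfg.get("min_specificity", 0.1),
                source="synthetic generator marker set",
            )

        sig_num = marker_signature(sig_cfg["numerator_type"])
        sig_den = marker_signature(sig_cfg["denominator_type"])
        s_num = programs.signature_score(state.normalized, gene_ids, sig_num)
        s_den = programs.signature_score(state.normalized, gene_ids, sig_den)
        ratio, shift = programs.score_ratio(s_num, s_den)
        pd.DataFrame(
            {"barcode": state.barcodes, "score_num": s_num, "score_den": s_den,
             "ratio": ratio}
        ).to_csv(os.path.join(out_dir, "signature_scores.tsv"), sep="\t", index=False)
        frac_cfg = config.get("fractions", {})
        fractions = programs.expressing_fraction(
            kept, sig_num, kept.cells["genotype"].to_numpy(),
            min_total_umi=frac_cfg.get("min_total_umi", 1),
            n_boot=frac_cfg.get("n_boot", 100),
            seed=stage_seed(config["seed"], "fractions"),
        )
        pd.DataFrame([asdict(f) for f in fractions]).to_csv(
            os.path.join(out_dir, "expressing_fractions.tsv"), sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "ratio_shift": float(shift),
            "signature_sizes": [len(sig_num.gene_ids), len(sig_den.gene_ids)],
        }

        stage = "abundance"
        ab_cfg = config.get("abundance", {})
        counts_ts = pd.crosstab(
            pd.Series(state.clusters, name="cluster"),
            kept.cells["sample_id"],
        )
        table = comparative.abundance_log2(
            counts_ts,
            reference_sample=ab_cfg.get("reference_sample", "wildtype"),
            pseudocount=ab_cfg.get("pseudocount", 1),
        )
        table.log2_ratio.to_csv(os.path.join(out_dir, "abundance_log2.tsv"), sep="\t")
        manifest["stages"][stage] = {
            "reference": table.reference_sample,
            "size_factors": {k: float(v) for k, v in table.sample_size_factors.items()},
        }

        stage = "de"
        de_cfg = config.get("de", {})
        cond_a, cond_b = de_cfg["contrast"]
        target = de_cfg.get("target_type")
        in_type = kept_types == target
        in_contrast = kept.cells["genotype"].isin([cond_a, cond_b]).to_numpy()
        sub = kept.subset_cells(in_type & in_contrast)
        sf = embed.size_factors(sub.total_umis)
        de_table = comparative.fit_gene_glm(
            sub,
            sub.cells["genotype"].to_numpy(),
            sf,
            min_cells_expressing=de_cfg.get("min_cells_expressing", 10),
            reference_level=cond_a,
        )
        de_table.to_csv(os.path.join(out_dir, "de_results.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {
            "contrast": [cond_a, cond_b],
            "n_cells": sub.n_cells,
            "n_genes_tested": len(de_table),
            "n_deg_q05": comparative.count_degs(
                de_table, de_cfg.get("q_significant", 0.05)
            ),
            "n_deg_q01_fc2": comparative.count_degs(
                de_table, de_cfg.get("q_stringent", 0.01),
                de_cfg.get("min_fold_change", 2.0),
            ),
        }

        if sim_cfg.trajectory is not None:
            stage = "trajectory"
            traj_label = (
                f"traj:{sim_cfg.trajectory.start_type}->{sim_cfg.trajectory.end_type}"
            )
            on_path = kept_types == traj_label
            est = trajectory.PrincipalGraphPseudotime(
                n_nodes=min(25, max(2, int(on_path.sum()) // 4)),
                random_state=stage_seed(config["seed"], stage),
            ).fit(state.pca_aligned[on_path])
            latent = (
                truth.barcodes.set_index("barcode")["latent_time"]
                .loc[state.barcodes[on_path]]
                .to_numpy()
            )
            roots = np.argsort(latent)[: max(1, int(on_path.sum()) // 20)]
            pt = est.order_cells(roots)
            pd.DataFrame(
                {"barcode": state.barcodes[on_path], "pseudotime": pt}
            ).to_csv(os.path.join(out_dir, "pseudotime.tsv"), sep="\t", index=False)
            rho, tau = trajectory.ordering_diagnostics(pt, latent)
            manifest["stages"][stage] = {
                "n_cells": int(on_path.sum()),
                "spearman_vs_latent": rho,
                "kendall_vs_latent": tau,
            }
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
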