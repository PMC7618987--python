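"""End-to-end pipeline runner with schema-validated configuration, stage
logging and a checksum manifest for reproducibility.

The demo pipeline exercises every stage on synthetic data: simulate counts
with the eight packaged supercluster programs -> QC -> log-normalize -> PCA ->
SNN graph -> Paris -> cut -> DEG-driven merge -> signature scoring ->
supercluster and condition annotation -> taxonomy + composition statistics ->
spatial scene simulation, cluster imputation and neighborhood network ->
binned-scene nucleus reconstruction. All randomness derives from one seed;
reruns with the same config produce byte-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from pydantic import BaseModel, ConfigDict

from . import io as mio
from .expression import QCRules, apply_qc, log_normalize
from .graph import build_knn_graph, cut_dendrogram, merge_weak_clusters, paris_cluster
from .neighborhood import NeighborhoodConfig, build_interaction_network, network_edge_table
from .nuclei import aggregate_nuclei, assign_spots, dilate_polygons, qc_nuclei, write_polygons_geojson
from .simulate import (
    BinnedSceneSpec,
    NucleusSpec,
    ProgramSpec,
    SpatialSceneSpec,
    generate_binned_scene,
    generate_count_matrix,
    generate_spatial_scene,
    load_fixture_modules,
)
from .spatial import derive_cluster_signatures, impute_clusters
from .stats import DiversityRecord, cluster_diversity_glm, enrichment_hypergeometric, bh_adjust
from .taxonomy import (
    annotate_condition_level,
    assign_dominant_module,
    build_taxonomy,
    classify_clusters,
    score_signature_rank,
)

logger = logging.getLogger("myelotax")

#: condition/region plan for the eight packaged programs; Surveillance is the
#: homeostatic baseline, the disease programs map to representative pathologies
DEFAULT_METADATA_PLAN = {
    "Surveillance": ("control", "cortex", "human"),
    "Neuroprotection": ("stroke", "cortex", "human"),
    "Phagocytosis": ("AD", "hippocampus", "human"),
    "Inflammation": ("GBM", "white_matter", "human"),
    "Cytokine production": ("MS", "white_matter", "human"),
    "Antigen presentation": ("MS", "spinal_cord", "human"),
    "IFN signature": ("AGS", "cortex", "human"),
    "Proliferation": ("tumor", "cerebellum", "human"),
}

DEFAULT_DISEASE_MAP = {
    "control": "homeostatic",
    "stroke": "non_homeostatic",
    "AD": "non_homeostatic",
    "GBM": "non_homeostatic",
    "MS": "non_homeostatic",
    "AGS": "non_homeostatic",
    "tumor": "non_homeostatic",
}


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: str = "human"
    cells_per_program: int = 150
    n_background_genes: int = 300
    fold_change: float = 8.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0


class GraphConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pcs: int = 30
    k: int = 20
    n_clusters: int = 16


class MergeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_cells: int = 20
    min_degs: int = 5
    p_adj_max: float = 0.05
    lfc_min: float = 0.25


class SpatialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    cells_per_program: int = 40
    n_other_cells: int = 60
    field_um: float = 1000.0
    radius_um: float = 100.0
    top_k: int = 20


class NucleiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    buffer_um: float = 2.0


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    glm_n_records: int = 40
    glm_rate_ratio: float = 1.5


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    min_features: int = 50
    max_mito_fraction: float = 1.0
    r_max: int = 1500
    simulate: SimulateConfig = SimulateConfig()
    graph: GraphConfig = GraphConfig()
    merge: MergeConfig = MergeConfig()
    spatial: SpatialConfig = SpatialConfig()
    nuclei: NucleiConfig = NucleiConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def _write_csv(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_counts(cfg: PipelineConfig):
    modules = load_fixture_modules(cfg.simulate.species)
    programs = [
        ProgramSpec(
            program_name=name,
            module_genes=tuple(genes),
            fold_change=cfg.simulate.fold_change,
            baseline_mean=cfg.simulate.baseline_mean,
            dispersion=cfg.simulate.dispersion,
        )
        for name, genes in modules.items()
    ]
    adata = generate_count_matrix(
        programs,
        cells_per_program=cfg.simulate.cells_per_program,
        n_background_genes=cfg.simulate.n_background_genes,
        metadata_plan=DEFAULT_METADATA_PLAN,
        seed=cfg.seed,
    )
    return adata, modules, programs


def _pca(x: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_pcs = min(n_pcs, min(x.shape) - 1)
    centered = (x - x.mean(0)) / np.maximum(x.std(0), 1e-8)
    return PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(centered)


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Execute every enabled stage, write artifacts under `out_dir`, and
    return the manifest (also written as manifest.json)."""
    t0 = time.time()
    os.makedirs(out_dir, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    manifest: dict = {"config": config.model_dump(), "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 3)}

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    adata, modules, programs = simulate_counts(config)
    mio.write_count_matrix(adata, os.path.join(out_dir, "counts"))

    # --- qc + normalize ---------------------------------------------------
    stage("qc")
    rules = QCRules(min_features=config.min_features, max_mito_fraction=config.max_mito_fraction)
    adata = apply_qc(adata, rules)
    with open(os.path.join(out_dir, "qc_report.json"), "w") as fh:
        json.dump(adata.uns["qc_removed"], fh, indent=2, sort_keys=True)
    norm = log_normalize(adata)

    # --- graph + paris + merge -------------------------------------------
    stage("graph")
    dense = np.asarray(norm.X.todense()) if sp.issparse(norm.X) else np.asarray(norm.X)
    emb = _pca(dense, config.graph.n_pcs, int(rng_seeds[0]))
    g = build_knn_graph(emb, k=config.graph.k, node_names=list(norm.obs_names))
    dend = paris_cluster(g)
    raw_assign = cut_dendrogram(dend, n_clusters=min(config.graph.n_clusters, dend.n_leaves))
    assignment, merge_log = merge_weak_clusters(
        norm,
        raw_assign,
        dend,
        min_cells=config.merge.min_cells,
        min_degs=config.merge.min_degs,
        p_adj_max=config.merge.p_adj_max,
        lfc_min=config.merge.lfc_min,
    )
    assignment.rename_axis("cell_id").to_frame().pipe(_write_csv, os.path.join(out_dir, "clusters.csv"))
    with open(os.path.join(out_dir, "dendrogram.newick"), "w") as fh:
        fh.write(dend.to_newick())
    _write_csv(dend.to_frame(), os.path.join(out_dir, "merge_table.csv"), index=False)
    with open(os.path.join(out_dir, "cluster_merge_log.json"), "w") as fh:
        json.dump(merge_log, fh, indent=2)

    # --- superclusters + taxonomy ----------------------------------------
    stage("taxonomy")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = score_signature_rank(norm, modules, r_max=config.r_max)
    dominant = assign_dominant_module(scores)
    superclusters = classify_clusters(scores, assignment)
    conditions = annotate_condition_level(adata, assignment, DEFAULT_DISEASE_MAP)
    tree = build_taxonomy(adata, assignment, superclusters, conditions, dend)
    _write_csv(tree.to_frame(), os.path.join(out_dir, "taxonomy.csv"))
    with open(os.path.join(out_dir, "taxonomy.json"), "w") as fh:
        fh.write(tree.to_json())
    _write_csv(dominant.rename_axis("cell_id"), os.path.join(out_dir, "dominant_modules.csv"))

    # --- composition statistics ------------------------------------------
    stage("stats")
    cond = adata.obs["condition"].astype(str)
    is_disease = cond.map(DEFAULT_DISEASE_MAP).eq("non_homeostatic")
    rows = []
    for sc in sorted(superclusters["supercluster"].unique()):
        cells_in = assignment.map(superclusters["supercluster"]).eq(sc)
        p, fold = enrichment_hypergeometric(
            int((cells_in & is_disease.reindex(assignment.index)).sum()),
            int(cells_in.sum()),
            int(is_disease.sum()),
            int(len(assignment)),
        )
        rows.append({"supercluster": sc, "p_value": p, "fold": fold})
    enrich = pd.DataFrame(rows)
    enrich["p_adjusted"] = bh_adjust(enrich["p_value"])
    _write_csv(enrich, os.path.join(out_dir, "enrichment.csv"), index=False)

    glm_rng = np.random.default_rng(int(rng_seeds[1]))
    records = []
    regions = ["cortex", "hippocampus", "white_matter", "spinal_cord", "cerebellum"]
    for i in range(config.stats.glm_n_records):
        is_dis = i % 2 == 1
        n_nuclei = int(glm_rng.integers(400, 4000))
        base_rate = 4.0 * (config.stats.glm_rate_ratio if is_dis else 1.0)
        n_clusters = int(glm_rng.poisson(base_rate * np.log(n_nuclei) / np.log(1000)))
        records.append(
            DiversityRecord(
                region=regions[i % len(regions)],
                condition_class="non_homeostasis" if is_dis else "homeostasis",
                n_clusters=min(n_clusters, n_nuclei),
                n_nuclei=n_nuclei,
            )
        )
    glm = cluster_diversity_glm(records)
    with open(os.path.join(out_dir, "glm_diversity.json"), "w") as fh:
        json.dump(
            {
                "rate_ratio": glm.rate_ratio,
                "wald_p": glm.wald_p,
                "dispersion": glm.dispersion,
                "family_used": glm.family_used,
                "conf_int": list(glm.conf_int),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    # --- spatial imputation + neighborhoods ------------------------------
    if config.spatial.enabled:
        stage("spatial")
        sp_dir = os.path.join(out_dir, "spatial")
        os.makedirs(sp_dir, exist_ok=True)
        sp_counts = generate_count_matrix(
            programs,
            cells_per_program=config.spatial.cells_per_program,
            n_background_genes=config.simulate.n_background_genes,
            metadata_plan=DEFAULT_METADATA_PLAN,
            seed=int(rng_seeds[2]),
        )
        n_mg = sp_counts.n_obs
        scene = generate_spatial_scene(
            SpatialSceneSpec(
                field_width_um=config.spatial.field_um,
                field_height_um=config.spatial.field_um,
                cell_types=(
                    ("Microglia", n_mg, ("uniform",)),
                    ("Neuron", config.spatial.n_other_cells, ("uniform",)),
                    ("Astrocyte", config.spatial.n_other_cells, ("uniform",)),
                ),
            ),
            seed=int(rng_seeds[3]),
        )
        mg_rows = scene[scene["identity"] == "Microglia"].reset_index(drop=True)
        sp_counts.obs["identity"] = "Microglia"
        sp_counts.obs["x_um"] = mg_rows["x_um"].to_numpy()
        sp_counts.obs["y_um"] = mg_rows["y_um"].to_numpy()
        signatures = derive_cluster_signatures(
            adata, assignment, panel_genes=list(sp_counts.var_names), top_k=config.spatial.top_k
        )
        imputed = impute_clusters(
            sp_counts,
            signatures,
            target_identity="Microglia",
            supercluster_map={str(k): str(v) for k, v in superclusters["supercluster"].items()},
        )
        imputed.obs["supercluster"] = imputed.obs["supercluster"].fillna("unassigned")
        _write_csv(
            imputed.obs[["identity", "x_um", "y_um", "imputed_cluster", "supercluster", "max_score", "margin"]]
            .rename_axis("cell_id"),
            os.path.join(sp_dir, "imputed.csv"),
        )
        network_cells = pd.concat(
            [
                imputed.obs.reset_index()[["x_um", "y_um"]].assign(
                    identity=imputed.obs["supercluster"].astype(str).to_numpy()
                ),
                scene[scene["identity"] != "Microglia"][["x_um", "y_um", "identity"]],
            ],
            ignore_index=True,
        )
        net = build_interaction_network(
            network_cells, NeighborhoodConfig(radius_um=config.spatial.radius_um)
        )
        _write_csv(network_edge_table(net), os.path.join(sp_dir, "edges.csv"), index=False)
        import networkx as nx

        nx.write_graphml(net, os.path.join(sp_dir, "network.graphml"))
        _write_csv(scene, os.path.join(sp_dir, "cells.csv"), index=False)

    # --- nucleus reconstruction ------------------------------------------
    if config.nuclei.enabled:
        stage("nuclei")
        nuc_dir = os.path.join(out_dir, "nuclei")
        os.makedirs(nuc_dir, exist_ok=True)
        spec = BinnedSceneSpec(
            nuclei=tuple(
                NucleusSpec(
                    nucleus_id=f"nuc{i}",
                    center=(20.0 + 30.0 * i, 20.0),
                    radius_um=6.0,
                    profile={"GENE_A": 40 + 10 * i, "GENE_B": 15 * i},
                )
                for i in range(4)
            )
        )
        spots, polygons, truth = generate_binned_scene(spec, seed=int(rng_seeds[4]))
        nuc_set = dilate_polygons(polygons, buffer_um=config.nuclei.buffer_um)
        assign, log = assign_spots(spots, nuc_set)
        recon = aggregate_nuclei(spots, assign, nuc_set)
        recon_qc = qc_nuclei(recon, QCRules(min_features=1))
        _write_csv(spots, os.path.join(nuc_dir, "spots.csv"), index=False)
        write_polygons_geojson(polygons, os.path.join(nuc_dir, "nuclei.geojson"))
        recon_df = pd.DataFrame(recon.X, index=recon.obs_names, columns=recon.var_names)
        _write_csv(recon_df.rename_axis("nucleus_id"), os.path.join(nuc_dir, "reconstruction.csv"))
        _write_csv(truth.rename_axis("nucleus_id"), os.path.join(nuc_dir, "truth.csv"))
        summary = dict(log)
        summary["exact_recovery"] = bool(
            (recon_df.reindex_like(truth).to_numpy() == truth.to_numpy()).all()
        ) if log["dropped_multi"] == 0 and log["unassigned"] == 0 else False
        summary["n_nuclei_after_qc"] = int(recon_qc.n_obs)
        with open(os.path.join(nuc_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    # --- manifest ---------------------------------------------------------
    stage("manifest")
    checksums = {}
    for root, _, files in os.walk(out_dir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            checksums[os.path.relpath(p, out_dir)] = _sha256(p)
    manifest["checksums"] = checksums
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
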