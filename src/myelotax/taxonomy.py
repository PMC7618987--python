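"""Rank-based gene-signature scoring, dominant-module assignment, supercluster
classification of clusters, and assembly of the four-level taxonomy
(Cell type -> Condition -> Supercluster -> Cluster).

The signature score is the Mann–Whitney-U-based statistic used for per-cell
module scoring: with a cell's genes ranked by expression (descending, average
ranks for ties, ranks truncated at ``r_max + 1``), a module of size n_g scores

    U' = sum(module ranks) - n_g (n_g + 1) / 2
    score = max(0, 1 - U' / (n_g * r_max))

which lies in [0, 1] and is invariant to monotone transforms of expression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import rankdata

from .graph import Dendrogram
from .stats import gini_coefficient

__all__ = [
    "SignatureScores",
    "TaxonomyTree",
    "score_signature_rank",
    "assign_dominant_module",
    "classify_clusters",
    "annotate_condition_level",
    "build_taxonomy",
]


@dataclass
class SignatureScores:
    """Raw [0,1] scores (cells x modules) plus the per-module z-scaled variant."""

    raw: pd.DataFrame
    r_max: int
    skipped_modules: list[str] = field(default_factory=list)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def scaled(self) -> pd.DataFrame:
        values = self.raw.to_numpy(dtype=float)
        mu = values.mean(axis=0, keepdims=True)
        sd = values.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0  # constant module score -> all zeros after centering
        return pd.DataFrame((values - mu) / sd, index=self.raw.index, columns=self.raw.columns)


def score_signature_rank(
    adata: AnnData, modules: dict[str, list[str]], r_max: int = 1500
) -> SignatureScores:
    """Per-cell rank-based signature score for each gene module.

    Module genes absent from the matrix are dropped (recorded per module; the
    module size n_g uses the retained count, mirroring restricted spatial
    panels); modules with no matching genes are skipped.
    """
    if r_max < 1:
        raise ValueError("r_max must be a positive integer")
    x = adata.X
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    ranks = rankdata(-dense, axis=1)  # descending, average ties
    ranks = np.minimum(ranks, r_max + 1)
    gene_pos = {g: i for i, g in enumerate(adata.var_names)}

    cols: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    dropped: dict[str, list[str]] = {}
    for name, genes in modules.items():
        present = [g for g in genes if g in gene_pos]
        missing = [g for g in genes if g not in gene_pos]
        if missing:
            dropped[name] = missing
        if not present:
            skipped.append(name)
            warnings.warn(f"module {name!r} has no genes in the matrix; skipped", stacklevel=2)
            continue
        idx = [gene_pos[g] for g in present]
        n_g = len(idx)
        u = ranks[:, idx].sum(axis=1) - n_g * (n_g + 1) / 2.0
        cols[name] = np.maximum(0.0, 1.0 - u / (n_g * r_max))
    raw = pd.DataFrame(cols, index=adata.obs_names)
    return SignatureScores(raw=raw, r_max=r_max, skipped_modules=skipped, dropped_genes=dropped)


def assign_dominant_module(scores: SignatureScores) -> pd.DataFrame:
    """Per-cell dominant module = argmax of the z-scaled score.

    Ties resolve to the lexicographically first module name; tied cells are
    flagged. Returns columns (module, tied)."""
    scaled = scores.scaled
    if scaled.shape[1] < 2:
        raise ValueError("dominant-module assignment needs at least two modules")
    cols = sorted(scaled.columns)
    z = scaled[cols].to_numpy()
    best = z.argmax(axis=1)  # first occurrence wins -> lexicographic with sorted cols
    maxv = z[np.arange(len(z)), best]
    tied = (z == maxv[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {"module": [cols[i] for i in best], "tied": tied}, index=scaled.index
    )


def classify_clusters(scores: SignatureScores, assignment: pd.Series) -> pd.DataFrame:
    """Supercluster per cluster = module with highest mean scaled score.

    Returns a frame indexed by cluster with columns (supercluster, margin);
    margin is the gap between the best and second-best mean scaled score, a
    low-confidence signal when near zero."""
    scaled = scores.scaled.loc[assignment.index]
    cols = sorted(scaled.columns)
    means = scaled[cols].groupby(assignment, observed=True).mean()
    z = means.to_numpy()
    best = z.argmax(axis=1)
    rows = {}
    for i, cluster in enumerate(means.index):
        ordered = np.sort(z[i])[::-1]
        margin = float(ordered[0] - ordered[1]) if len(ordered) > 1 else float("inf")
        rows[cluster] = {"supercluster": cols[best[i]], "margin": margin}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster")


def annotate_condition_level(
    adata: AnnData, assignment: pd.Series, disease_map: dict[str, str]
) -> pd.DataFrame:
    """Label each cluster Homeostasis / Non-homeostasis by majority of its cells.

    ``disease_map`` sends every sample condition to 'homeostatic' or
    'non_homeostatic'. A cluster is Non-homeostasis when the non-homeostatic
    cell fraction exceeds 0.5; exact ties go to Non-homeostasis and are
    flagged. Returns columns (condition, non_homeostatic_fraction, tied)."""
    conditions = adata.obs["condition"].astype(str)
    unmapped = sorted(set(conditions) - set(disease_map))
    if unmapped:
        raise ValueError(f"conditions missing from disease_map: {unmapped}")
    bad = sorted(set(disease_map.values()) - {"homeostatic", "non_homeostatic"})
    if bad:
        raise ValueError(f"disease_map values must be homeostatic/non_homeostatic, got {bad}")
    is_disease = conditions.map(disease_map).eq("non_homeostatic").to_numpy()
    frac = pd.Series(is_disease, index=adata.obs_names).groupby(assignment.reindex(adata.obs_names), observed=True).mean()
    out = pd.DataFrame(
        {
            "condition": np.where(frac >= 0.5, "Non-homeostasis", "Homeostasis"),
            "non_homeostatic_fraction": frac,
            "tied": frac == 0.5,
        }
    ).rename_axis("cluster")
    return out


@dataclass
class TaxonomyTree:
    """Four-level taxonomy with per-cluster composition and Gini coefficient.

    ``clusters`` is a flat frame indexed by cluster with columns cell_type,
    condition, supercluster, n_cells, gini, leaf_rank plus one share column
    per sample condition; the nested JSON view groups clusters under
    Cell type -> Condition -> Supercluster."""

    cell_type: str
    clusters: pd.DataFrame

    def to_json(self) -> str:
        tree: dict = {"cell_type": self.cell_type, "conditions": {}}
        for cluster, row in self.clusters.sort_values("leaf_rank").iterrows():
            cond = tree["conditions"].setdefault(row["condition"], {"superclusters": {}})
            sc = cond["superclusters"].setdefault(row["supercluster"], {"clusters": {}})
            sc["clusters"][str(cluster)] = {
                "n_cells": int(row["n_cells"]),
                "gini": float(row["gini"]),
                "leaf_rank": int(row["leaf_rank"]),
                "composition": {
                    c.removeprefix("share_"): float(row[c])
                    for c in self.clusters.columns
                    if c.startswith("share_")
                },
            }
        return json.dumps(tree, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "TaxonomyTree":
        tree = json.loads(payload)
        rows = {}
        for cond, cd in tree["conditions"].items():
            for sc, sd in cd["superclusters"].items():
                for cluster, info in sd["clusters"].items():
                    row = {
                        "cell_type": tree["cell_type"],
                        "condition": cond,
                        "supercluster": sc,
                        "n_cells": info["n_cells"],
                        "gini": info["gini"],
                        "leaf_rank": info["leaf_rank"],
                    }
                    row.update({f"share_{k}": v for k, v in info["composition"].items()})
                    rows[cluster] = row
        frame = pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster")
        frame = frame.sort_values("leaf_rank")
        try:
            frame.index = frame.index.astype(int)
        except (TypeError, ValueError):
            pass
        return cls(cell_type=tree["cell_type"], clusters=frame)

    def to_frame(self) -> pd.DataFrame:
        return self.clusters.copy()


def build_taxonomy(
    adata: AnnData,
    assignment: pd.Series,
    superclusters: pd.DataFrame,
    conditions: pd.DataFrame,
    dendrogram: Dendrogram,
) -> TaxonomyTree:
    """Assemble the four-level hierarchy with per-cluster Gini coefficients.

    The Gini is computed over the cluster's condition-normalized share vector
    (cluster cell counts divided by the total number of cells per sample
    condition). Leaf order follows the dendrogram."""
    cell_types = adata.obs["cell_type"].astype(str)
    per_cluster_types = cell_types.groupby(assignment.reindex(adata.obs_names), observed=True).nunique()
    if (per_cluster_types > 1).any():
        bad = per_cluster_types[per_cluster_types > 1].index.tolist()
        raise ValueError(f"clusters mixing multiple cell types: {bad}")
    cell_type = cell_types.iloc[0]

    cond = adata.obs["condition"].astype(str)
    totals = cond.value_counts()
    table = pd.crosstab(assignment.reindex(adata.obs_names), cond)
    shares = table.div(totals.reindex(table.columns), axis=1)

    order = dendrogram.leaf_order()
    leaf_rank: dict[int, int] = {}
    for pos, leaf in enumerate(order):
        c = int(assignment.loc[dendrogram.leaf_names[leaf]])
        if c not in leaf_rank:
            leaf_rank[c] = len(leaf_rank)

    rows = {}
    for cluster in table.index:
        share_vec = shares.loc[cluster].to_numpy(dtype=float)
        rows[cluster] = {
            "cell_type": cell_type,
            "condition": conditions.loc[cluster, "condition"],
            "supercluster": superclusters.loc[cluster, "supercluster"],
            "n_cells": int(table.loc[cluster].sum()),
            "gini": gini_coefficient(share_vec) if share_vec.sum() > 0 else 0.0,
            "leaf_rank": leaf_rank.get(int(cluster), len(leaf_rank)),
        }
        rows[cluster].update({f"share_{c}": float(v) for c, v in shares.loc[cluster].items()})
    frame = pd.DataFrame.from_dict(rows, orient="index").rename_axis("cluster").sort_values("leaf_rank")
    return TaxonomyTree(cell_type=cell_type, clusters=frame)
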