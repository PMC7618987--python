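"""Projection of reference-defined clusters onto spatial cells.

Spatial single-cell data (targeted panels or reconstructed nuclei) carries a
restricted gene space; clusters defined on the single-nucleus reference are
imputed onto spatial cells by scoring each cell against cluster-specific DEG
signatures (restricted to the shared panel) with the rank-based signature
score and assigning the argmax. Module feature maps give clipped z-scored
per-cell module expression with non-target cells fixed at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .expression import log_normalize, wilcoxon_deg
from .taxonomy import score_signature_rank

__all__ = [
    "ClusterSignatureSet",
    "derive_cluster_signatures",
    "impute_clusters",
    "module_feature_map",
]


@dataclass
class ClusterSignatureSet:
    """Top-DEG gene signature per reference cluster, panel-restricted."""

    signatures: dict[str, list[str]]
    non_imputable: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def derive_cluster_signatures(
    reference: AnnData,
    assignment: pd.Series,
    panel_genes: list[str],
    p_adj_max: float = 0.05,
    top_k: int = 20,
    min_genes: int = 3,
) -> ClusterSignatureSet:
    """One-vs-rest DEGs on the shared gene space; keep the top_k up-regulated
    genes per cluster passing `p_adj_max`, ordered by descending log2FC.

    Normalization happens on the full reference library before the gene space
    is restricted, so panel restriction cannot manufacture compositional
    differences. Clusters retaining fewer than `min_genes` genes are reported
    as non-imputable and excluded from the signature set."""
    if not 10 <= top_k <= 30:
        warnings.warn(f"top_k={top_k} outside the usual 10-30 range", stacklevel=2)
    shared = [g for g in reference.var_names if g in set(panel_genes)]
    if not shared:
        raise ValueError("no genes shared between reference and panel")
    totals = (
        np.asarray(reference.X.sum(axis=1)).ravel()
        if sp.issparse(reference.X)
        else reference.X.sum(axis=1)
    )
    full = reference[totals > 0].copy()
    labels = assignment.reindex(full.obs_names)
    full.obs["_cluster"] = labels.astype(str).to_numpy()
    norm = log_normalize(full)[:, shared].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = wilcoxon_deg(norm, "_cluster", mode="one_vs_rest")

    signatures: dict[str, list[str]] = {}
    non_imputable: list[str] = []
    for cluster in sorted(labels.astype(str).unique()):
        hits = table[
            (table["group"] == cluster)
            & (table["p_adjusted"] < p_adj_max)
            & (table["log2_fold_change"] > 0)
        ].sort_values(["log2_fold_change", "gene"], ascending=[False, True])
        genes = hits["gene"].head(top_k).tolist()
        if len(genes) < min_genes:
            non_imputable.append(cluster)
        else:
            signatures[cluster] = genes
    return ClusterSignatureSet(
        signatures=signatures,
        non_imputable=non_imputable,
        provenance={"p_adj_max": p_adj_max, "top_k": top_k, "min_genes": min_genes,
                    "n_shared_genes": len(shared)},
    )


def impute_clusters(
    spatial: AnnData,
    signatures: ClusterSignatureSet,
    target_identity: str = "Microglia",
    supercluster_map: dict[str, str] | None = None,
    r_max: int | None = None,
) -> AnnData:
    """Assign each target-identity cell the cluster whose signature scores highest.

    Non-target cells are untouched. Cells where no signature is scorable stay
    unassigned (counted in ``.uns['imputation']``). The supercluster label is
    inherited through `supercluster_map` when given. Adds obs columns
    imputed_cluster, supercluster, max_score, margin."""
    out = spatial.copy()
    out.obs["imputed_cluster"] = pd.array([pd.NA] * out.n_obs, dtype="string")
    out.obs["supercluster"] = pd.array([pd.NA] * out.n_obs, dtype="string")
    out.obs["max_score"] = np.nan
    out.obs["margin"] = np.nan

    target_mask = (out.obs["identity"].astype(str) == target_identity).to_numpy()
    n_unassigned = 0
    if target_mask.any() and signatures.signatures:
        sub = out[target_mask]
        eff_rmax = r_max if r_max is not None else min(1500, sub.n_vars)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = score_signature_rank(sub, signatures.signatures, r_max=eff_rmax)
        raw = scores.raw
        if raw.shape[1] == 0:
            n_unassigned = int(target_mask.sum())
        else:
            cols = sorted(raw.columns)
            z = raw[cols].to_numpy()
            best = z.argmax(axis=1)
            maxv = z[np.arange(len(z)), best]
            second = np.sort(z, axis=1)[:, -2] if z.shape[1] > 1 else np.full(len(z), -np.inf)
            labels = [cols[i] for i in best]
            out.obs.loc[target_mask, "imputed_cluster"] = labels
            out.obs.loc[target_mask, "max_score"] = maxv
            out.obs.loc[target_mask, "margin"] = maxv - second
            if supercluster_map:
                out.obs.loc[target_mask, "supercluster"] = [
                    supercluster_map.get(l, pd.NA) for l in labels
                ]
    elif target_mask.any():
        n_unassigned = int(target_mask.sum())
    out.uns["imputation"] = {
        "n_target": int(target_mask.sum()),
        "n_unassigned": n_unassigned,
        "non_imputable_clusters": list(signatures.non_imputable),
    }
    return out


def module_feature_map(
    spatial: AnnData, module: list[str], target_identity: str = "Microglia"
) -> pd.Series:
    """Clipped z-scored module expression per cell.

    Module-gene counts are summed per target-identity cell (other cells get 0),
    z-scored across all cells, and constrained to [-1, +1]. A degenerate
    (zero-variance) map returns all zeros with a warning."""
    present = [g for g in module if g in set(spatial.var_names)]
    if not present:
        raise ValueError("no module genes present in the spatial panel")
    x = spatial[:, present].X
    sums = np.asarray(x.sum(axis=1)).ravel() if sp.issparse(x) else np.asarray(x).sum(axis=1)
    target = (spatial.obs["identity"].astype(str) == target_identity).to_numpy()
    values = np.where(target, sums, 0.0)
    sd = values.std()
    if sd == 0:
        warnings.warn("module feature map has zero variance; returning zeros", stacklevel=2)
        z = np.zeros_like(values)
    else:
        z = (values - values.mean()) / sd
    return pd.Series(np.clip(z, -1.0, 1.0), index=spatial.obs_names, name="module_z")
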