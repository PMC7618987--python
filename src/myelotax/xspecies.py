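"""Cross-species comparison of supercluster and cluster expression profiles:
ortholog merge, aggregate correlation with significance, bootstrap
gene-resampling stability, within-species supercluster similarity, and
downsampled cross-species flow tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

__all__ = [
    "CorrelationReport",
    "merge_on_orthologs",
    "correlate_groups",
    "bootstrap_stability",
    "supercluster_similarity",
    "cross_species_flow",
]


@dataclass
class CorrelationReport:
    """Pairwise correlation matrix with matching two-sided p-values."""

    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    method: str
    stability: pd.DataFrame | None = None

    def stars(self, thresholds: tuple[float, ...] = (0.01, 0.001, 0.0001)) -> pd.DataFrame:
        """Significance stars: one per threshold crossed (most to least strict)."""
        def mark(p: float) -> str:
            return "".join("*" for t in thresholds if p < t)
        return self.p_values.map(mark)


def classify_orthologs(orth: pd.DataFrame) -> pd.DataFrame:
    """Annotate each (source_gene, target_gene) row with its mapping class
    (one_to_one / one_to_many / many_to_many) from table multiplicities."""
    orth = orth.drop_duplicates(subset=["source_gene", "target_gene"]).copy()
    src_mult = orth.groupby("source_gene")["target_gene"].transform("size")
    tgt_mult = orth.groupby("target_gene")["source_gene"].transform("size")
    cls = np.where(
        (src_mult == 1) & (tgt_mult == 1),
        "one_to_one",
        np.where((src_mult > 1) & (tgt_mult > 1), "many_to_many", "one_to_many"),
    )
    orth["mapping_class"] = cls
    return orth


def merge_on_orthologs(
    a: AnnData,
    b: AnnData,
    orth: pd.DataFrame,
    strategy: str = "drop_non_one_to_one",
    min_shared: int = 50,
) -> AnnData:
    """Map species-b genes into species-a's namespace and concatenate on the
    shared gene space.

    `orth` has columns source_gene (b's namespace) and target_gene (a's).
    Under the default strategy only one-to-one mappings are used; dropped
    mappings are recorded in ``.uns['ortholog_merge']``. Raises when the
    shared space falls below `min_shared`."""
    if strategy not in ("drop_non_one_to_one", "keep_all"):
        raise ValueError(f"unknown strategy {strategy!r}")
    table = classify_orthologs(orth)
    dropped = table[table["mapping_class"] != "one_to_one"] if strategy == "drop_non_one_to_one" else table.iloc[0:0]
    used = table[table["mapping_class"] == "one_to_one"] if strategy == "drop_non_one_to_one" else table
    mapping = dict(zip(used["source_gene"], used["target_gene"]))

    b_mapped_names = [mapping.get(g) for g in b.var_names]
    keep_b = [i for i, g in enumerate(b_mapped_names) if g is not None]
    b_sub = b[:, keep_b].copy()
    b_sub.var_names = [b_mapped_names[i] for i in keep_b]

    shared = [g for g in a.var_names if g in set(b_sub.var_names)]
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes after ortholog mapping (floor {min_shared})")
    a_sub = a[:, shared].copy()
    b_sub = b_sub[:, shared].copy()
    import anndata as ad

    merged = ad.concat(
        [a_sub, b_sub], label="species_batch", keys=["a", "b"], index_unique="-"
    )
    merged.uns["ortholog_merge"] = {
        "n_shared": len(shared),
        "n_dropped_mappings": int(len(dropped)),
        "dropped_sources": sorted(dropped["source_gene"].unique().tolist()),
        "strategy": strategy,
    }
    return merged


def _pair_correlation(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def correlate_groups(
    a_profiles: pd.DataFrame, b_profiles: pd.DataFrame, method: str = "pearson"
) -> CorrelationReport:
    """Pairwise correlation between the columns of two gene x group matrices.

    Profiles must share their gene index; genes are inner-joined. Pairs with a
    zero-variance profile are reported as NaN."""
    genes = a_profiles.index.intersection(b_profiles.index)
    if len(genes) < 3:
        raise ValueError("need at least three shared genes")
    a_m = a_profiles.loc[genes]
    b_m = b_profiles.loc[genes]
    coefs = pd.DataFrame(index=a_m.columns, columns=b_m.columns, dtype=float)
    pvals = coefs.copy()
    for ca in a_m.columns:
        for cb in b_m.columns:
            r, p = _pair_correlation(a_m[ca].to_numpy(), b_m[cb].to_numpy(), method)
            coefs.loc[ca, cb] = r
            pvals.loc[ca, cb] = p
    return CorrelationReport(coefficients=coefs, p_values=pvals, method=method)


def bootstrap_stability(
    a_profiles: pd.DataFrame,
    b_profiles: pd.DataFrame,
    n_iter: int = 1000,
    gene_fraction: float = 0.8,
    seed: int = 0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Stability of each cross-group correlation under gene resampling.

    Each iteration draws floor(gene_fraction x G) genes without replacement
    and recomputes the correlation matrix; stability of a pair is the fraction
    of iterations where |r_boot| >= |r_obs| (1 = stable, 0 = unstable). An
    iteration with undefined r counts as not exceeding."""
    genes = a_profiles.index.intersection(b_profiles.index)
    n_draw = int(np.floor(gene_fraction * len(genes)))
    if n_draw < 3:
        raise ValueError("gene_fraction x n_genes must be at least 3")
    obs = correlate_groups(a_profiles, b_profiles, method=method).coefficients.to_numpy()
    rng = np.random.default_rng(seed)
    a_m = a_profiles.loc[genes].to_numpy()
    b_m = b_profiles.loc[genes].to_numpy()
    exceed = np.zeros_like(obs, dtype=float)
    for _ in range(n_iter):
        pick = rng.choice(len(genes), size=n_draw, replace=False)
        xa, xb = a_m[pick], b_m[pick]
        xa_c = xa - xa.mean(axis=0)
        xb_c = xb - xb.mean(axis=0)
        if method == "spearman":
            xa_c = stats.rankdata(xa, axis=0) - (n_draw + 1) / 2.0
            xb_c = stats.rankdata(xb, axis=0) - (n_draw + 1) / 2.0
        denom = np.outer(np.sqrt((xa_c**2).sum(axis=0)), np.sqrt((xb_c**2).sum(axis=0)))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_boot = (xa_c.T @ xb_c) / denom
        valid = np.isfinite(r_boot)
        exceed += np.where(valid & (np.abs(r_boot) >= np.abs(obs) - 1e-12), 1.0, 0.0)
    return pd.DataFrame(exceed / n_iter, index=a_profiles.columns, columns=b_profiles.columns)


def supercluster_similarity(profiles: pd.DataFrame) -> CorrelationReport:
    """Symmetric Spearman similarity between supercluster expression profiles.

    `profiles` is a gene x supercluster matrix of z-scored average expression;
    zero-variance genes are dropped before correlating."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least two superclusters")
    keep = profiles.std(axis=1, ddof=0) > 0
    pruned = profiles[keep]
    if pruned.shape[0] < 3:
        raise ValueError("fewer than three informative genes")
    return correlate_groups(pruned, pruned, method="spearman")


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` by the largest-remainder method."""
    if targets.sum() == 0:
        return np.zeros_like(targets, dtype=int)
    quota = targets / targets.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def cross_species_flow(
    a_cells: pd.DataFrame,
    b_cells: pd.DataFrame,
    min_link_fraction: float = 0.01,
    seed: int = 0,
    joint_column: str = "joint_cluster",
    label_column: str = "supercluster",
) -> pd.DataFrame:
    """Downsample species to equal size and emit cross-species link shares.

    Both frames need `label_column` (native supercluster/cluster label) and
    `joint_column` (shared co-embedding group). The larger species is randomly
    downsampled to the smaller's size while preserving its native cluster
    proportions (largest-remainder rounding). Link share between native labels
    bridges through joint groups:

        share(a, b) = sum_j P(a | j) P(b | j) P(j)

    Links below `min_link_fraction` are suppressed."""
    shared = set(a_cells[label_column]) & set(b_cells[label_column])
    if not shared:
        raise ValueError("species share no supercluster labels")
    rng = np.random.default_rng(seed)

    def downsample(cells: pd.DataFrame, n_target: int) -> pd.DataFrame:
        if len(cells) <= n_target:
            return cells
        groups = cells.groupby(label_column, observed=True, sort=True)
        sizes = groups.size()
        take = _largest_remainder(sizes.to_numpy(dtype=float), n_target)
        picked = []
        for (label, grp), n in zip(groups, take):
            idx = rng.choice(len(grp), size=n, replace=False)
            picked.append(grp.iloc[np.sort(idx)])
        return pd.concat(picked)

    n = min(len(a_cells), len(b_cells))
    a_ds = downsample(a_cells, n)
    b_ds = downsample(b_cells, n)

    pj_a = a_ds[joint_column].value_counts(normalize=True)
    pj_b = b_ds[joint_column].value_counts(normalize=True)
    joints = sorted(set(pj_a.index) | set(pj_b.index))
    pj = {j: (pj_a.get(j, 0.0) + pj_b.get(j, 0.0)) / 2.0 for j in joints}

    links: dict[tuple[str, str], float] = {}
    for j in joints:
        a_in = a_ds[a_ds[joint_column] == j]
        b_in = b_ds[b_ds[joint_column] == j]
        if a_in.empty or b_in.empty:
            continue
        pa = a_in[label_column].value_counts(normalize=True)
        pb = b_in[label_column].value_counts(normalize=True)
        for la, va in pa.items():
            for lb, vb in pb.items():
                links[(la, lb)] = links.get((la, lb), 0.0) + va * vb * pj[j]
    rows = [
        {"source_group": la, "target_group": lb, "share": share}
        for (la, lb), share in sorted(links.items())
        if share >= min_link_fraction
    ]
    return pd.DataFrame(rows, columns=["source_group", "target_group", "share"])
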