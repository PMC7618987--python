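"""Count-matrix data model, QC, normalization, aggregation and the Wilcoxon DEG test.

The in-memory container throughout the package is :class:`anndata.AnnData` with
cells as observations and genes as variables. Raw integer counts live in ``.X``
of a "count" AnnData; :func:`log_normalize` returns a new AnnData whose ``.X``
holds log-normalized values. Per-cell metadata (sample, condition, region,
species, cell_type, ...) lives in ``.obs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCRules",
    "apply_qc",
    "log_normalize",
    "zscore_genes",
    "aggregate_expression",
    "wilcoxon_deg",
    "mito_predicate",
    "ribo_predicate",
]


def mito_predicate(species: str = "human") -> Callable[[str], bool]:
    """Prefix rule flagging mitochondrially encoded genes ('MT-' / 'mt-')."""
    prefix = "MT-" if species == "human" else "mt-"
    return lambda g: g.startswith(prefix)


def ribo_predicate(species: str = "human") -> Callable[[str], bool]:
    """Prefix rule flagging ribosomal protein genes (RPS*/RPL*, case-insensitive)."""
    return lambda g: g.upper().startswith(("RPS", "RPL"))


@dataclass
class QCRules:
    """Cell-level quality-control thresholds.

    Presets mirror the three filtering regimes used for single-nucleus data,
    targeted spatial panels, and genome-wide binned spatial data.
    """

    min_features: int = 0
    max_mito_fraction: float = 1.0
    min_counts: int = 0
    drop_doublets: bool = False
    mito_gene_predicate: Callable[[str], bool] = field(default_factory=mito_predicate)

    def __post_init__(self) -> None:
        if self.min_features < 0 or self.min_counts < 0:
            raise ValueError("min_features and min_counts must be nonnegative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")

    @classmethod
    def snrna(cls, species: str = "human") -> "QCRules":
        """Single-nucleus preset: >=500 genes, <=10% mito, doublets dropped."""
        return cls(
            min_features=500,
            max_mito_fraction=0.10,
            drop_doublets=True,
            mito_gene_predicate=mito_predicate(species),
        )

    @classmethod
    def targeted_spatial(cls) -> "QCRules":
        """Targeted in-situ panel preset: >=5 features and >=10 counts per cell."""
        return cls(min_features=5, min_counts=10)

    @classmethod
    def genome_wide_spatial(cls, species: str = "human") -> "QCRules":
        """Genome-wide binned spatial preset: >=5 features, <=75% mito content."""
        return cls(
            min_features=5,
            max_mito_fraction=0.75,
            mito_gene_predicate=mito_predicate(species),
        )


def _counts_csr(adata: AnnData) -> sp.csr_matrix:
    x = adata.X
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


def apply_qc(adata: AnnData, rules: QCRules) -> AnnData:
    """Return the submatrix of cells passing every QC rule.

    The number of cells failing each rule (counted independently, so a cell may
    appear under several rules) is stored in ``.uns['qc_removed']`` of the
    returned object. Removing all cells is a warning, not an error.
    """
    x = _counts_csr(adata)
    n_features = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel()

    mito_mask = np.fromiter(
        (bool(rules.mito_gene_predicate(g)) for g in adata.var_names),
        dtype=bool,
        count=adata.n_vars,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0,
            np.asarray(x[:, mito_mask].sum(axis=1)).ravel() / np.maximum(totals, 1),
            0.0,
        )

    fail_features = n_features < rules.min_features
    fail_counts = totals < rules.min_counts
    fail_mito = mito_frac > rules.max_mito_fraction
    if rules.drop_doublets and "doublet_flag" in adata.obs:
        fail_doublet = adata.obs["doublet_flag"].astype(bool).to_numpy()
    else:
        fail_doublet = np.zeros(adata.n_obs, dtype=bool)

    keep = ~(fail_features | fail_counts | fail_mito | fail_doublet)
    report = {
        "min_features": int(fail_features.sum()),
        "min_counts": int(fail_counts.sum()),
        "max_mito_fraction": int(fail_mito.sum()),
        "doublets": int(fail_doublet.sum()),
        "removed_total": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    out = adata[keep].copy()
    out.uns["qc_removed"] = report
    return out


def log_normalize(adata: AnnData, scale_factor: float = 10_000.0) -> AnnData:
    """Library-size log normalization: x -> ln(1 + x / cell_total * scale_factor)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    x = _counts_csr(adata).astype(np.float64)
    totals = np.asarray(x.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = list(adata.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total counts cannot be normalized: {names}")
    scaled = sp.diags(scale_factor / totals) @ x
    scaled.data = np.log1p(scaled.data)
    out = AnnData(X=scaled.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["scale_factor"] = float(scale_factor)
    return out


def zscore_genes(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each gene (row) across columns using the population SD.

    Zero-variance genes are dropped and returned as the second element. Raises
    if fewer than two columns are supplied.
    """
    if profiles.shape[1] < 2:
        raise ValueError("z-scoring requires at least two columns")
    values = profiles.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    keep = sd.ravel() > 0
    dropped = list(profiles.index[~keep])
    z = (values[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=profiles.index[keep], columns=profiles.columns), dropped


def aggregate_expression(
    values: AnnData | pd.DataFrame,
    group_by: str | Sequence,
) -> pd.DataFrame:
    """Per-group per-gene mean of the input values; genes x groups.

    `values` may be an AnnData (groups from ``.obs[group_by]``) or a cells x
    genes DataFrame with an explicit label sequence. Empty groups cannot occur
    by construction (groups come from labels present on cells).
    """
    if isinstance(values, AnnData):
        labels = np.asarray(values.obs[group_by]) if isinstance(group_by, str) else np.asarray(group_by)
        x = values.X
        mat = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)
        genes = values.var_names
    else:
        labels = np.asarray(group_by)
        mat = values.to_numpy(dtype=float)
        genes = values.columns
    df = pd.DataFrame(mat, columns=genes)
    df["_group"] = labels
    agg = df.groupby("_group", observed=True).mean().T
    agg.columns.name = None
    return agg


def _rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per column (gene); normal approximation
    with tie correction and continuity correction."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    return np.atleast_1d(res.pvalue)


def wilcoxon_deg(
    adata: AnnData,
    group_by: str,
    mode: str = "one_vs_rest",
    pair: tuple[str, str] | None = None,
    exclude: Iterable[Callable[[str], bool]] = (),
    min_cells: int = 3,
) -> pd.DataFrame:
    """Differential expression by two-sided Wilcoxon rank-sum test.

    Parameters
    ----------
    adata
        Log-normalized expression (output of :func:`log_normalize`).
    group_by
        ``.obs`` column holding group labels.
    mode
        ``"one_vs_rest"`` tests every group against all remaining cells;
        ``"pairwise"`` tests ``pair[0]`` against ``pair[1]``.
    exclude
        Gene predicates (e.g. mito/ribo prefix rules) removed before testing.
    min_cells
        Groups smaller than this are skipped with a warning.

    Returns a table with columns gene, group, log2_fold_change, p_value,
    p_adjusted (BH within each group's test family), pct_in, pct_out.
    """
    labels = np.asarray(adata.obs[group_by].astype(str))
    gene_mask = np.ones(adata.n_vars, dtype=bool)
    for pred in exclude:
        gene_mask &= ~np.fromiter((bool(pred(g)) for g in adata.var_names), bool, adata.n_vars)
    genes = np.asarray(adata.var_names)[gene_mask]
    x = adata.X[:, gene_mask]
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)

    if mode == "pairwise":
        if pair is None:
            raise ValueError("pairwise mode requires pair=(a, b)")
        contrasts = [(pair[0], labels == pair[0], labels == pair[1])]
    elif mode == "one_vs_rest":
        contrasts = [(g, labels == g, labels != g) for g in sorted(set(labels))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    frames = []
    for name, in_mask, out_mask in contrasts:
        if in_mask.sum() < min_cells or out_mask.sum() < min_cells:
            warnings.warn(f"group {name!r} has fewer than {min_cells} cells; skipped", stacklevel=2)
            continue
        a, b = dense[in_mask], dense[out_mask]
        pvals = _rank_sum_pvalues(a, b)
        m_in = np.expm1(a).mean(axis=0)
        m_out = np.expm1(b).mean(axis=0)
        lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "group": name,
                    "log2_fold_change": lfc,
                    "p_value": pvals,
                    "p_adjusted": multipletests(pvals, method="fdr_bh")[1],
                    "pct_in": (a > 0).mean(axis=0),
                    "pct_out": (b > 0).mean(axis=0),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene", "group", "log2_fold_change", "p_value", "p_adjusted", "pct_in", "pct_out"]
        )
    return pd.concat(frames, ignore_index=True)
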