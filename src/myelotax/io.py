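"""Readers and writers for the on-disk interchange formats.

Count matrices follow the 10x convention: MatrixMarket ``matrix.mtx`` with
genes as rows and cells as columns, plus ``features.tsv`` / ``barcodes.tsv``
and a cell-metadata CSV keyed by barcode. Spatial tables, DEG tables and
taxonomy summaries travel as CSV.
"""

from __future__ import annotations

import os

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["write_count_matrix", "read_count_matrix"]

META_COLUMNS = ["sample", "condition", "region", "species", "cell_type"]


def write_count_matrix(adata: AnnData, outdir: str) -> None:
    """Write cells x genes AnnData as genes x cells MTX + TSVs + metadata CSV."""
    os.makedirs(outdir, exist_ok=True)
    x = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), x.T.tocoo(), field="integer")
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    adata.obs.to_csv(os.path.join(outdir, "metadata.csv"), index_label="cell_id")


def read_count_matrix(indir: str) -> AnnData:
    """Read the MTX + features/barcodes + metadata layout back into AnnData."""
    x = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0].astype(str)
    meta_path = os.path.join(indir, "metadata.csv")
    if os.path.exists(meta_path):
        obs = pd.read_csv(meta_path, index_col="cell_id")
        obs.index = obs.index.astype(str)
        obs = obs.reindex(cells)
    else:
        obs = pd.DataFrame(index=cells)
    obs.index.name = None
    return AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name=None)))
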