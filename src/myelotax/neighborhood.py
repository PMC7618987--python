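"""Spatial neighborhood interaction statistics and the identity interaction network.

For every cell, neighbors are all other cells within a fixed radius (default
100 µm, boundary inclusive). The directed interaction proportion from identity
A to identity B is

    Proportion(A -> B) = [ sum over A cells of #B neighbors
                           / sum over A cells of #total neighbors ]
                         / (N_A x N_B) x 100

i.e. the pooled fraction of B among neighbors of A cells, normalized by the
product of identity abundances and expressed as a percent. The undirected
network averages the two directed proportions per pair; identities with no
edges remain as zero-degree nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NeighborhoodConfig",
    "compute_neighborhoods",
    "interaction_proportion",
    "build_interaction_network",
]


@dataclass(frozen=True)
class NeighborhoodConfig:
    radius_um: float = 100.0
    min_cells_per_identity: int = 3
    unit_scale: float = 1.0  # multiply raw coordinates to obtain µm

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.unit_scale <= 0:
            raise ValueError("radius_um and unit_scale must be positive")
        if self.min_cells_per_identity < 1:
            raise ValueError("min_cells_per_identity must be >= 1")


def _filtered(cells: pd.DataFrame, cfg: NeighborhoodConfig) -> pd.DataFrame:
    counts = cells["identity"].value_counts()
    keep = counts[counts >= cfg.min_cells_per_identity].index
    out = cells[cells["identity"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no identities survive the min-cells filter")
    return out


def compute_neighborhoods(
    cells: pd.DataFrame, cfg: NeighborhoodConfig = NeighborhoodConfig()
) -> tuple[pd.DataFrame, list[np.ndarray], np.ndarray]:
    """Neighbor lists within radius (self excluded, distance <= radius counts).

    `cells` needs columns x_um, y_um, identity. Identities with fewer than
    `min_cells_per_identity` cells are removed before analysis. Returns the
    filtered table, per-cell neighbor index arrays, and the pairwise distance
    matrix of the filtered cells."""
    if len(cells) < 2:
        raise ValueError("at least two cells are required")
    cells = _filtered(cells, cfg)
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float) * cfg.unit_scale
    tree = cKDTree(xy)
    pairs = tree.query_ball_tree(tree, r=cfg.radius_um)
    neighbors = [np.array([j for j in row if j != i], dtype=int) for i, row in enumerate(pairs)]
    dists = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    return cells, neighbors, dists


def interaction_proportion(
    cells: pd.DataFrame,
    neighbors: list[np.ndarray],
    dists: np.ndarray,
    a: str,
    b: str,
) -> tuple[float, float]:
    """Directed interaction proportion A->B (percent) and the mean A->B
    neighbor distance in µm (NaN when no A cell has a B neighbor)."""
    ident = cells["identity"].to_numpy()
    a_idx = np.flatnonzero(ident == a)
    b_set = ident == b
    n_a, n_b = a_idx.size, int(b_set.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"identity {a!r} or {b!r} absent after filtering")
    b_neigh = 0
    total_neigh = 0
    pair_dists: list[float] = []
    for i in a_idx:
        nb = neighbors[i]
        total_neigh += nb.size
        hits = nb[b_set[nb]]
        b_neigh += hits.size
        pair_dists.extend(dists[i, hits].tolist())
    if total_neigh == 0:
        return 0.0, float("nan")
    proportion = (b_neigh / total_neigh) / (n_a * n_b) * 100.0
    mean_dist = float(np.mean(pair_dists)) if pair_dists else float("nan")
    return proportion, mean_dist


def build_interaction_network(
    cells: pd.DataFrame,
    cfg: NeighborhoodConfig = NeighborhoodConfig(),
    identity_column: str = "identity",
) -> nx.Graph:
    """Undirected identity interaction network.

    Directed proportions are computed for every ordered identity pair and
    symmetrized by averaging A->B and B->A; mean distances are averaged over
    the directions that have neighbor pairs. Nodes carry n_cells and every
    identity (even edge-less ones) is present."""
    work = cells.rename(columns={identity_column: "identity"}) if identity_column != "identity" else cells
    filtered, neighbors, dists = compute_neighborhoods(work, cfg)
    identities = sorted(filtered["identity"].unique())
    g = nx.Graph()
    for ident in identities:
        g.add_node(ident, n_cells=int((filtered["identity"] == ident).sum()))
    for i, a in enumerate(identities):
        for b in identities[i:]:
            p_ab, d_ab = interaction_proportion(filtered, neighbors, dists, a, b)
            p_ba, d_ba = interaction_proportion(filtered, neighbors, dists, b, a)
            prop = (p_ab + p_ba) / 2.0
            ds = [d for d in (d_ab, d_ba) if np.isfinite(d)]
            if prop > 0:
                g.add_edge(a, b, proportion_percent=prop,
                           mean_distance_um=float(np.mean(ds)) if ds else float("nan"))
    return g


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    """Flat edge table (identity_a, identity_b, proportion_percent, mean_distance_um)."""
    rows = [
        {"identity_a": a, "identity_b": b, **attrs}
        for a, b, attrs in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["identity_a", "identity_b", "proportion_percent", "mean_distance_um"])
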