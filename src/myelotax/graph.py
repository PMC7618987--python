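"""Cell–cell kNN graph construction, Paris hierarchical graph clustering,
dendrogram cutting, and DEG-driven merging of under-supported clusters.

Paris agglomerates graph nodes under the node-pair sampling distance

    d(a, b) = p(a) p(b) / p(a, b)

where p(a, b) is the fraction of total edge weight between clusters a and b
and p(a) the weighted-degree fraction of a. At every step the connected pair
with minimal distance merges (ties broken by the lexicographically smallest
cluster-id pair); merge distances are recorded as dendrogram heights.
Disconnected components are clustered independently and joined under an
infinite-height root.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from .expression import wilcoxon_deg

__all__ = [
    "CellGraph",
    "Dendrogram",
    "build_knn_graph",
    "paris_cluster",
    "cut_dendrogram",
    "merge_weak_clusters",
]

#: shared-neighbor edges weaker than this Jaccard overlap are pruned
SNN_PRUNE_CUTOFF = 1.0 / 15.0


@dataclass
class CellGraph:
    """Weighted undirected shared-nearest-neighbor graph over cells."""

    nodes: list[str]
    weights: sp.csr_matrix  # symmetric, zero diagonal
    n_neighbors: int
    n_components_used: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class Dendrogram:
    """Merge list in scipy-linkage convention.

    ``merges`` has one row (left_id, right_id, height, size) per merge; leaves
    are ids 0..n-1, the i-th merge creates id n+i. Heights are the Paris merge
    distances; joins across disconnected components carry height ``inf``.
    """

    merges: np.ndarray  # (n-1, 4) float
    leaf_names: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (int(l), int(r)) for i, (l, r, _, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf ids from depth-first traversal of the root(s)."""
        kids = self.children()
        n = self.n_leaves
        root = n + len(self.merges) - 1 if len(self.merges) else 0
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                left, right = kids[node]
                stack.append(right)
                stack.append(left)
        return order

    def to_newick(self, inf_height: float | None = None) -> str:
        """Newick string with heights as branch lengths.

        Infinite heights (component joins) are written as twice the largest
        finite height (or 1.0 if none), controllable via ``inf_height``.
        """
        finite = [h for h in self.merges[:, 2] if math.isfinite(h)]
        cap = inf_height if inf_height is not None else (2.0 * max(finite) if finite else 1.0)
        heights = {self.n_leaves + i: (h if math.isfinite(h) else cap) for i, h in enumerate(self.merges[:, 2])}
        kids = self.children()

        def node_height(i: int) -> float:
            return heights.get(i, 0.0)

        def render(i: int, parent_h: float) -> str:
            bl = max(parent_h - node_height(i), 0.0)
            if i < self.n_leaves:
                return f"{self.leaf_names[i]}:{bl:.6g}"
            l, r = kids[i]
            return f"({render(l, node_height(i))},{render(r, node_height(i))}):{bl:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        l, r = kids[root]
        h = node_height(root)
        return f"({render(l, h)},{render(r, h)});"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])


def build_knn_graph(embedding: np.ndarray, k: int, prune: float = SNN_PRUNE_CUTOFF,
                    node_names: list[str] | None = None) -> CellGraph:
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets, pruned.

    Each cell's neighbor set is itself plus its `k` nearest other cells
    (Euclidean in the embedding). An edge joins cells i, j when either is in
    the other's set, weighted by |S_i ∩ S_j| / |S_i ∪ S_j|; weights below
    `prune` are dropped. The result is symmetric with no self-loops.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if embedding.ndim != 2 or embedding.shape[1] < 1:
        raise ValueError("embedding must be a 2-D cells x dims matrix")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    # neighbor set = the cell itself plus its k nearest others
    sets = []
    for i in range(n):
        others = [int(j) for j in idx[i] if j != i][:k]
        sets.append(frozenset([i, *others]))

    pairs = {(min(i, j), max(i, j)) for i in range(n) for j in sets[i] if j != i}
    rows, cols, vals = [], [], []
    for i, j in sorted(pairs):
        w = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
        if w >= prune:
            rows.append(i)
            cols.append(j)
            vals.append(w)
    w = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    w = (w + w.T).tocsr()
    names = node_names if node_names is not None else [str(i) for i in range(n)]
    return CellGraph(nodes=list(names), weights=w, n_neighbors=k,
                     n_components_used=embedding.shape[1])


def paris_cluster(g: CellGraph) -> Dendrogram:
    """Agglomerative dendrogram under the Paris node-pair sampling distance."""
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    w = g.weights.tocoo()

    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i, j, v in zip(w.row, w.col, w.data):
        if i < j and v > 0:
            adj[i][j] = adj[i].get(j, 0.0) + v
            adj[j][i] = adj[j].get(i, 0.0) + v
    deg = {i: sum(adj[i].values()) for i in range(n)}
    total = sum(deg.values())  # = 2 x total edge weight

    def dist(a: int, b: int, wab: float) -> float:
        if total == 0 or wab <= 0:
            return math.inf
        return (deg[a] * deg[b]) / (total * wab)

    heap: list[tuple[float, int, int]] = []
    for a in range(n):
        for b, wab in adj[a].items():
            if a < b:
                heapq.heappush(heap, (dist(a, b, wab), a, b))

    alive = set(range(n))
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    while heap:
        d, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue
        new = next_id
        next_id += 1
        alive.discard(a)
        alive.discard(b)
        nbrs: dict[int, float] = {}
        for src in (a, b):
            for c, wc in adj[src].items():
                if c in alive:
                    nbrs[c] = nbrs.get(c, 0.0) + wc
        adj[new] = nbrs
        for c, wc in nbrs.items():
            adj[c][new] = wc
        deg[new] = deg[a] + deg[b]
        sizes[new] = sizes[a] + sizes[b]
        merges.append((a, b, d, sizes[new]))
        alive.add(new)
        for c, wc in nbrs.items():
            lo, hi = (c, new) if c < new else (new, c)
            heapq.heappush(heap, (dist(lo, hi, wc), lo, hi))

    # join remaining (disconnected) components under an infinite-height root
    remaining = sorted(alive)
    while len(remaining) > 1:
        a, b = remaining[0], remaining[1]
        new = next_id
        next_id += 1
        sizes[new] = sizes[a] + sizes[b]
        merges.append((a, b, math.inf, sizes[new]))
        remaining = [new] + remaining[2:]

    return Dendrogram(merges=np.array(merges, dtype=float).reshape(-1, 4), leaf_names=list(g.nodes))


def _cluster_members(d: Dendrogram, n_keep_merges: int) -> list[list[int]]:
    """Leaf sets of the clusters obtained by keeping the first merges only."""
    n = d.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i in range(n_keep_merges):
        l, r, _, _ = d.merges[i]
        new = n + i
        members[new] = members.pop(int(l)) + members.pop(int(r))
    return list(members.values())


def cut_dendrogram(d: Dendrogram, n_clusters: int | None = None,
                   height_gap: bool = False, max_clusters: int | None = None) -> pd.Series:
    """Cut to a flat clustering; labels follow dendrogram leaf order.

    Either request `n_clusters` exactly, or set `height_gap=True` to pick the
    cut whose undone merge sits above the largest relative height gap
    (infinite component-join heights are ignored when searching the gap).
    """
    m = len(d.merges)
    n = d.n_leaves
    if height_gap:
        heights = d.merges[:, 2]
        best_ratio, best_k = -1.0, 1
        for i in range(m - 1):
            h0, h1 = heights[i], heights[i + 1]
            if not (math.isfinite(h0) and math.isfinite(h1)) or h0 <= 0:
                continue
            k = m - i  # undoing merges i+1..m-1 leaves m - i clusters
            if max_clusters is not None and k > max_clusters:
                continue
            ratio = h1 / h0
            if ratio > best_ratio:
                best_ratio, best_k = ratio, k
        n_clusters = best_k
    if n_clusters is None:
        raise ValueError("provide n_clusters or height_gap=True")
    if n_clusters > n:
        raise ValueError(f"cannot cut {n} leaves into {n_clusters} clusters")
    groups = _cluster_members(d, m - (n_clusters - 1))
    # order labels by leaf order
    order = d.leaf_order()
    pos = {leaf: p for p, leaf in enumerate(order)}
    groups.sort(key=lambda g: min(pos[x] for x in g))
    labels = np.empty(n, dtype=int)
    for lab, grp in enumerate(groups):
        for leaf in grp:
            labels[leaf] = lab
    return pd.Series(labels, index=d.leaf_names, name="cluster")


def _nearest_sibling(d: Dendrogram, assignment: pd.Series) -> dict[int, int]:
    """For each cluster, the cluster it first joins in the dendrogram.

    Replays the merge list over leaves; the first merge uniting leaves of
    cluster c with leaves of any other cluster defines c's sibling. When the
    joining group holds several clusters, the one nearest to c in leaf order
    is chosen (nearest leaf-set sibling).
    """
    n = d.n_leaves
    leaf_cluster = assignment.reindex(d.leaf_names).to_numpy()
    order = d.leaf_order()
    # mean leaf-order position per cluster, for the nearest-in-order tie rule
    pos = {leaf: p for p, leaf in enumerate(order)}
    cpos: dict[int, float] = {}
    for c in np.unique(leaf_cluster):
        cpos[int(c)] = float(np.mean([pos[i] for i in range(n) if leaf_cluster[i] == c]))

    groups: dict[int, set[int]] = {i: {int(leaf_cluster[i])} for i in range(n)}
    sibling: dict[int, int] = {}
    for i, (l, r, _, _) in enumerate(d.merges):
        gl, gr = groups.pop(int(l)), groups.pop(int(r))
        for c in gl:
            if c not in sibling and (gr - {c}):
                sibling[c] = min(gr - {c}, key=lambda s: (abs(cpos[s] - cpos[c]), s))
        for c in gr:
            if c not in sibling and (gl - {c}):
                sibling[c] = min(gl - {c}, key=lambda s: (abs(cpos[s] - cpos[c]), s))
        groups[n + i] = gl | gr
    return sibling


def merge_weak_clusters(
    adata: AnnData,
    assignment: pd.Series,
    dendrogram: Dendrogram,
    min_cells: int = 20,
    min_degs: int = 5,
    p_adj_max: float = 0.05,
    lfc_min: float = 0.25,
) -> tuple[pd.Series, list[dict]]:
    """Iteratively merge clusters that are too small or lack DEG support.

    A cluster with fewer than `min_cells` cells, or with fewer than `min_degs`
    genes passing (p_adjusted < `p_adj_max` and |log2FC| >= `lfc_min`) against
    its nearest dendrogram sibling, is merged into that sibling; repeated to a
    fixed point. `adata` must carry log-normalized values (``.uns`` has
    ``scale_factor``); raw counts are accepted and normalized on the fly.

    Returns the relabeled assignment (contiguous labels in leaf order) and the
    merge log.
    """
    from .expression import log_normalize

    if "scale_factor" not in adata.uns:
        adata = log_normalize(adata)
    labels = assignment.copy()
    log: list[dict] = []

    def deg_count(cells_a: pd.Index, cells_b: pd.Index) -> int:
        sub = adata[list(cells_a) + list(cells_b)].copy()
        sub.obs["_grp"] = ["a"] * len(cells_a) + ["b"] * len(cells_b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = wilcoxon_deg(sub, "_grp", mode="pairwise", pair=("a", "b"))
        hits = (table["p_adjusted"] < p_adj_max) & (table["log2_fold_change"].abs() >= lfc_min)
        return int(hits.sum())

    changed = True
    while changed:
        changed = False
        counts = labels.value_counts()
        if len(counts) <= 1:
            break
        siblings = _nearest_sibling(dendrogram, labels)
        for c in sorted(counts.index, key=lambda c: (counts[c], c)):
            sib = siblings.get(int(c))
            if sib is None:
                continue
            cells_c = labels.index[labels == c]
            reason = None
            if counts[c] < min_cells:
                reason = "min_cells"
            else:
                cells_s = labels.index[labels == sib]
                if deg_count(cells_c, cells_s) < min_degs:
                    reason = "min_degs"
            if reason:
                labels[labels == c] = sib
                log.append({"merged": int(c), "into": int(sib), "reason": reason})
                changed = True
                break

    # renumber contiguously in dendrogram leaf order
    order = dendrogram.leaf_order()
    seen: dict[int, int] = {}
    for leaf in order:
        c = int(labels.loc[dendrogram.leaf_names[leaf]])
        if c not in seen:
            seen[c] = len(seen)
    return labels.map(seen).rename("cluster"), log
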