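import numpy as np
import pandas as pd
import pytest

from myelotax.simulate import ProgramSpec, generate_count_matrix, load_fixture_modules


@pytest.fixture(scope="session")
def three_program_counts():
    """3 planted programs x 200 cells, fold 8 over a 0.5 baseline."""
    programs = [
        ProgramSpec(f"P{i}", tuple(f"G{i}_{j}" for j in range(6)), fold_change=8.0)
        for i in range(3)
    ]
    return generate_count_matrix(programs, 200, 100, seed=7), programs


@pytest.fixture(scope="session")
def eight_program_counts():
    """The study-scale synthetic dataset: the eight packaged supercluster
    modules as planted programs, 150 cells each, fold 8."""
    modules = load_fixture_modules("human")
    programs = [
        ProgramSpec(name, tuple(genes), fold_change=8.0) for name, genes in modules.items()
    ]
    adata = generate_count_matrix(programs, 150, 300, seed=11)
    return adata, modules


@pytest.fixture(scope="session")
def eight_program_clustering(eight_program_counts):
    """Full clustering of the eight-program dataset (shared: it is the slow step)."""
    import scipy.sparse as sp

    from myelotax.expression import log_normalize
    from myelotax.graph import build_knn_graph, cut_dendrogram, merge_weak_clusters, paris_cluster
    from myelotax.pipeline import _pca

    adata, modules = eight_program_counts
    norm = log_normalize(adata)
    dense = np.asarray(norm.X.todense()) if sp.issparse(norm.X) else np.asarray(norm.X)
    emb = _pca(dense, 30, 0)
    graph = build_knn_graph(emb, k=20, node_names=list(norm.obs_names))
    dend = paris_cluster(graph)
    assignment, _ = merge_weak_clusters(norm, cut_dendrogram(dend, n_clusters=16), dend)
    return adata, norm, modules, dend, assignment


def paris_oracle(n, edges):
    """Exhaustive greedy agglomeration under d(a,b) = p(a)p(b)/p(a,b).

    Independent of the package implementation: recomputes all pairwise
    cluster distances at every step and merges the minimum (lexicographic
    tie-break). Returns the merge list [(a, b, dist)]."""
    adj = {i: {} for i in range(n)}
    for i, j, w in edges:
        adj[i][j] = adj[i].get(j, 0) + w
        adj[j][i] = adj[j].get(i, 0) + w
    deg = {i: sum(adj[i].values()) for i in range(n)}
    total = sum(deg.values())
    alive = set(range(n))
    merges = []
    nxt = n
    while True:
        best = None
        for a in sorted(alive):
            for b in sorted(adj[a]):
                if b <= a or b not in alive:
                    continue
                d = (deg[a] * deg[b]) / (total * adj[a][b])
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        if best is None:
            break
        d, a, b = best
        merged = {}
        for src in (a, b):
            for c, w in adj[src].items():
                if c in alive and c not in (a, b):
                    merged[c] = merged.get(c, 0) + w
        alive -= {a, b}
        adj[nxt] = merged
        for c, w in merged.items():
            adj[c][nxt] = w
        deg[nxt] = deg[a] + deg[b]
        merges.append((a, b, d))
        alive.add(nxt)
        nxt += 1
    return merges


@pytest.fixture(scope="session")
def random_graph_suite():
    """Fixed suite of 100 random connected weighted graphs with <=10 nodes."""
    rng = np.random.default_rng(2024)
    graphs = []
    while len(graphs) < 100:
        n = int(rng.integers(3, 11))
        p = rng.uniform(0.3, 0.9)
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    edges.append((i, j, float(np.round(rng.uniform(0.1, 2.0), 3))))
        # connectivity check
        if not edges:
            continue
        seen = {0}
        frontier = [0]
        adj = {i: [] for i in range(n)}
        for i, j, _ in edges:
            adj[i].append(j)
            adj[j].append(i)
        while frontier:
            u = frontier.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        if len(seen) == n:
            graphs.append((n, edges))
    return graphs
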