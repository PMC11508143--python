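"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
they verify: centralities come from hand-rolled all-pairs BFS with
shortest-path counting rather than networkx/igraph, TOM from a triple loop,
Pearson correlation from the two-pass textbook formula, and the
hypergeometric tail from explicit enumeration of the pmf.
"""

from __future__ import annotations

from collections import deque
from math import comb

import numpy as np


def bfs_distances(adj: dict, source):
    """Unweighted single-source distances and shortest-path counts."""
    dist = {source: 0}
    sigma = {source: 1}
    order = []
    q = deque([source])
    while q:
        u = q.popleft()
        order.append(u)
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma, order


def centralities_bruteforce(edges, nodes=None):
    """DG, BW, CN, CC for an undirected simple graph given as an edge list.

    BW is normalized by (n_c-1)(n_c-2)/2 within each connected component of
    size n_c; CN is (n_c-1)/sum of distances within the component; CC is the
    triangle-based local clustering coefficient.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if nodes is not None:
        for n in nodes:
            adj.setdefault(n, set())
    nodes = list(adj)
    dg = {u: len(adj[u]) for u in nodes}

    cc = {}
    for u in nodes:
        k = dg[u]
        if k < 2:
            cc[u] = 0.0
            continue
        nbrs = list(adj[u])
        tri = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if nbrs[j] in adj[nbrs[i]]
        )
        cc[u] = 2.0 * tri / (k * (k - 1))

    # connected components
    seen, comps = set(), []
    for u in nodes:
        if u in seen:
            continue
        dist, _, _ = bfs_distances(adj, u)
        comp = list(dist)
        seen.update(comp)
        comps.append(comp)

    bw = {u: 0.0 for u in nodes}
    cn = {u: 0.0 for u in nodes}
    for comp in comps:
        nc = len(comp)
        if nc == 1:
            continue
        dists = {}
        sigmas = {}
        for s in comp:
            d, sg, _ = bfs_distances(adj, s)
            dists[s] = d
            sigmas[s] = sg
        for v in comp:
            cn[v] = (nc - 1) / sum(dists[v][u] for u in comp)
        if nc < 3:
            continue
        norm = (nc - 1) * (nc - 2) / 2.0
        for v in comp:
            acc = 0.0
            for i, s in enumerate(comp):
                if s == v:
                    continue
                for t in comp[i + 1:]:
                    if t == v or s == v:
                        continue
                    if dists[s][v] + dists[v][t] == dists[s][t]:
                        acc += sigmas[s][v] * sigmas[v][t] / sigmas[s][t]
            bw[v] = acc / norm
    return dg, bw, cn, cc


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of an adjacency matrix."""
    n = a.shape[0]
    t = np.ones((n, n))
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def pearson_bruteforce(x: np.ndarray) -> np.ndarray:
    """Two-pass covariance / std-product Pearson correlation (genes x samples)."""
    n_genes, n_samples = x.shape
    mu = x.mean(axis=1)
    r = np.ones((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            di, dj = x[i] - mu[i], x[j] - mu[j]
            r[i, j] = r[j, i] = (di * dj).sum() / np.sqrt(
                (di**2).sum() * (dj**2).sum()
            )
    return r


def hypergeom_tail_bruteforce(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct pmf summation: X ~ Hypergeometric(N, K, n)."""
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / total
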