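"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: spatial components
are found by BFS over pairwise 26-adjacency (not scipy.ndimage), FDR by
the definitional step-up minimum, partial correlation by the
precision-matrix identity.
"""

import numpy as np


def bfs_components(coords: np.ndarray) -> np.ndarray:
    """26-connectivity components by breadth-first search over voxel pairs."""
    n = len(coords)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(coords[i] - coords[j])) <= 1:
                adj[i].append(j)
                adj[j].append(i)
    comp = np.full(n, -1, dtype=int)
    c = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        queue = [start]
        comp[start] = c
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if comp[v] < 0:
                    comp[v] = c
                    queue.append(v)
        c += 1
    return comp


def brute_force_fc_clusters(edges, z_values, coords):
    """Exhaustive FC-cluster formation on supra-threshold edges.

    ``edges``: (i, j) voxel-row pairs already above threshold; ``coords``
    indexed by voxel row. Returns (clusters, intra) where each cluster is
    a frozenset of edges and intra is the set of within-component edges.
    """
    involved = sorted({v for e in edges for v in e})
    pos = {v: k for k, v in enumerate(involved)}
    comp = bfs_components(np.asarray([coords[v] for v in involved]))
    groups, intra = {}, set()
    for (i, j), z in zip(edges, z_values):
        ci, cj = comp[pos[i]], comp[pos[j]]
        if ci == cj:
            intra.add((i, j))
            continue
        groups.setdefault((min(ci, cj), max(ci, cj)), set()).add((i, j))
    return {frozenset(g) for g in groups.values()}, intra


def stepup_fdr(p: np.ndarray) -> np.ndarray:
    """Definitional Benjamini-Hochberg: q_i = min over j with p_j >= p_i
    of m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        best = min(best, m * p[idx] / rank)
        q[idx] = min(best, 1.0)
    return q


def precision_partial_corr(x, y, covs):
    """Partial correlation from the inverse correlation matrix."""
    mat = np.column_stack([x, y, covs])
    prec = np.linalg.inv(np.corrcoef(mat, rowvar=False))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


def random_cluster_instance(rng, max_voxels=30, grid=6):
    """A random small FC-cluster problem: voxels, supra edges, z values."""
    n = rng.integers(4, max_voxels + 1)
    all_coords = np.stack(
        np.unravel_index(np.arange(grid**3), (grid, grid, grid)), axis=1
    )
    rows = rng.choice(grid**3, size=n, replace=False)
    coords = all_coords[rows]
    n_edges = int(rng.integers(0, n * (n - 1) // 2 + 1) * 0.3) + 1
    pairs = set()
    for _ in range(n_edges):
        i, j = rng.choice(n, 2, replace=False)
        pairs.add((min(i, j), max(i, j)))
    edges = sorted(pairs)
    # all edges are meant to be supra-threshold: keep |z| well above any CDT
    z = (5.0 + np.abs(rng.normal(0, 1, len(edges)))) * rng.choice(
        [-1, 1], len(edges))
    return coords, edges, z
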