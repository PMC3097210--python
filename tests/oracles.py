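"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the motif oracle is a
character-by-character sliding window, the alignment oracle a from-scratch
Gotoh DP, the tree oracle an exhaustive enumeration of unrooted topologies
with least-squares branch fitting, and the cluster oracle a transitive
closure over the pair relation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Motif scanning


def naive_motif_scan(sequence: str, pattern: str) -> list[int]:
    """1-based start positions where the degenerate pattern matches;
    X in the pattern matches any standard residue or X, fixed positions
    match only themselves (never a sequence X)."""
    out = []
    for start in range(len(sequence) - len(pattern) + 1):
        ok = True
        for k, pc in enumerate(pattern):
            sc = sequence[start + k]
            if pc == "X":
                if sc not in STANDARD and sc != "X":
                    ok = False
                    break
            elif sc != pc:
                ok = False
                break
        if ok:
            out.append(start + 1)
    return out


# ---------------------------------------------------------------------------
# Global alignment score (affine gaps, Gotoh)


def gotoh_score(a: str, b: str, score, gap_open: float = -10.0,
                gap_extend: float = -1.0) -> float:
    """Optimal global alignment score; a length-k gap costs
    gap_open + (k-1)*gap_extend. ``score(x, y)`` gives substitution scores."""
    n, m = len(a), len(b)
    NEG = -1e30
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# Exhaustive unrooted topologies + least-squares branch fit

# A topology is a list of edges (u, v); leaves are taxon-name strings and
# internal nodes are negative integers.


def enumerate_topologies(taxa: list[str]):
    """All unrooted binary topologies over the taxa (3 -> 1, 4 -> 3,
    5 -> 15, 6 -> 105)."""
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    base = [(taxa[0], -1), (taxa[1], -1), (taxa[2], -1)]
    stack = [(base, 3, -2)]
    while stack:
        edges, k, next_internal = stack.pop()
        if k == len(taxa):
            yield edges
            continue
        taxon = taxa[k]
        for idx, (u, v) in enumerate(edges):
            new_node = next_internal
            new_edges = edges[:idx] + edges[idx + 1 :]
            new_edges += [(u, new_node), (v, new_node), (taxon, new_node)]
            stack.append((new_edges, k + 1, next_internal - 1))


def _paths(edges, taxa):
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}

    def path_edges(src, dst):
        stack = [(src, None, [])]
        while stack:
            node, prev, acc = stack.pop()
            if node == dst:
                return acc
            for nxt in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, acc + [edge_index[frozenset((node, nxt))]]))
        raise RuntimeError("disconnected topology")

    rows = []
    for a, b in itertools.combinations(taxa, 2):
        row = np.zeros(len(edges))
        for e in path_edges(a, b):
            row[e] = 1.0
        rows.append(row)
    return np.array(rows)


def ls_fit(edges, taxa, dist_lookup) -> float:
    """Least-squares branch-length fit; returns the residual sum of squares."""
    A = _paths(edges, taxa)
    d = np.array([dist_lookup(a, b) for a, b in itertools.combinations(taxa, 2)])
    sol, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = A @ sol - d
    return float(resid @ resid)


def topology_bipartitions(edges, taxa) -> set[frozenset[str]]:
    """Non-trivial bipartitions induced by internal edges, canonicalized to
    the side without the alphabetically first taxon."""
    taxa_set = set(taxa)
    ref = min(taxa_set)
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u, v):
        seen = {v, u}
        stack = [u]
        tips = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                tips.add(node)
            for nxt in adj[node]:
                if nxt not in seen or nxt == v:
                    pass
                if nxt != v and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return tips

    parts = set()
    for u, v in edges:
        if isinstance(u, str) or isinstance(v, str):
            continue
        tips = side(u, v)
        if len(tips) < 2 or len(taxa_set - tips) < 2:
            continue
        if ref in tips:
            tips = taxa_set - tips
        parts.add(frozenset(tips))
    return parts


def best_ls_topology(taxa, dist_lookup) -> set[frozenset[str]]:
    """Bipartitions of the minimum-SSQ topology over the exhaustive scan."""
    best = None
    best_parts = None
    for edges in enumerate_topologies(list(taxa)):
        ssq = ls_fit(edges, taxa, dist_lookup)
        if best is None or ssq < best - 1e-12:
            best = ssq
            best_parts = topology_bipartitions(edges, taxa)
    return best_parts


def random_additive_matrix(taxa, rng):
    """Distances generated as path lengths on a random binary tree with
    branch lengths in [0.1, 1]; returns (matrix dict, true bipartitions)."""
    topologies = None
    edges = None
    # sample a topology by random sequential insertion
    base = [(taxa[0], -1), (taxa[1], -1), (taxa[2], -1)]
    edges = base
    next_internal = -2
    for k in range(3, len(taxa)):
        idx = int(rng.integers(len(edges)))
        u, v = edges[idx]
        edges = edges[:idx] + edges[idx + 1 :]
        edges += [(u, next_internal), (v, next_internal), (taxa[k], next_internal)]
        next_internal -= 1
    lengths = {frozenset(e): float(rng.uniform(0.1, 1.0)) for e in edges}
    A = _paths(edges, taxa)
    edge_order = list(edges)
    blens = np.array([lengths[frozenset(e)] for e in edge_order])
    dvec = A @ blens
    dist = {}
    for (a, b), d in zip(itertools.combinations(taxa, 2), dvec):
        dist[(a, b)] = dist[(b, a)] = float(d)
    return dist, topology_bipartitions(edges, taxa)


# ---------------------------------------------------------------------------
# Cluster transitive closure


def brute_clusters(intervals: dict[str, tuple[str, int, int]], threshold: int):
    """Connected components of the 'same chromosome and intergenic gap <=
    threshold between consecutive-by-position genes' relation, computed as a
    transitive closure over all pairs via chains."""
    names = sorted(intervals)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for a, b in itertools.combinations(names, 2):
        ca, sa, ea = intervals[a]
        cb, sb, eb = intervals[b]
        if ca != cb:
            continue
        # chain check must hold between positional neighbours only; emulate
        # by allowing union when no third gene lies strictly between them
        lo, hi = (ea, sb) if sa <= sb else (eb, sa)
        gap = hi - lo - 1
        between = any(
            intervals[c][0] == ca and min(sa, sb) < intervals[c][1] < max(sa, sb)
            for c in names if c not in (a, b)
        )
        if not between and gap <= threshold:
            union(a, b)
    groups: dict[str, set[str]] = {}
    for n in names:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}
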