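"""Independent reference implementations used only to check the package.

These are deliberately written with different algorithms/structures than
the production code: a full-matrix affine Needleman-Wunsch (score only),
a union-find connected-components partitioner, and exhaustive clique
enumeration.
"""

import itertools


def nw_affine_score(a, b, match=1, mismatch=-2, gap_open=-4, gap_extend=-1):
    """Unbanded global alignment score, affine gaps costing
    gap_open + L*gap_extend.  Full O(n*m) matrix."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
    return int(max(M[n][m], X[n][m], Y[n][m]))


def components_union_find(n_vertices, edges):
    """Partition {0..n-1} under edges via union-find."""
    parent = list(range(n_vertices))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for v in range(n_vertices):
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=min)


def max_clique_brute(vertices, has_edge):
    """Largest clique by exhaustive enumeration (use only for <= ~12)."""
    verts = list(vertices)
    best = []
    for r in range(len(verts), 0, -1):
        for combo in itertools.combinations(verts, r):
            if all(has_edge(u, v) for u, v in itertools.combinations(combo, 2)):
                return list(combo)
    return best


def kmer_matches_brute(read, window, k):
    """All (diagonal, read_pos) pairs where a read k-mer unique in the
    read occurs in the window; brute force over every pair of positions."""
    from collections import Counter

    counts = Counter(read[i : i + k] for i in range(len(read) - k + 1))
    out = {}
    for i in range(len(read) - k + 1):
        km = read[i : i + k]
        if counts[km] != 1:
            continue
        for j in range(len(window) - k + 1):
            if window[j : j + k] == km:
                out.setdefault(j - i, []).append(i)
    return out
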