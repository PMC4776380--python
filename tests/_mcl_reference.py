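"""Independently coded reference Markov clustering for oracle tests.

Plain-Python implementation (lists of lists, no numpy) with the same
parameterisation as the package engine: self-loops at each node's
maximum incident weight, column-stochastic iteration of expansion /
inflation / pruning, clusters from attractor components with overlap
resolved toward the smallest attractor label.
"""


def reference_mcl(nodes, weighted_edges, inflation=6.0, prune=1e-5, tol=1e-8, max_iter=200):
    """Cluster ``nodes`` given undirected ``(u, v, w)`` edges.

    Returns a set of frozensets partitioning the node set.
    """
    nodes = sorted(nodes)
    n = len(nodes)
    if n == 0:
        return set()
    pos = {v: i for i, v in enumerate(nodes)}
    mat = [[0.0] * n for _ in range(n)]
    for u, v, w in weighted_edges:
        i, j = pos[u], pos[v]
        if i == j:
            continue
        mat[i][j] = max(mat[i][j], float(w))
        mat[j][i] = max(mat[j][i], float(w))
    for j in range(n):
        col_max = max(mat[i][j] for i in range(n))
        mat[j][j] = col_max if col_max > 0 else 1.0

    def normalise(m):
        for j in range(n):
            s = sum(m[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    m[i][j] /= s
        return m

    mat = normalise(mat)
    for _ in range(max_iter):
        prev = [row[:] for row in mat]
        # expansion: matrix product, naive triple loop
        new = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for k in range(n):
                a = mat[i][k]
                if a == 0.0:
                    continue
                for j in range(n):
                    new[i][j] += a * mat[k][j]
        # inflation
        for i in range(n):
            for j in range(n):
                new[i][j] = new[i][j] ** inflation
        new = normalise(new)
        for i in range(n):
            for j in range(n):
                if new[i][j] < prune:
                    new[i][j] = 0.0
        mat = normalise(new)
        delta = max(
            abs(mat[i][j] - prev[i][j]) for i in range(n) for j in range(n)
        )
        if delta < tol:
            break

    attractors = [i for i in range(n) if mat[i][i] > 0]
    att = set(attractors)
    # union-find over attractors sharing any column's support
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for j in range(n):
        rows = [i for i in range(n) if mat[i][j] > 0 and i in att]
        for a, b in zip(rows, rows[1:]):
            union(a, b)

    comp_members = {}
    strays = []
    for j in range(n):
        rows = [i for i in range(n) if mat[i][j] > 0 and i in att]
        if not rows:
            strays.append(nodes[j])
            continue
        comps = {find(i) for i in rows}
        if len(comps) == 1:
            comp = comps.pop()
        else:
            comp = find(min(rows, key=lambda i: nodes[i]))
        comp_members.setdefault(comp, set()).add(nodes[j])
    clusters = {frozenset(s) for s in comp_members.values()}
    clusters.update(frozenset([v]) for v in strays)
    return clusters
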