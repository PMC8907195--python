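"""Independent brute-force oracles for the graph metrics.

Everything here is written from first principles (explicit path and
triangle enumeration, literal per-class variance sums) and deliberately
shares no code with the package implementation.
"""

import numpy as np


def _neighbors(A, i):
    return [j for j in range(A.n) if j != i and A.weights[i, j] > 0]


def simple_paths(A, start, end):
    """All simple paths start -> end with their inverse-weight lengths."""
    out = []

    def dfs(node, visited, length, path):
        if node == end:
            out.append((length, list(path)))
            return
        for nxt in _neighbors(A, node):
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, length + 1.0 / A.weights[node, nxt], path)
                path.pop()
                visited.remove(nxt)

    dfs(start, {start}, 0.0, [start])
    return out


def brute_tallies(A):
    """Shortest-path counts per ordered pair by exhaustive enumeration."""
    tallies = {}
    for h in range(A.n):
        for j in range(A.n):
            if h == j:
                continue
            paths = simple_paths(A, h, j)
            if not paths:
                tallies[(h, j)] = (0, {})
                continue
            best = min(length for length, _ in paths)
            minimal = [p for length, p in paths if length == best]
            via = {}
            for p in minimal:
                for node in p[1:-1]:
                    via[node] = via.get(node, 0) + 1
            tallies[(h, j)] = (len(minimal), via)
    return tallies


def brute_betweenness(A, normalized=False):
    tallies = brute_tallies(A)
    b = np.zeros(A.n)
    for i in range(A.n):
        total = 0.0
        for (h, j), (rho, via) in tallies.items():
            if rho == 0 or i in (h, j):
                continue
            total += via.get(i, 0) / rho
        b[i] = total
    if normalized:
        b = b / ((A.n - 1) * (A.n - 2))
    return b


def brute_clustering(A):
    c = np.zeros(A.n)
    for i in range(A.n):
        nbrs = _neighbors(A, i)
        k = len(nbrs)
        if k < 2:
            continue
        t = 0.0
        for a_idx, a in enumerate(nbrs):
            for b in nbrs[a_idx + 1:]:
                if A.weights[a, b] > 0:
                    t += (A.weights[i, a] * A.weights[i, b] * A.weights[a, b]) ** (1 / 3)
        c[i] = 2.0 * t / (k * (k - 1))
    return c


def _sorted_neighbour_degree_sequences(A):
    degs = [len(_neighbors(A, i)) for i in range(A.n)]
    seqs = [sorted(degs[j] for j in _neighbors(A, i)) for i in range(A.n)]
    return degs, seqs


def brute_neighbourhood_complexity(A):
    degs, seqs = _sorted_neighbour_degree_sequences(A)
    nc = [float("nan")] * A.n
    for p in sorted(set(degs)):
        members = [i for i in range(A.n) if degs[i] == p]
        if p == 0 or len(members) < 2:
            continue
        mu = [
            sum(seqs[i][j] for i in members) / len(members) for j in range(p)
        ]
        for i in members:
            dev = sum((seqs[i][j] - mu[j]) ** 2 for j in range(p))
            nc[i] = dev / (p * (len(members) - 1))
    return np.array(nc)


def brute_hierarchical_complexity(A):
    degs, seqs = _sorted_neighbour_degree_sequences(A)
    distinct = sorted(set(degs))
    if not distinct:
        return 0.0
    total = 0.0
    for p in distinct:
        members = [i for i in range(A.n) if degs[i] == p]
        if p == 0 or len(members) < 2:
            continue
        mu = [sum(seqs[i][j] for i in members) / len(members) for j in range(p)]
        dev = sum(
            (seqs[i][j] - mu[j]) ** 2 for i in members for j in range(p)
        )
        total += dev / (p * (len(members) - 1))
    return total / len(distinct)
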