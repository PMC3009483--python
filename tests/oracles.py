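"""Independent brute-force oracles shared by the test modules.

These are deliberately naive (character loops, exhaustive products) and
never call into the code paths they check.
"""

from itertools import product


def naive_hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_edges(strings, l, d):
    """All-pairs window scan: ((i,j),(i2,j2)) -> distance for every edge."""
    edges = {}
    for i, a in enumerate(strings):
        for i2, b in enumerate(strings):
            if i2 <= i:
                continue
            for j in range(len(a) - l + 1):
                for j2 in range(len(b) - l + 1):
                    k = naive_hamming(a[j : j + l], b[j2 : j2 + l])
                    if k <= 2 * d:
                        edges[((i, j), (i2, j2))] = k
    return edges


def brute_force_transversal_cliques(local_vertices, sub):
    """Exhaustive enumeration of one-vertex-per-string cliques."""
    n = sub.graph.n
    twod = 2 * sub.graph.d
    per_string = [
        [v for v in local_vertices if sub.string_of[v] == i] for i in range(n)
    ]
    if any(not ps for ps in per_string):
        return set()
    found = set()
    for combo in product(*per_string):
        ok = all(
            sub.dist[a, b] <= twod
            for ai, a in enumerate(combo)
            for b in combo[ai + 1 :]
        )
        if ok:
            found.add(tuple(sub.graph.vertex_ij(sub.vertices[v]) for v in combo))
    return found
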