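"""The weighted substring (window) graph and candidate-set extraction.

Every length-l window of every input sequence is a vertex v_{i,j} (sequence
i, 0-based offset j, half-open window [j, j+l)). Windows from *different*
sequences are joined when their Hamming distance k is at most 2d, with
weight l - k for d < k <= 2d and 10(l - k) for k <= d — close pairs are
emphasised. A set of n mutually adjacent vertices, one per sequence (a
*transversal clique*), induces a pairwise-bounded set of n windows: the
graph reduces pairwise-bounded candidate search to clique search, which the
per-offset reference subgraphs and Markov clustering make tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import DNA, Alphabet, packed_space

__all__ = [
    "WindowGraph",
    "Subgraph",
    "CandidateSet",
    "reference_subgraph",
    "filter_clusters",
    "extract_candidate_sets",
]

_NO_EDGE = np.uint8(255)  # same-sequence marker in the distance matrix


def edge_weight_from_distance(k, l: int, d: int):
    """Vectorised edge-weight rule: 10(l-k) for k <= d, l-k for d < k <= 2d,
    0 (no edge) beyond 2d."""
    k = np.asarray(k)
    w = np.zeros(k.shape, dtype=np.float32)
    mid = (k > d) & (k <= 2 * d)
    w[mid] = (l - k[mid]).astype(np.float32)
    near = k <= d
    w[near] = 10.0 * (l - k[near])
    return w


class WindowGraph:
    """All-window Hamming-distance structure of a sequence set.

    Stores the full inter-window distance matrix (uint8; same-sequence pairs
    carry the sentinel 255, so "distance <= 2d" is exactly the edge
    predicate). For n sequences of length ~m this is (n(m-l+1))^2 bytes —
    about 140 MB at n=20, m=600 — traded deliberately for O(1) subgraph
    gathers across the m-l+1 reference subgraphs.
    """

    def __init__(self, strings, l: int, d: int, alphabet: Alphabet = DNA):
        strings = list(strings)
        if len(strings) < 2:
            raise ValueError("need at least 2 sequences")
        if not 0 <= d <= l:
            raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
        short = [i for i, s in enumerate(strings) if len(s) < l]
        if short:
            raise ValueError(f"sequences shorter than l={l}: indices {short}")
        self.l = l
        self.d = d
        self.n = len(strings)
        self.alphabet = alphabet
        self.space = packed_space(l, alphabet)
        codes = [alphabet.encode(s) for s in strings]
        self.windows = [self.space.pack_windows(c) for c in codes]
        self.window_counts = np.array([len(w) for w in self.windows])
        self.starts = np.concatenate([[0], np.cumsum(self.window_counts)])
        self.n_vertices = int(self.starts[-1])
        flat = np.concatenate(self.windows)
        self._flat = flat
        dist = np.empty((self.n_vertices, self.n_vertices), dtype=np.uint8)
        for i in range(self.n):
            lo, hi = self.starts[i], self.starts[i + 1]
            dist[lo:hi] = np.minimum(
                self.space.hamming(flat[lo:hi, None], flat[None, :]), 254
            ).astype(np.uint8)
            dist[lo:hi, lo:hi] = _NO_EDGE
        self.dist = dist

    # -- vertex bookkeeping ----------------------------------------------

    def vertex_id(self, i: int, j: int) -> int:
        if not 0 <= j < self.window_counts[i]:
            raise IndexError(f"offset {j} out of range for sequence {i}")
        return int(self.starts[i] + j)

    def vertex_ij(self, vid) -> tuple:
        i = int(np.searchsorted(self.starts, vid, side="right") - 1)
        return i, int(vid - self.starts[i])

    def string_of_vertex(self, vids) -> np.ndarray:
        return np.searchsorted(self.starts, np.asarray(vids), side="right") - 1

    def window_string(self, vid: int) -> str:
        return self.space.decode(self._flat[vid])

    # -- edges ------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int((self.dist <= 2 * self.d).sum() // 2)

    def neighbors(self, vid: int) -> np.ndarray:
        return np.flatnonzero(self.dist[vid] <= 2 * self.d)


@dataclass
class Subgraph:
    """Induced subgraph on the closed neighbourhood of a reference vertex."""

    graph: WindowGraph
    ref_vertex: int
    vertices: np.ndarray  # global vertex ids, ascending; includes ref
    dist: np.ndarray  # (k, k) uint8 slice of the parent distance matrix
    string_of: np.ndarray  # (k,) input-sequence index per local vertex
    _adjacency: np.ndarray | None = None
    _weights: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.vertices)

    def adjacency(self) -> np.ndarray:
        if self._adjacency is None:
            self._adjacency = self.dist <= 2 * self.graph.d
        return self._adjacency

    def weights(self) -> np.ndarray:
        if self._weights is None:
            w = edge_weight_from_distance(self.dist, self.graph.l, self.graph.d)
            w[self.dist == _NO_EDGE] = 0.0
            self._weights = w
        return self._weights

    def covers_all_strings(self) -> bool:
        return len(np.unique(self.string_of)) == self.graph.n


def reference_subgraph(G: WindowGraph, R: int, j: int) -> Subgraph:
    """Induced subgraph on {v_{R,j}} ∪ N(v_{R,j}).

    Over all offsets j these subgraphs cover every clique containing any
    vertex of the reference sequence R — in particular every transversal
    clique, which must contain exactly one window of R.
    """
    ref = G.vertex_id(R, j)
    nb = G.neighbors(ref)
    vertices = np.union1d(nb, [ref])
    sub = G.dist[np.ix_(vertices, vertices)]
    return Subgraph(G, ref, vertices, sub, G.string_of_vertex(vertices))


# ---------------------------------------------------------------------------
# cluster filtering and transversal-clique extraction


def _transversal_prune(local: np.ndarray, sub: Subgraph) -> np.ndarray:
    """Iteratively delete vertices adjacent to fewer than n-1 distinct other
    sequences inside the set; a vertex failing this can sit in no
    n-transversal clique (each clique member is adjacent to one vertex of
    every other sequence)."""
    n = sub.graph.n
    local = np.asarray(local, dtype=np.intp)
    a0 = sub.adjacency()[np.ix_(local, local)].astype(np.float32)
    strings = sub.string_of[local]
    onehot = np.zeros((local.size, n), dtype=np.float32)
    onehot[np.arange(local.size), strings] = 1.0
    active = np.ones(local.size, dtype=bool)
    while active.any():
        # neighbours-per-sequence counts restricted to active vertices
        per_seq = (a0 * active) @ onehot
        deg = (per_seq > 0).sum(axis=1)
        ok = active & (deg >= n - 1)
        if (ok == active).all():
            break
        active = ok
    return local[active]


def filter_clusters(clusters, sub: Subgraph, *, prune: bool = True):
    """Keep only clusters that can still host an n-transversal clique.

    Each cluster is reduced by the iterative degree prune; it survives when
    at least one vertex of every input sequence remains. Surviving clusters
    are returned pruned (a sound reduction: deleted vertices belong to no
    transversal clique).
    """
    n = sub.graph.n
    kept = []
    for cl in clusters:
        cl = np.asarray(cl, dtype=np.intp)
        if len(np.unique(sub.string_of[cl])) < n:
            continue
        if prune:
            cl = _transversal_prune(cl, sub)
        if cl.size and len(np.unique(sub.string_of[cl])) == n:
            kept.append(cl)
    return kept


@dataclass(frozen=True)
class CandidateSet:
    """A transversal clique: one window per input sequence, all pairwise
    within 2d — i.e. a pairwise-bounded candidate motif set."""

    vertices: tuple  # ((i, j), ...) ordered by sequence index
    strings: tuple  # induced window strings, same order
    weight: int

    @property
    def key(self) -> tuple:
        return self.vertices


def extract_candidate_sets(cluster, sub: Subgraph, cap: int = 100_000):
    """All n-transversal cliques inside one (filtered) cluster.

    Depth-first search in sequence order; within a sequence, vertices are
    tried by decreasing total incident weight inside the cluster (highest-
    affinity first). A partial selection is pruned as soon as a candidate
    window exceeds distance 2d to any chosen one, so every emitted set is a
    clique. Enumeration is complete up to ``cap``; hitting the cap returns
    the truncated list with a flag (pathological input).

    Returns (candidates, truncated).
    """
    g = sub.graph
    cl = np.asarray(cluster, dtype=np.intp)
    order = np.argsort(-sub.weights()[np.ix_(cl, cl)].sum(axis=1), kind="stable")
    cl_sorted = cl[order]
    # cluster-local index space: vertices renumbered 0..k-1 in affinity order
    strings_sorted = sub.string_of[cl_sorted]
    per_string = [np.flatnonzero(strings_sorted == i) for i in range(g.n)]
    if any(ps.size == 0 for ps in per_string):
        return [], False
    adj = sub.adjacency()[np.ix_(cl_sorted, cl_sorted)]

    dist = sub.dist
    iu = np.triu_indices(g.n, 1)
    out: list[CandidateSet] = []
    truncated = False
    chosen: list[int] = []
    all_feasible = np.ones(cl_sorted.size, dtype=bool)

    def emit() -> None:
        sel = cl_sorted[np.array(chosen)]
        gids = sub.vertices[sel]
        out.append(
            CandidateSet(
                vertices=tuple(g.vertex_ij(v) for v in gids),
                strings=tuple(g.window_string(v) for v in gids),
                weight=int(dist[np.ix_(sel, sel)][iu].sum()),
            )
        )

    def dfs(string_idx: int, feasible: np.ndarray) -> bool:
        nonlocal truncated
        if len(out) >= cap:
            truncated = True
            return False
        if string_idx == g.n:
            emit()
            return True
        for v in per_string[string_idx][feasible[per_string[string_idx]]]:
            chosen.append(int(v))
            if not dfs(string_idx + 1, feasible & adj[v]):
                chosen.pop()
                return False
            chosen.pop()
        return True

    dfs(0, all_feasible)
    return out, truncated
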