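"""Independent oracles used by the test suite.

Everything here is deliberately naive: alignments are scored by
enumerating every monotone alignment path, and additive trees are
generated explicitly so their path-length matrices can be handed to
neighbor joining.  None of it shares code with the package paths it
checks.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive affine-gap alignment scoring


@functools.lru_cache(maxsize=None)
def alignment_paths(la: int, lb: int) -> tuple[tuple[tuple[tuple[int, int], ...], float], ...]:
    """All monotone alignment paths for lengths (la, lb).

    Each path is ``(match_pairs, gap_runs_cost_coefficients)`` where
    ``match_pairs`` are the 0-based (i, j) diagonal steps and the second
    element is ``(n_gap_runs, n_gap_positions)`` folded into a tuple for
    later affine costing.
    """
    paths: list[tuple[tuple[tuple[int, int], ...], tuple[int, int]]] = []

    def walk(i, j, matches, runs, gaps, last):
        if i == la and j == lb:
            paths.append((tuple(matches), (runs, gaps)))
            return
        if i < la and j < lb:
            matches.append((i, j))
            walk(i + 1, j + 1, matches, runs, gaps, "M")
            matches.pop()
        if i < la:
            walk(i + 1, j, matches, runs + (1 if last != "X" else 0), gaps + 1, "X")
        if j < lb:
            walk(i, j + 1, matches, runs + (1 if last != "Y" else 0), gaps + 1, "Y")

    walk(0, 0, [], 0, 0, "")
    return tuple(paths)


def brute_force_score(a: str, b: str, S, gap_open: float, gap_extend: float) -> float:
    """Best affine-gap global score by full path enumeration."""
    best = -np.inf
    for matches, (runs, gaps) in alignment_paths(len(a), len(b)):
        score = sum(S[a[i], b[j]] for i, j in matches)
        score -= runs * gap_open + (gaps - runs) * gap_extend
        best = max(best, score)
    return float(best)


def batch_brute_force_scores(
    seqs_a: list[str], seqs_b: list[str], S, gap_open: float, gap_extend: float
) -> np.ndarray:
    """Enumeration scores for every (a, b) pair of two same-length pools.

    Vectorized over pairs so exhausting thousands of short pairs stays
    affordable; the per-path scoring is still the naive sum used above.
    """
    la, lb = len(seqs_a[0]), len(seqs_b[0])
    alphabet = sorted({c for s in seqs_a + seqs_b for c in s})
    code = {c: k for k, c in enumerate(alphabet)}
    Ssub = np.array([[S[x, y] for y in alphabet] for x in alphabet])
    A = np.array([[code[c] for c in s] for s in seqs_a])
    B = np.array([[code[c] for c in s] for s in seqs_b])
    # (Na, Nb, la, lb) substitution scores, flattened over the last two axes
    P = Ssub[A[:, None, :, None], B[None, :, None, :]].reshape(len(A), len(B), la * lb)
    best = np.full((len(A), len(B)), -np.inf)
    for matches, (runs, gaps) in alignment_paths(la, lb):
        gap_cost = runs * gap_open + (gaps - runs) * gap_extend
        if matches:
            idx = np.array([i * lb + j for i, j in matches])
            score = P[:, :, idx].sum(axis=2) - gap_cost
        else:
            score = np.full(best.shape, -gap_cost)
        np.maximum(best, score, out=best)
    return best


# ---------------------------------------------------------------------------
# random additive trees


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree with uniform branch lengths.

    Returns ``(labels, distance_matrix, splits)`` where splits are the
    non-trivial bipartitions canonicalized by the side not containing
    the alphabetically first label.
    """
    labels = [f"T{k}" for k in range(n_leaves)]
    # adjacency: node -> {neighbor: branch length}; leaves are labels,
    # internal nodes are negative ints
    adj: dict = {labels[0]: {}, labels[1]: {}, labels[2]: {}}
    internal = -1
    center = internal
    adj[center] = {}
    for leaf in labels[:3]:
        w = rng.uniform(0.1, 1.0)
        adj[center][leaf] = w
        adj[leaf][center] = w
    internal -= 1
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[rng.integers(len(edges))]
        w_uv = adj[u].pop(v)
        adj[v].pop(u)
        mid = internal
        internal -= 1
        split = rng.uniform(0.2, 0.8)
        adj[mid] = {u: w_uv * split, v: w_uv * (1 - split)}
        adj[u][mid] = w_uv * split
        adj[v][mid] = w_uv * (1 - split)
        w = rng.uniform(0.1, 1.0)
        adj[mid][leaf] = w
        adj[leaf] = {mid: w}

    def dist_from(src):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        return seen

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        d = dist_from(a)
        for j, b in enumerate(labels):
            D[i, j] = d[b]

    # splits: cut each internal-internal or internal-leaf edge
    leafset = frozenset(labels)
    anchor = min(labels)
    splits = set()
    for u in adj:
        for v in adj[u]:
            if isinstance(u, str) or str(u) > str(v):
                continue
            # leaves on v's side when edge (u, v) is cut
            side = set()
            stack = [v]
            seen = {u, v}
            if isinstance(v, str):
                side.add(v)
            while stack:
                node = stack.pop()
                for nb in adj[node]:
                    if nb in seen:
                        continue
                    seen.add(nb)
                    if isinstance(nb, str):
                        side.add(nb)
                    else:
                        stack.append(nb)
            side = frozenset(side)
            if len(side) < 2 or len(leafset - side) < 2:
                continue
            if anchor in side:
                side = leafset - side
            splits.add(side)
    return labels, D, splits


def all_short_sequences(alphabet: str, max_len: int) -> list[str]:
    out = []
    for L in range(1, max_len + 1):
        out.extend("".join(p) for p in itertools.product(alphabet, repeat=L))
    return out
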