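"""Pairwise and progressive multiple alignment.

Pairwise global alignment with affine gap penalties is delegated to
Biopython's ``PairwiseAligner`` (Needleman–Wunsch/Gotoh in C); the
progressive multiple aligner stacks profile–profile alignments up a
UPGMA guide tree built on pairwise identity distances.  Defaults are
the classic BLOSUM62 / open 10 / extend 0.5 combination, where a gap
of length L costs ``open + (L - 1) * extend``.

Externally computed alignments are first-class citizens: every
downstream module consumes :class:`~gh13csr.seqio.Msa` regardless of
whether it came from here or from an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import AMINO_ACIDS, GAP, Msa, SequenceRecord


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive scores")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


DEFAULT_PARAMS = AlignParams()


def load_matrix(name: str):
    """A Biopython substitution matrix by name, with a helpful error."""
    available = substitution_matrices.load()
    if name not in available:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: {', '.join(available)}"
        )
    return substitution_matrices.load(name)


def _seq(x) -> str:
    return x.residues if isinstance(x, SequenceRecord) else str(x)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def pairwise_align(
    a, b, params: AlignParams = DEFAULT_PARAMS
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns the two gapped strings and the affine-gap alignment score.
    The first reported optimal traceback is used, which is deterministic
    for fixed inputs.
    """
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(params)
    alignment = aligner.align(sa, sb)[0]
    return alignment[0], alignment[1], float(alignment.score)


def percent_identity(aligned_a: str, aligned_b: str) -> tuple[float, int]:
    """Identity over residue–residue columns of an aligned pair.

    Returns ``(identity, n_comparable_columns)``; gap-containing columns
    are excluded from the denominator.
    """
    matches = comparable = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    return (matches / comparable if comparable else 0.0), comparable


# ---------------------------------------------------------------------------
# progressive MSA


def _profile_matrix(rows: list[str], index: dict[str, int]) -> np.ndarray:
    """Column frequency matrix (L x |alphabet|+1), last slot is the gap."""
    n_sym = len(index) + 1
    L = len(rows[0])
    out = np.zeros((L, n_sym))
    for row in rows:
        for j, ch in enumerate(row):
            out[j, index.get(ch, n_sym - 1)] += 1
    return out / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], score: np.ndarray, params: AlignParams
) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two profiles.

    ``score[i, j]`` is the expected substitution score between column i of
    profile A and column j of profile B.  Traceback prefers the diagonal,
    then a gap in profile B, then a gap in profile A.
    """
    la, lb = score.shape
    open_, ext = params.gap_open, params.gap_extend
    neg = -np.inf
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(open_ + (i - 1) * ext)
    for j in range(1, lb + 1):
        Y[0, j] = -(open_ + (j - 1) * ext)
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        si = score[i - 1]
        for j in range(1, lb + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best_prev + si[j - 1]
            Xi[j] = max(Mi1[j] - open_, Xi1[j] - ext, Yi1[j] - open_)
            Yi[j] = max(Mi[j - 1] - open_, Yi[j - 1] - ext, Xi[j - 1] - open_)
    # traceback
    i, j = la, lb
    state = max(
        (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])), key=lambda kv: kv[1]
    )[0]
    ops: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == "M":
            ops.append("M")
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            for s, v in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(v - prev) < eps:
                    state = s
                    break
        elif state == "X":
            ops.append("X")
            target = X[i, j]
            i -= 1
            if abs(M[i, j] - open_ - target) < eps:
                state = "M"
            elif abs(X[i, j] - ext - target) < eps:
                state = "X"
            else:
                state = "Y"
        else:
            ops.append("Y")
            target = Y[i, j]
            j -= 1
            if abs(M[i, j] - open_ - target) < eps:
                state = "M"
            elif abs(Y[i, j] - ext - target) < eps:
                state = "Y"
            else:
                state = "X"
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def identity_distance_matrix(
    records: list[SequenceRecord], params: AlignParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Symmetric matrix of 1 - pairwise identity (guide-tree distances)."""
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ga, gb, _ = pairwise_align(records[i], records[j], params)
            ident, _ = percent_identity(ga, gb)
            d[i, j] = d[j, i] = 1.0 - ident
    return d


def progressive_msa(
    records: list[SequenceRecord], params: AlignParams = DEFAULT_PARAMS
) -> Msa:
    """Progressive multiple alignment along a UPGMA guide tree.

    Row order follows the input order and de-gapping any output row
    reproduces the corresponding input residues.
    """
    ids = [r.accession for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate accessions in alignment input")
    if not records:
        raise ValueError("nothing to align")
    if len(records) == 1:
        return Msa(ids, [records[0].residues])

    S = load_matrix(params.matrix)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    index["X"] = len(index)
    n_sym = len(index) + 1  # + gap slot
    S_full = np.zeros((n_sym, n_sym))
    for a, ia in index.items():
        for b, ib in index.items():
            S_full[ia, ib] = S[a, b]

    dist = identity_distance_matrix(records, params)
    if len(records) == 2:
        merge_order = [(0, 1)]
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        merge_order = [(int(a), int(b)) for a, b, _, _ in Z]

    # cluster id -> (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(len(records))
    }
    next_id = len(records)
    for a, b in merge_order:
        mem_a, rows_a = clusters.pop(a)
        mem_b, rows_b = clusters.pop(b)
        fa = _profile_matrix(rows_a, index)
        fb = _profile_matrix(rows_b, index)
        score = fa @ S_full @ fb.T
        new_a, new_b = _align_profiles(rows_a, rows_b, score, params)
        clusters[next_id] = (mem_a + mem_b, new_a + new_b)
        next_id += 1

    members, rows = clusters.popitem()[1]
    by_index = dict(zip(members, rows))
    return Msa(ids, [by_index[i] for i in range(len(records))])
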