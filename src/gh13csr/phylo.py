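"""Distance trees for the barrel segment and the CSR fingerprint.

The two complementary views of the family's evolution are (i) a tree
on the alignment segment spanning the TIM-barrel strands beta1..beta8
and (ii) a tree on the 55-column CSR fingerprint alignment.  Trees are
built by neighbor joining on p-distances with optional bootstrap
supports; NJ is deterministic, recovers additive distances exactly,
and stands in for likelihood methods at desk scale — the alignments
can always be exported for an external ML program.

Gap handling in the p-distance follows the pairwise-deletion
convention by default (each pair of rows is compared over the columns
where both carry residues); complete deletion is available as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .csr import Fingerprint
from .seqio import GAP, Msa


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")


def _encode(msa: Msa) -> np.ndarray:
    arr = np.frombuffer(
        "".join(msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa), msa.width)
    return arr


def p_distance(msa: Msa, deletion: str = "pairwise") -> DistanceMatrix:
    """Fraction of mismatching residues over comparable columns.

    Pairs with no comparable column get distance 1 with a warning.
    """
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    arr = _encode(msa)
    gap = ord(GAP)
    residue = arr != gap
    if deletion == "complete":
        keep = residue.all(axis=0)
        arr = arr[:, keep]
        residue = residue[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = residue[i] & residue[j]
            comparable = int(both.sum())
            if comparable == 0:
                warnings.warn(
                    f"rows {msa.row_ids[i]!r} and {msa.row_ids[j]!r} share no "
                    "comparable columns; distance set to 1"
                )
                dij = 1.0
            else:
                dij = float((arr[i][both] != arr[j][both]).sum()) / comparable
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=tuple(msa.row_ids), matrix=d)


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining on the Q-criterion.

    Ties are broken by taxon order (first minimum in row-major scan),
    negative branch lengths are clamped to zero, and the returned tree
    is unrooted (trifurcating root).
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.matrix.astype(float).copy()
    nodes = [TreeNode(name=name) for name in dist.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        parent = TreeNode(children=[a, b])
        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
    # final three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lengths):
        node.length = max(float(length), 0.0)
    return TreeNode(children=nodes)


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-name sets, canonicalized.

    Each split is represented by the side not containing the
    alphabetically first leaf, so the set is rooting-invariant.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if anchor in side:
            side = leaves - side
        splits.add(side)
    return splits


def _resample_msa(msa: Msa, rng: np.random.Generator) -> Msa:
    cols = rng.integers(0, msa.width, size=msa.width)
    rows = ["".join(row[c] for c in cols) for row in msa.rows]
    return Msa(list(msa.row_ids), rows)


def bootstrap_tree(
    msa: Msa,
    n_replicates: int = 500,
    seed: int = 0,
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Supports are replicate counts (integers in ``0..n_replicates``)
    attached as internal-node labels; results are reproducible
    bit-for-bit for a given ``(msa, n_replicates, seed)``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = neighbor_joining(p_distance(msa, deletion))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-overlap pairs in replicates
        for _ in range(n_replicates):
            rep = neighbor_joining(p_distance(_resample_msa(msa, rng), deletion))
            for split in tree_splits(rep):
                if split in counts:
                    counts[split] += 1
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if anchor in side:
            side = leaves - side
        node.name = str(counts[side])
    return tree


def fingerprint_msa(fingerprints: list[Fingerprint]) -> Msa:
    """The 55-column alignment formed by stacking fingerprints."""
    return Msa(
        [fp.accession for fp in fingerprints], [fp.sequence for fp in fingerprints]
    )


def split_support(tree: TreeNode, split: frozenset[str]) -> int | None:
    """Bootstrap count of a given canonical split, if present in the tree."""
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    if anchor in split:
        split = leaves - split
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = leaves - side
        if side == split:
            return int(node.name) if node.name and node.name.isdigit() else None
    return None


def build_both_trees(
    segment_msa: Msa,
    fingerprints: list[Fingerprint],
    n_replicates: int = 500,
    seed: int = 0,
    deletion: str = "pairwise",
) -> tuple[TreeNode, TreeNode, dict]:
    """Segment tree, CSR-fingerprint tree, and a split-comparison report.

    Both inputs must cover the same taxa.  The report counts bipartitions
    shared between the two trees and unique to each, quantifying the
    "subtle differences in clustering" between the two sequence views.
    """
    fp_msa = fingerprint_msa(fingerprints)
    if set(segment_msa.row_ids) != set(fp_msa.row_ids):
        raise ValueError("segment alignment and fingerprints cover different taxa")
    seg_tree = bootstrap_tree(segment_msa, n_replicates, seed, deletion)
    csr_tree = bootstrap_tree(fp_msa, n_replicates, seed + 1, deletion)
    seg_splits = tree_splits(seg_tree)
    csr_splits = tree_splits(csr_tree)
    report = {
        "n_taxa": len(segment_msa),
        "segment_columns": segment_msa.width,
        "fingerprint_columns": fp_msa.width,
        "n_replicates": n_replicates,
        "shared_splits": len(seg_splits & csr_splits),
        "unique_segment_splits": len(seg_splits - csr_splits),
        "unique_csr_splits": len(csr_splits - seg_splits),
    }
    return seg_tree, csr_tree, report
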