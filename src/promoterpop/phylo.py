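"""Site-difference matrices, Jukes-Cantor correction, neighbor-joining trees
with bootstrap support, and newick output.

Trees are unrooted (the root node is a trifurcation); figures that root on an
outgroup do so by including the outgroup sequence and rooting on its pendant
edge. Neighbor joining is implemented here so that Q-criterion ties break
deterministically (lexicographically smallest label pair) and negative branch
lengths are clamped to zero with the deficit logged; skbio's implementation
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with per-pair compared-site counts."""

    labels: list[str]
    matrix: np.ndarray
    n_compared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("entries must be finite and nonnegative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _as_matrix(sequences) -> np.ndarray:
    return np.asarray(
        [list(s) if isinstance(s, str) else s for s in sequences], dtype="<U1"
    )


def pairwise_difference_matrix(labels, sequences) -> DistanceMatrix:
    """Raw count of differing sites per pair; sites with N in either sequence
    are excluded pairwise."""
    seqs = _as_matrix(sequences)
    if seqs.ndim != 2:
        raise ValueError("sequences must have equal length")
    n = len(labels)
    if seqs.shape[0] != n:
        raise ValueError("labels and sequences differ in number")
    d = np.zeros((n, n))
    comp = np.full((n, n), seqs.shape[1], dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        ok = (seqs[i] != "N") & (seqs[j] != "N")
        d[i, j] = d[j, i] = int((seqs[i][ok] != seqs[j][ok]).sum())
        comp[i, j] = comp[j, i] = int(ok.sum())
    return DistanceMatrix(list(labels), d, comp)


def jukes_cantor_distance(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differing sites."""
    if p < 0:
        raise ValueError("p must be nonnegative")
    if p >= 0.75:
        raise ValueError("saturated: p >= 0.75 has no JC distance")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def jukes_cantor_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Apply the JC correction to a raw difference matrix (needs per-pair
    compared-site counts)."""
    if dm.n_compared is None:
        raise ValueError("compared-site counts required for JC correction")
    n = len(dm.labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ncomp = dm.n_compared[i, j]
        p = dm.matrix[i, j] / ncomp if ncomp else 0.0
        out[i, j] = out[j, i] = jukes_cantor_distance(p)
    return DistanceMatrix(dm.labels, out, dm.n_compared)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou & Nei agglomeration).

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf). Negative
    branch lengths are clamped to zero and the deficit logged.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if len(set(dm.labels)) != n:
        raise ValueError("duplicate labels")

    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab) for lab in dm.labels
    }
    dist: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((dm.labels[i], dm.labels[j]))] = float(dm.matrix[i, j])

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    def clamp(length: float, where: str) -> float:
        if length < 0:
            log.info("clamped negative branch length %.4g at %s", length, where)
            return 0.0
        return length

    active = sorted(nodes)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best_pair = None
        best_q = np.inf
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * d(a, b) - r[a] - r[b]
            key = tuple(sorted((a, b)))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and (best_pair is None or key < best_pair)
            ):
                best_q, best_pair = q, key
        a, b = best_pair
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        parent = TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length = clamp(la, a)
        nb.length = clamp(lb, b)
        parent.extend([na, nb])
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        nodes[new_label] = parent
        active = sorted(set(active) - {a, b} | {new_label})

    a, b, c = active
    root = TreeNode()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        nx = nodes[x]
        nx.length = clamp(0.5 * (d(x, y) + d(x, z) - d(y, z)), x)
        root.append(nx)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as the
    leaf set *not* containing the alphabetically first leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(labels, sequences, n_reps: int = 1000, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports from resampled site columns.

    Site columns are resampled with replacement; support of each internal
    bipartition is the percentage of replicates containing it, attached to the
    corresponding internal node as ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seqs = _as_matrix(sequences)
    rng = np.random.default_rng(seed)
    tree = nj_tree(pairwise_difference_matrix(labels, seqs))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree_bipartitions(tree)}
    nsites = seqs.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, nsites, size=nsites)
        rep = nj_tree(pairwise_difference_matrix(labels, seqs[:, cols]))
        for bp in tree_bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    leaves = sorted(labels)
    ref = leaves[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves) - side
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Standard newick with branch lengths; bootstrap supports (if any) become
    internal node labels."""
    if tree is None or tree.count(tips=True) == 0:
        raise ValueError("empty tree")
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None and not node.name:
            node.name = f"{support:g}"
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
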