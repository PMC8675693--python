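import itertools

import numpy as np
import pytest

from promoterpop.phylo import (
    DistanceMatrix,
    bootstrap_support,
    jukes_cantor_distance,
    jukes_cantor_matrix,
    nj_tree,
    pairwise_difference_matrix,
    read_newick,
    tree_bipartitions,
    write_newick,
)


# --- independent helpers -----------------------------------------------------

def random_additive_tree(labels, rng):
    """Random unrooted binary tree as an edge list with positive lengths."""
    # start from the 3-taxon star, insert remaining leaves on random edges
    nodes = list(labels[:3])
    internal = ["I0"]
    edges = {(l, "I0"): rng.uniform(0.5, 3.0) for l in labels[:3]}
    for k, leaf in enumerate(labels[3:], start=1):
        edge = list(edges)[rng.integers(len(edges))]
        w = edges.pop(edge)
        new = f"I{k}"
        a, b = edge
        split = rng.uniform(0.2, 0.8)
        edges[(a, new)] = w * split
        edges[(new, b)] = w * (1 - split)
        edges[(leaf, new)] = rng.uniform(0.5, 3.0)
        internal.append(new)
    return edges


def path_distances(labels, edges):
    import networkx as nx

    g = nx.Graph()
    for (a, b), w in edges.items():
        g.add_edge(a, b, weight=w)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(
            g, labels[i], labels[j], weight="weight"
        )
    return d


def edge_bipartitions(labels, edges):
    import networkx as nx

    g = nx.Graph(list(edges))
    ref = sorted(labels)[0]
    out = set()
    for a, b in list(edges):
        g.remove_edge(a, b)
        side = {n for n in nx.node_connected_component(g, a) if n in labels}
        g.add_edge(a, b)
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out


def all_topologies(labels):
    """Every unrooted binary topology as an edge set (no lengths)."""
    if len(labels) == 3:
        yield {(l, "I0") for l in labels}
        return
    for sub in all_topologies(labels[:-1]):
        for edge in list(sub):
            rest = sub - {edge}
            a, b = edge
            new = f"J{len(labels)}_{abs(hash(edge)) % 10**6}"
            yield rest | {(a, new), (new, b), (labels[-1], new)}


def ols_tree_length(labels, topology, dmat):
    """Least-squares branch lengths for a fixed topology; total tree length."""
    edges = sorted(topology)
    idx = {e: k for k, e in enumerate(edges)}
    import networkx as nx

    g = nx.Graph(edges)
    rows, rhs = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        path = nx.shortest_path(g, labels[i], labels[j])
        row = np.zeros(len(edges))
        for a, b in zip(path[:-1], path[1:]):
            e = (a, b) if (a, b) in idx else (b, a)
            row[idx[e]] = 1.0
        rows.append(row)
        rhs.append(dmat[i, j])
    x, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return float(np.sum(x))


# --- tests -------------------------------------------------------------------

def test_difference_matrix_examples():
    dm = pairwise_difference_matrix(["a", "b"], ["ACGT", "ACGA"])
    assert dm.matrix[0, 1] == 1 and dm.n_compared[0, 1] == 4
    dm = pairwise_difference_matrix(["a", "b"], ["ACNT", "ACGA"])
    assert dm.matrix[0, 1] == 1 and dm.n_compared[0, 1] == 3  # N excluded
    dm = pairwise_difference_matrix(["a", "b"], ["ACGT", "ACGT"])
    assert dm.matrix[0, 1] == 0


def test_difference_matrix_matches_double_loop():
    rng = np.random.default_rng(4)
    seqs = ["".join(rng.choice(list("ACGN"), size=40)) for _ in range(7)]
    dm = pairwise_difference_matrix([f"h{i}" for i in range(7)], seqs)
    for i, j in itertools.combinations(range(7), 2):
        diff = sum(
            1 for x, y in zip(seqs[i], seqs[j]) if "N" not in (x, y) and x != y
        )
        assert dm.matrix[i, j] == diff


def test_jukes_cantor_values_and_limits():
    assert jukes_cantor_distance(0.0) == 0.0
    assert jukes_cantor_distance(0.03) == pytest.approx(0.03062, abs=5e-6)
    for p in (1e-4, 1e-6):
        assert jukes_cantor_distance(p) / p == pytest.approx(1.0, rel=1e-3)
    with pytest.raises(ValueError, match="saturated"):
        jukes_cantor_distance(0.75)


def test_jukes_cantor_matrix_uses_pairwise_compared_counts():
    dm = pairwise_difference_matrix(["a", "b", "c"], ["ACNT", "ACGA", "ACGT"])
    jc = jukes_cantor_matrix(dm)
    assert jc.matrix[0, 1] == pytest.approx(jukes_cantor_distance(1 / 3))


def test_nj_three_taxa_and_error():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0.0]]))
    tree = nj_tree(dm)
    assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"a": 1.0, "b": 3.0, "c": 5.0})
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_recovers_random_additive_trees(n_taxa):
    rng = np.random.default_rng(n_taxa)
    labels = [f"t{i}" for i in range(n_taxa)]
    edges = random_additive_tree(labels, rng)
    d = path_distances(labels, edges)
    tree = nj_tree(DistanceMatrix(labels, d))
    assert tree_bipartitions(tree) == edge_bipartitions(labels, edges)
    # branch lengths of an additive matrix are recovered exactly: pendant
    # edges are uniquely determined
    pendant = {t.name: t.length for t in tree.tips()}
    for lab in labels:
        true = [w for (a, b), w in edges.items() if lab in (a, b)][0]
        assert pendant[lab] == pytest.approx(true)


def test_nj_topology_equals_brute_force_minimum_evolution():
    rng = np.random.default_rng(17)
    labels = [f"t{i}" for i in range(6)]
    edges = random_additive_tree(labels, rng)
    d = path_distances(labels, edges)
    best = (np.inf, None)
    count = 0
    for topo in all_topologies(labels):
        count += 1
        length = ols_tree_length(labels, topo, d)
        if length < best[0] - 1e-9:
            best = (length, topo)
    assert count == 105  # unrooted binary topologies on 6 taxa
    me_bips = edge_bipartitions(labels, set(best[1]))
    nj_bips = tree_bipartitions(nj_tree(DistanceMatrix(labels, d)))
    assert nj_bips == me_bips


def test_nj_cross_check_against_skbio():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(23)
    labels = [f"t{i}" for i in range(7)]
    edges = random_additive_tree(labels, rng)
    d = path_distances(labels, edges)
    ours = tree_bipartitions(nj_tree(DistanceMatrix(labels, d)))
    theirs = tree_bipartitions(skbio_nj(SkbioDM(d, labels)))
    assert ours == theirs


def test_bootstrap_support_extremes_and_determinism():
    # many identical diagnostic columns: perfectly congruent signal
    seqs = [
        "A" * 10 + "C" * 10,
        "A" * 10 + "C" * 10,
        "G" * 10 + "C" * 10,
        "G" * 10 + "T" * 10,
        "G" * 10 + "T" * 10,
    ]
    labels = list("abcde")
    tree = bootstrap_support(labels, seqs, n_reps=100, seed=1)
    supports = [n.support for n in tree.non_tips(include_self=False)
                if getattr(n, "support", None) is not None]
    assert supports and all(s == 100.0 for s in supports)
    one = bootstrap_support(labels, seqs, n_reps=1, seed=2)
    for n in one.non_tips(include_self=False):
        if getattr(n, "support", None) is not None:
            assert n.support in (0.0, 100.0)
    t1 = bootstrap_support(labels, seqs, n_reps=50, seed=7)
    t2 = bootstrap_support(labels, seqs, n_reps=50, seed=7)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
    assert s1 == s2


def test_newick_round_trip_and_empty_error(tmp_path):
    rng = np.random.default_rng(31)
    labels = [f"t{i}" for i in range(6)]
    edges = random_additive_tree(labels, rng)
    tree = nj_tree(DistanceMatrix(labels, path_distances(labels, edges)))
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    text = path.read_text()
    assert text.strip().endswith(";")
    back = read_newick(path)
    assert tree_bipartitions(back) == tree_bipartitions(tree)
    with pytest.raises(ValueError, match="empty"):
        write_newick(None, path)
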