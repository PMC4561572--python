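"""Nei distance, neighbor joining, locus bootstrap."""

import math

import numpy as np
import pytest

from hybridtrace.distance_tree import (
    bootstrap_support, nei_distance_matrix, nei_standard_distance, nj_tree,
)
from hybridtrace.popgen_stats import allele_frequencies
from hybridtrace.synthetic_data import SimulationConfig, simulate_dataset

from conftest import build_dataset


def freq_fixture():
    """popA: {a:1}, {a:.5,b:.5}; popB: {a:.5,b:.5} at both loci."""
    ds = build_dataset(
        [[(150, 150), (150, 152)], [(150, 152), (150, 152)]],
        ["s1", "s2"], ["A", "B"], locus_names=["l1", "l2"])
    return allele_frequencies(ds)


def test_nei_identical_populations_zero():
    ds = build_dataset([[(150, 152)], [(150, 152)]], ["s1", "s2"], ["A", "B"])
    f = allele_frequencies(ds)
    assert nei_standard_distance(f, "s1_A", "s2_B") == 0.0


def test_nei_disjoint_allele_sets_infinite():
    ds = build_dataset([[(150, 150)], [(152, 152)]], ["s1", "s2"], ["A", "B"])
    f = allele_frequencies(ds)
    assert math.isinf(nei_standard_distance(f, "s1_A", "s2_B"))


def test_nei_hand_oracle():
    # Jxy = 0.5, Jx = 0.75, Jy = 0.5 -> D = -ln(0.5/sqrt(0.375)) ~ 0.2027
    f = freq_fixture()
    d = nei_standard_distance(f, "s1_A", "s2_B")
    assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.375)), abs=1e-12)
    assert d == pytest.approx(0.2027, abs=5e-4)


def test_nei_matrix_agrees_with_pairwise_function():
    cfg = SimulationConfig(seed=4, n_sites=3, n_loci=6, n_per_population=8)
    ds, *_ = simulate_dataset(cfg)
    f = allele_frequencies(ds)
    labels, dm = nei_distance_matrix(f)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                assert dm[i, j] == pytest.approx(
                    nei_standard_distance(f, a, b), abs=1e-12)
    assert np.allclose(dm, dm.T) and np.all(np.diag(dm) == 0)


def test_nei_pairwise_locus_deletion():
    """A population unscored at a locus is compared on the remaining loci."""
    ds = build_dataset(
        [[(150, 150), (150, 152)], [(150, 152), (150, 152)],
         [(150, 152), (0, 0)]],
        ["s1", "s2", "s3"], ["A", "B", "A"], locus_names=["l1", "l2"])
    f = allele_frequencies(ds)
    # s3_A scored only at l1, where it matches s2_B exactly
    assert nei_standard_distance(f, "s2_B", "s3_A") == 0.0


def test_nei_no_common_locus_is_error():
    ds = build_dataset(
        [[(150, 150), (0, 0)], [(0, 0), (152, 152)]],
        ["s1", "s2"], ["A", "B"], locus_names=["l1", "l2"])
    f = allele_frequencies(ds)
    with pytest.raises(ValueError, match="common"):
        nei_standard_distance(f, "s1_A", "s2_B")


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

def _patristic(tree):
    """Leaf-to-leaf path lengths of a PhyloTree (independent traversal)."""
    import itertools
    dists = {}

    def walk(node, acc):
        if not node.children:
            dists[node.name] = acc + node.length
            return
        for c in node.children:
            walk(c, acc + (node.length if node is not tree.root else 0.0))

    # path distance via root-paths on the rooted representation
    paths = {}

    def collect(node, path):
        path = path + [node]
        if not node.children:
            paths[node.name] = path
        for c in node.children:
            collect(c, path)

    collect(tree.root, [])
    out = {}
    for a, b in itertools.combinations(sorted(paths), 2):
        pa, pb = paths[a], paths[b]
        k = 0
        while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
            k += 1
        d = sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])
        out[(a, b)] = d
    return out


def test_nj_three_taxa_three_point_formulas():
    labels = ["x", "y", "z"]
    dm = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
    t = nj_tree(labels, dm)
    lengths = {c.name: c.length for c in t.root.children}
    assert lengths == {"x": 1.0, "y": 2.0, "z": 3.0}


def _random_additive(n_leaves, rng):
    """Random unrooted binary tree -> (leaf labels, additive matrix, splits)."""
    # adjacency with branch lengths; nodes: 0..n-1 leaves, then internals
    adj = {}
    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]
    nxt = n_leaves
    center = nxt
    nxt += 1
    for leaf in range(3):
        add_edge(leaf, center, rng.uniform(0.1, 1.0))
    for leaf in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = nxt
        nxt += 1
        drop_edge(u, v)
        cut = rng.uniform(0.2, 0.8) * w
        add_edge(u, mid, cut)
        add_edge(mid, v, w - cut)
        add_edge(leaf, mid, rng.uniform(0.1, 1.0))
    # distances by BFS
    labels = [f"t{i}" for i in range(n_leaves)]
    dm = np.zeros((n_leaves, n_leaves))
    for s in range(n_leaves):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t_ in range(n_leaves):
            dm[s, t_] = dist[t_]
    dm = (dm + dm.T) / 2  # remove float asymmetry from path-sum order
    # true splits: remove each internal edge
    splits = set()
    ref = sorted(labels)[0]
    for u in adj:
        for v in adj[u]:
            if u < v:
                side = set()
                stack = [(v, u)]
                seen = {u, v}
                side_nodes = [v]
                while side_nodes:
                    x = side_nodes.pop()
                    side.add(x)
                    for y in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            side_nodes.append(y)
                leaves = {f"t{i}" for i in side if i < n_leaves}
                if 2 <= len(leaves) <= n_leaves - 2:
                    if ref in leaves:
                        leaves = set(labels) - leaves
                    splits.add(frozenset(leaves))
    return labels, dm, splits


@pytest.mark.parametrize("seed", range(8))
def test_nj_recovers_random_additive_trees(seed):
    """On an additive matrix, NJ returns the generating topology and the
    patristic distances reproduce the matrix exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    labels, dm, true_splits = _random_additive(n, rng)
    t = nj_tree(labels, dm)
    assert t.bipartitions() == true_splits
    pat = _patristic(t)
    for (a, b), d in pat.items():
        i, j = labels.index(a), labels.index(b)
        assert d == pytest.approx(dm[i, j], abs=1e-9)


def test_nj_matches_skbio_topology():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(123)
    labels, dm, _ = _random_additive(7, rng)
    mine = nj_tree(labels, dm).bipartitions()
    sk = skbio.tree.nj(skbio.DistanceMatrix(dm, labels))
    ref = sorted(labels)[0]
    theirs = set()
    for node in sk.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            theirs.add(frozenset(side))
    assert mine == theirs


def test_nj_tie_break_deterministic():
    labels = ["a", "b", "c", "d"]
    dm = np.ones((4, 4)) - np.eye(4)
    t1 = nj_tree(labels, dm).to_newick()
    t2 = nj_tree(labels, dm).to_newick()
    assert t1 == t2
    # all-equal distances: lowest (row, col) pair (a, b) joins first
    assert frozenset({"c", "d"}) in nj_tree(labels, dm).bipartitions()


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))
    with pytest.raises(ValueError, match="infinite|pairwise"):
        nj_tree(["a", "b", "c"],
                np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]]))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(["a", "b"], np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_single_locus_degenerate_supports_one():
    cfg = SimulationConfig(seed=6, n_sites=3, n_loci=1, n_per_population=15,
                           missing_rate=0.0)
    ds, *_ = simulate_dataset(cfg)
    t = bootstrap_support(ds, n_reps=1, seed=0)
    assert t.supports and all(v == 1.0 for v in t.supports.values())


def test_bootstrap_seed_determinism():
    cfg = SimulationConfig(seed=7, n_sites=3, n_loci=8, n_per_population=10)
    ds, *_ = simulate_dataset(cfg)
    a = bootstrap_support(ds, n_reps=50, seed=3)
    b = bootstrap_support(ds, n_reps=50, seed=3)
    assert a.supports == b.supports and a.to_newick() == b.to_newick()
    assert all(0.0 <= v <= 1.0 for v in a.supports.values())


def test_bootstrap_support_monotone_in_divergence():
    """Stronger between-taxon divergence should not lower the support for
    the species bipartition (stochastic tolerance)."""
    sups = {}
    for F in (0.05, 0.30):
        cfg = SimulationConfig(seed=11, divergence=F, n_sites=4,
                               n_per_population=20, cline_alpha_max=0.0)
        ds, *_ = simulate_dataset(cfg)
        t = bootstrap_support(ds, n_reps=100, seed=1)
        pops = set(ds.population_labels())
        split = frozenset(p for p in pops if p.endswith("_pom"))
        if sorted(pops)[0] in split:
            split = frozenset(pops - split)
        sups[F] = t.supports.get(split, 0.0)
    assert sups[0.30] >= sups[0.05] - 0.05


def test_newick_roundtrip_parseable():
    skbio = pytest.importorskip("skbio")
    import io
    cfg = SimulationConfig(seed=12, n_sites=3, n_loci=5, n_per_population=10)
    ds, *_ = simulate_dataset(cfg)
    t = bootstrap_support(ds, n_reps=20, seed=0)
    parsed = skbio.TreeNode.read(io.StringIO(t.to_newick()))
    # newick readers map unquoted underscores to spaces
    names = {tip.name.replace(" ", "_") for tip in parsed.tips()}
    assert names == set(ds.population_labels())
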