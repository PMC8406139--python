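"""Distances, neighbor joining (oracle-checked), bootstrap and clade logic."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from polyprospect.io_formats import read_newick, write_newick
from polyprospect.phylogenetics import (
    bootstrap_support,
    clade_composition,
    distance_matrix,
    extract_clade,
    is_monophyletic,
    neighbor_joining,
    pairwise_distance,
    root_tree,
)
from polyprospect.synthetic_data import make_divergent_families


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_identical_sequences_have_zero_distance():
    for model in ("p", "poisson"):
        assert pairwise_distance("MKTAYIAKQR", "MKTAYIAKQR", model) == 0.0
    assert pairwise_distance("ACGTACGT", "ACGTACGT", "jc69") == 0.0


def test_poisson_correction_closed_form():
    # 1 mismatch in 10 aligned columns -> p = 0.1
    a, b = "MKTAYIAKQR", "MKTAYIAKQW"
    assert pairwise_distance(a, b, "p") == pytest.approx(0.1)
    assert pairwise_distance(a, b, "poisson") == pytest.approx(-math.log(0.9), abs=1e-9)


def test_jc69_inflates_p_distance():
    a, b = "ACGTACGTACGTACGTACGT", "ACGTACGTTGGTACGTACGT"
    p = pairwise_distance(a, b, "p")
    assert pairwise_distance(a, b, "jc69") >= p > 0


def test_saturated_distances_error():
    with pytest.raises(ValueError, match="saturated"):
        # maximally divergent nucleotide pair exceeds the JC69 domain
        pairwise_distance("AAAAAAAAAA", "CCCCCCCCCC", "jc69")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form():
    dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                        ids=list("ABC"))
    t = neighbor_joining(dm)
    lengths = {x.name: x.length for x in t.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_four_taxon_additive_example():
    ids = list("ABCD")
    D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    t = neighbor_joining(DistanceMatrix(D, ids))
    splits = {frozenset(x.name for x in n.tips())
              for n in t.non_tips(include_self=False)}
    assert frozenset("AB") in splits or frozenset("CD") in splits
    (ab,) = [n for n in t.non_tips(include_self=False)
             if frozenset(x.name for x in n.tips()) in (frozenset("AB"),
                                                        frozenset("CD"))]
    assert ab.length == pytest.approx(1.0)


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError, match="3 taxa|at least 3"):
        neighbor_joining(DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["A", "B"]))


def _random_additive_matrix(rng, n):
    """Random binary tree -> (ids, matrix, canonical nontrivial splits)."""
    children, lengths, nid, avail = {}, {}, n, list(range(n))
    while len(avail) > 1:
        i, j = rng.choice(len(avail), 2, replace=False)
        a, b = avail[max(i, j)], avail[min(i, j)]
        avail = [x for x in avail if x not in (a, b)] + [nid]
        children[nid] = (a, b)
        lengths[a] = float(rng.uniform(0.1, 1.0))
        lengths[b] = float(rng.uniform(0.1, 1.0))
        nid += 1

    parent = {}
    for x, (a, b) in children.items():
        parent[a] = x
        parent[b] = x

    def path_to_root(x):
        out = [x]
        while x in parent:
            x = parent[x]
            out.append(x)
        return out

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = path_to_root(i), path_to_root(j)
            shared = set(pi) & set(pj)
            d = sum(lengths[x] for x in pi if x not in shared)
            d += sum(lengths[x] for x in pj if x not in shared)
            D[i, j] = D[j, i] = d

    def tipset(x):
        if x < n:
            return {x}
        a, b = children[x]
        return tipset(a) | tipset(b)

    allt = frozenset(map(str, range(n)))
    splits = set()
    for x in children:
        s = frozenset(map(str, tipset(x)))
        if 2 <= len(s) <= n - 2:
            splits.add(allt - s if min(allt) in s else s)
    return list(map(str, range(n))), D, splits, allt


def _splits_of(tree, allt):
    out = set()
    n = len(allt)
    anchor = min(allt)
    for node in tree.non_tips(include_self=False):
        s = frozenset(x.name for x in node.tips())
        if 2 <= len(s) <= n - 2:
            out.add(allt - s if anchor in s else s)
    return out


def test_nj_recovers_random_additive_topologies_and_path_lengths():
    """>=50 random additive matrices: topology + path-length reproduction."""
    rng = np.random.default_rng(97)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        ids, D, splits, allt = _random_additive_matrix(rng, n)
        tree = neighbor_joining(DistanceMatrix(D, ids))
        assert _splits_of(tree, allt) == splits
        tips = {x.name: x for x in tree.tips()}
        for i in range(n):
            for j in range(i + 1, n):
                assert tips[str(i)].distance(tips[str(j)]) == pytest.approx(
                    D[i, j], abs=1e-9)


def test_nj_agrees_with_skbio_on_topology():
    rng = np.random.default_rng(101)
    for _ in range(10):
        n = int(rng.integers(4, 8))
        ids, D, splits, allt = _random_additive_matrix(rng, n)
        ours = _splits_of(neighbor_joining(DistanceMatrix(D, ids)), allt)
        theirs = _splits_of(skbio_nj(DistanceMatrix(D, ids)), allt)
        assert ours == theirs == splits


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_separating_edge_strongly_supported():
    seqs, labels = make_divergent_families(n_per_clade=5, within_identity=0.95,
                                           between_identity=0.40, seed=7)
    tree = bootstrap_support(seqs, n_reps=100, seed=11)
    clade1 = {n for n, _ in seqs if labels[n] == "clade1"}
    allt = {n for n, _ in seqs}
    supports = [node.support for node in tree.non_tips(include_self=False)
                if {x.name for x in node.tips()} in (clade1, allt - clade1)]
    assert supports and min(supports) >= 95
    assert is_monophyletic(tree, clade1)


def test_bootstrap_single_replicate_supports_are_binary():
    seqs, _ = make_divergent_families(n_per_clade=3, length=120, seed=3)
    tree = bootstrap_support(seqs, n_reps=1, seed=5)
    vals = {node.support for node in tree.non_tips(include_self=False)
            if node.support is not None}
    assert vals <= {0, 100}


def test_bootstrap_deterministic_given_seed():
    seqs, _ = make_divergent_families(n_per_clade=3, length=120, seed=3)
    a = write_newick(bootstrap_support(seqs, n_reps=25, seed=9))
    b = write_newick(bootstrap_support(seqs, n_reps=25, seed=9))
    assert a == b


# ---------------------------------------------------------------------------
# clade logic
# ---------------------------------------------------------------------------

def test_monophyly_on_rooted_quartet():
    t = read_newick("((A,B),(C,D));")
    assert is_monophyletic(t, ["A", "B"])
    assert not is_monophyletic(t, ["A", "C"])
    assert is_monophyletic(t, ["A"])
    with pytest.raises(ValueError, match="Z"):
        is_monophyletic(t, ["A", "Z"])


def test_monophyly_with_outgroup_rooting():
    t = read_newick("(A:1,B:1,(C:1,(D:1,E:1):1):1);")
    assert is_monophyletic(t, ["D", "E"], outgroup=["A", "B"])
    assert not is_monophyletic(t, ["C", "A"], outgroup=["D", "E"])


def test_root_tree_splits_subtending_edge_equally():
    t = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:2);")
    r = root_tree(t, ["C", "D"])
    kids = {frozenset(x.name for x in c.tips()): c.length for c in r.children}
    assert kids[frozenset("CD")] == pytest.approx(0.5)
    assert is_monophyletic(r, ["A", "B"])  # no outgroup needed once rooted


def test_rooting_preserves_bipartitions():
    t = read_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1,F:1);")
    allt = frozenset("ABCDEF")
    r = root_tree(t, ["A", "B"])
    assert _splits_of(t, allt) == _splits_of(r, allt)


def test_extract_clade_and_errors():
    t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    sub = extract_clade(t, ["A", "B"])
    assert {x.name for x in sub.tips()} == {"A", "B"}
    assert {x.length for x in sub.tips()} == {1.0}
    with pytest.raises(ValueError, match="not monophyletic"):
        extract_clade(t, ["A", "C"])


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

def test_composition_percentages_match_reported_clade_summaries():
    labels = {f"b{i}": "Betaproteobacteria" for i in range(4704)}
    labels.update({f"o{i}": "other" for i in range(164)})
    table = clade_composition(labels, list(labels))
    assert table.total == 4868
    assert table.percentages["Betaproteobacteria"] == 96.6

    labels2 = {f"x{i}": "basal" for i in range(4013)}
    labels2.update({f"y{i}": "rest" for i in range(977)})
    table2 = clade_composition(labels2, list(labels2))
    assert table2.total == 4990
    assert table2.int_percentages["basal"] == 80


def test_composition_single_group_and_rounding_sum():
    t = clade_composition({"a": "g", "b": "g"}, ["a", "b"])
    assert t.percentages == {"g": 100.0}
    labels = {f"t{i}": f"g{i % 3}" for i in range(7)}
    t2 = clade_composition(labels, list(labels))
    assert sum(t2.percentages.values()) == pytest.approx(100.0, abs=0.1)


def test_composition_unlabeled_tip_errors():
    with pytest.raises(ValueError, match="unlabeled"):
        clade_composition({"a": "g"}, ["a", "b"])
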