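"""Distances, neighbor joining, bootstrap and Fitch parsimony."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1evo import phylo, simulate as sim


# ---------------------------------------------------------------------------
# distances


def test_identical_sequences_have_zero_distance():
    dm = phylo.pairwise_distance(["a", "b"], ["ACGTACGT", "ACGTACGT"], "JC")
    assert dm.values[0, 1] == 0.0


@pytest.mark.parametrize("model", ["p", "JC", "K2P"])
def test_models_agree_with_closed_forms_at_p10(model):
    # 100 sites, 10 mismatches: 6 transitions + 4 transversions
    s1 = "A" * 60 + "C" * 40
    s2 = "G" * 6 + "A" * 54 + "A" * 4 + "C" * 36
    dm = phylo.pairwise_distance(["x", "y"], [s1, s2], model)
    p, P, Q = 0.10, 0.06, 0.04
    if model == "p":
        expected = p
    elif model == "JC":
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert abs(expected - 0.10732) < 5e-5
    else:
        expected = (-0.5 * math.log(1 - 2 * P - Q)
                    - 0.25 * math.log(1 - 2 * Q))
    assert dm.values[0, 1] == pytest.approx(expected, abs=1e-9)


def test_tn93_finite_and_above_jc_on_heterogeneous_divergence():
    rng = np.random.default_rng(11)
    anc = sim.random_sequence(rng, 2000)
    der = sim.evolve(anc, 0.12, rng)
    jc = phylo.pairwise_distance(["x", "y"], [anc, der], "JC").values[0, 1]
    tn = phylo.pairwise_distance(["x", "y"], [anc, der], "TN93").values[0, 1]
    assert np.isfinite(tn)
    assert tn == pytest.approx(jc, rel=0.1)


def test_k2p_exceeds_jc_for_transition_only_divergence():
    s1 = "AACCGGTT" * 25
    s2 = s1.replace("A", "G", 0)
    s2 = "G" + s1[1:20] + "G" + s1[21:]  # two A->G transitions
    jc = phylo.pairwise_distance(["x", "y"], [s1, s2], "JC").values[0, 1]
    k2p = phylo.pairwise_distance(["x", "y"], [s1, s2], "K2P").values[0, 1]
    assert k2p > jc


def test_pairwise_deletion_and_zero_overlap_error():
    dm = phylo.pairwise_distance(["a", "b"], ["ACGT-NGT", "ACGTAAGT"], "p")
    assert dm.values[0, 1] == pytest.approx(0.0)
    with pytest.raises(ValueError, match="no comparable sites"):
        phylo.pairwise_distance(["a", "b"], ["AC--", "--AC"], "p")


def test_saturation_flagged_not_raised():
    s1 = "A" * 100
    s2 = "C" * 50 + "G" * 50   # p = 1.0, JC undefined
    dm = phylo.pairwise_distance(["a", "b"], [s1, s2], "JC")
    assert dm.saturated[0, 1]
    assert np.isnan(dm.values[0, 1])


# ---------------------------------------------------------------------------
# neighbor joining


def _random_tree_matrix(rng, n):
    """Random unrooted binary tree on n labelled leaves and its additive
    distance matrix."""
    labels = [f"t{i}" for i in range(n)]
    nodes = [phylo.Node(name=l, length=rng.uniform(0.05, 1.0))
             for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = phylo.Node(children=[nodes[i], nodes[j]],
                            length=rng.uniform(0.05, 1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    root = phylo.Node(children=nodes)
    names, mat = root.leaf_distances()
    order = np.argsort(names)
    return root, [names[i] for i in order], mat[np.ix_(order, order)]


def _bipartitions(tree):
    full = frozenset(tree.leaf_names())
    out = set()
    for bp in tree.bipartitions():
        out.add(min(bp, full - bp, key=lambda s: (len(s), sorted(s))))
    return out


def test_three_taxa_branch_lengths_solve_three_point_equations():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(list("abc"), d))
    names, mat = tree.leaf_distances()
    idx = {n: i for i, n in enumerate(names)}
    assert mat[idx["a"], idx["b"]] == pytest.approx(3.0, abs=1e-9)
    assert mat[idx["a"], idx["c"]] == pytest.approx(4.0, abs=1e-9)
    assert mat[idx["b"], idx["c"]] == pytest.approx(5.0, abs=1e-9)


def test_nj_recovers_additive_topology_and_path_lengths():
    rng = np.random.default_rng(1)
    for _ in range(10):
        true, labels, mat = _random_tree_matrix(rng, 6)
        est = phylo.neighbor_joining(phylo.DistanceMatrix(labels, mat))
        assert _bipartitions(est) == _bipartitions(true)
        names, est_mat = est.leaf_distances()
        order = np.argsort(names)
        est_mat = est_mat[np.ix_(order, order)]
        assert np.allclose(est_mat, mat, atol=1e-9)


def test_nj_matches_scikit_bio_on_random_matrices():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(2)
    for _ in range(5):
        _, labels, mat = _random_tree_matrix(rng, 7)
        ours = phylo.neighbor_joining(phylo.DistanceMatrix(labels, mat))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=labels))
        their_bps = set()
        full = frozenset(labels)
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels) - 1:
                their_bps.add(min(tips, full - tips,
                                  key=lambda s: (len(s), sorted(s))))
        assert _bipartitions(ours) <= their_bps | _bipartitions(ours)
        assert _bipartitions(ours) == their_bps


def test_nj_invariant_to_label_permutation():
    rng = np.random.default_rng(3)
    _, labels, mat = _random_tree_matrix(rng, 6)
    t1 = phylo.neighbor_joining(phylo.DistanceMatrix(labels, mat))
    perm = rng.permutation(len(labels))
    t2 = phylo.neighbor_joining(phylo.DistanceMatrix(
        [labels[i] for i in perm], mat[np.ix_(perm, perm)]))
    assert _bipartitions(t1) == _bipartitions(t2)


def test_nj_rejects_asymmetric_matrix():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        phylo.neighbor_joining(phylo.DistanceMatrix(list("abc"), d))


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_single_replicate_gives_binary_support():
    rng = np.random.default_rng(4)
    anc = sim.random_sequence(rng, 400)
    seqs = [sim.evolve(anc, 0.05, rng) for _ in range(5)]
    tree = phylo.bootstrap_support([f"s{i}" for i in range(5)], seqs,
                                   n_reps=1, seed=0)
    sup = [n.support for n in tree.walk()
           if not n.is_leaf and n.support is not None]
    assert sup and all(s in (0.0, 100.0) for s in sup)


def test_bootstrap_supports_clear_clade_separation():
    rng = np.random.default_rng(5)
    anc = sim.random_sequence(rng, 600)
    a = sim.evolve(anc, 0.08, rng)
    b = sim.evolve(anc, 0.08, rng)
    seqs, labels = [], []
    for grp, prog in (("a", a), ("b", b)):
        for i in range(4):
            labels.append(f"{grp}{i}")
            seqs.append(sim.evolve(prog, 0.01, rng))
    tree = phylo.bootstrap_support(labels, seqs, n_reps=100, seed=0)
    split = frozenset(l for l in labels if l.startswith("a"))
    supports = {bp: node.support for bp, node in tree.bipartitions().items()}
    full = frozenset(labels)
    found = [s for bp, s in supports.items() if bp in (split, full - split)]
    assert found and found[0] >= 95.0


# ---------------------------------------------------------------------------
# Fitch parsimony


def _brute_force_parsimony(tree, leaf_states):
    states = sorted(set(leaf_states.values()))
    internals = [n for n in tree.walk() if not n.is_leaf]

    def edges(assign):
        total = 0
        for node in internals:
            for child in node.children:
                cs = (leaf_states[child.name] if child.is_leaf
                      else assign[id(child)])
                if cs != assign[id(node)]:
                    total += 1
        return total

    best = math.inf
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        best = min(best, edges(assign))
    return best


def test_fitch_zero_changes_for_uniform_labels():
    tree = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    assert phylo.fitch_changes(tree, dict.fromkeys("abcde", "X")) == 0


def test_fitch_equals_exhaustive_minimum_on_six_leaf_trees():
    rng = np.random.default_rng(6)
    tree = phylo.parse_newick(
        "((a:1,b:1):1,((c:1,d:1):1,e:1):1,f:1);")
    leaves = "abcdef"
    for _ in range(30):
        states = {l: "PQR"[rng.integers(0, 3)] for l in leaves}
        assert phylo.fitch_changes(tree, states) == \
            _brute_force_parsimony(tree, states)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("AB"), min_size=5, max_size=5))
def test_fitch_bounded_by_minority_count(labels):
    tree = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    states = dict(zip("abcde", labels))
    counts = {s: labels.count(s) for s in set(labels)}
    minority = sum(counts.values()) - max(counts.values())
    assert phylo.fitch_changes(tree, states) <= minority


def test_fitch_rejects_unlabeled_leaf():
    tree = phylo.parse_newick("((a:1,b:1):1,c:1,d:1);")
    with pytest.raises(ValueError, match="no state"):
        phylo.fitch_changes(tree, {"a": "X", "b": "X", "c": "X"})


# ---------------------------------------------------------------------------
# newick round trip


def test_newick_round_trip_preserves_topology_and_lengths():
    rng = np.random.default_rng(8)
    _, labels, mat = _random_tree_matrix(rng, 6)
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, mat))
    back = phylo.parse_newick(tree.newick())
    assert _bipartitions(back) == _bipartitions(tree)
    assert sorted(back.leaf_names()) == sorted(tree.leaf_names())
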