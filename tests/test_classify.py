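"""Promoter typing, novel-UTR clustering, family definition, consensus,
naming."""

import numpy as np
import pytest

from l1evo import classify, phylo, simulate as sim


@pytest.fixture(scope="module")
def library():
    _, promoters = sim.build_ancestral_element(0, ("Lx", "F", "A"))
    return promoters


# ---------------------------------------------------------------------------
# UTR assignment


def test_exact_library_entry_assigned_at_full_identity(library):
    region = "T" * 100 + library["F"]
    a = classify.assign_utr_type(region, library)
    assert a.utr_type == "F"
    assert a.identity == pytest.approx(100.0)


def test_mutated_entry_assigned_above_threshold(library, rng):
    region = sim.evolve(library["A"], 0.17, rng)   # ~15% observed divergence
    a = classify.assign_utr_type("G" * 50 + region, library, min_identity=80)
    assert a.utr_type == "A"
    assert 80 <= a.identity < 100


def test_random_regions_stay_unassigned(library):
    rng = np.random.default_rng(42)
    assigned = 0
    for _ in range(100):
        region = sim.random_sequence(rng, 600, 0.42)
        a = classify.assign_utr_type(region, library, min_identity=80)
        assigned += a.utr_type != "unassigned"
    assert assigned == 0


def test_empty_region_unassigned_with_reason(library):
    a = classify.assign_utr_type("", library)
    assert a.utr_type == "unassigned"
    assert a.reason == "empty 5' region"


def test_monomer_count_detects_tandem_structure(library):
    # library promoters are monomer+monomer+tail
    a = classify.assign_utr_type(library["Lx"], library)
    assert a.monomer_count == 2


# ---------------------------------------------------------------------------
# novel-UTR clustering


def test_novel_promoter_carried_by_thirty_copies_recovered(rng):
    novel = sim.random_sequence(rng, 600, 0.45)
    regions = {f"c{i}": sim.evolve(novel, 0.02, rng) for i in range(30)}
    types = classify.cluster_novel_utrs(regions, min_cluster_size=10)
    assert len(types) == 1
    cons = types[0].consensus
    ident = np.mean([a == b for a, b in zip(cons, novel)])
    assert ident >= 0.99


def test_mutually_distant_regions_yield_no_types(rng):
    regions = {f"c{i}": sim.random_sequence(rng, 400) for i in range(12)}
    assert classify.cluster_novel_utrs(regions, min_cluster_size=3) == []


def test_two_distinct_promoters_make_two_types(rng):
    p1 = sim.random_sequence(rng, 500)
    p2 = sim.evolve(p1, 0.55, rng)   # ~40% observed: far below threshold
    regions = {}
    for i in range(12):
        regions[f"a{i}"] = sim.evolve(p1, 0.02, rng)
        regions[f"b{i}"] = sim.evolve(p2, 0.02, rng)
    types = classify.cluster_novel_utrs(regions, identity_threshold=85.0,
                                        min_cluster_size=10)
    assert len(types) == 2


# ---------------------------------------------------------------------------
# star statistic


def test_true_star_passes():
    leaves = [phylo.Node(name=f"l{i}", length=1.0) for i in range(6)]
    tree = phylo.Node(children=leaves)
    stat, ok = classify.star_statistic(tree)
    assert stat == 0.0 and ok


def test_two_clade_tree_fails():
    a = phylo.Node(children=[phylo.Node(name=f"a{i}", length=0.01)
                             for i in range(4)], length=1.0, support=100.0)
    b = phylo.Node(children=[phylo.Node(name=f"b{i}", length=0.01)
                             for i in range(4)], length=1.0, support=100.0)
    tree = phylo.Node(children=[a, b])
    stat, ok = classify.star_statistic(tree)
    assert stat > 0.9 and not ok


def test_simulated_single_family_usually_passes(rng):
    passes = 0
    n_reps = 20
    for rep in range(n_reps):
        anc = sim.random_sequence(rng, 800)
        labels = [f"c{i}" for i in range(20)]
        seqs = [sim.evolve(anc, 0.02, rng) for _ in labels]
        tree = phylo.bootstrap_support(labels, seqs, n_reps=50, seed=rep)
        _, ok = classify.star_statistic(tree)
        passes += ok
    assert passes >= 0.95 * n_reps


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_members_is_the_member():
    assert classify.build_consensus(["ACGT", "ACGT", "ACGT"]) == "ACGT"


def test_consensus_tie_breaks_alphabetically():
    rows = ["AAAC", "AAAC", "AAAC", "CCCA", "CCCA", "CCCA"]
    assert classify.build_consensus(rows) == "AAAA"


def test_consensus_drops_gap_majority_columns():
    rows = ["A-CT", "A-CT", "AGCT"]
    assert classify.build_consensus(rows) == "ACT"


def test_consensus_recovers_progenitor_from_noisy_copies(rng):
    prog = sim.random_sequence(rng, 1000)
    rows = [sim.evolve(prog, 0.02, rng) for _ in range(11)]
    cons = classify.build_consensus(rows)
    ident = np.mean([a == b for a, b in zip(cons, prog)])
    assert ident >= 0.999


def test_consensus_requires_rows():
    with pytest.raises(ValueError):
        classify.build_consensus([])


# ---------------------------------------------------------------------------
# family definition


def _two_family_inputs(rng, n=12, gap=0.05, noise=0.01):
    anc = sim.random_sequence(rng, 1000)
    pa = sim.evolve(anc, gap / 2, rng)
    pb = sim.evolve(anc, gap / 2, rng)
    inserts, p_of = {}, {}
    for i in range(n):
        inserts[f"a{i}"] = sim.evolve(pa, noise, rng)
        inserts[f"b{i}"] = sim.evolve(pb, noise, rng)
        p_of[f"a{i}"] = p_of[f"b{i}"] = "A"
    return inserts, p_of


def test_two_families_recovered_with_perfect_membership(rng):
    inserts, p_of = _two_family_inputs(rng)
    fams = classify.define_families(inserts, p_of, n_boot=80, seed=1)
    assert len(fams) == 2
    members = sorted(tuple(sorted(f.members)) for f in fams)
    assert members[0] == tuple(sorted(f"a{i}" for i in range(12)))
    assert members[1] == tuple(sorted(f"b{i}" for i in range(12)))
    assert all(f.validated for f in fams)


def test_single_simulated_family_stays_one_cluster(rng):
    anc = sim.random_sequence(rng, 1000)
    inserts = {f"c{i}": sim.evolve(anc, 0.02, rng) for i in range(15)}
    p_of = dict.fromkeys(inserts, "F")
    fams = classify.define_families(inserts, p_of, n_boot=80, seed=2)
    assert len(fams) == 1
    assert fams[0].validated


def test_two_epoch_family_split_by_star_violation(rng):
    # copies drawn from two epochs of one drifting lineage: internal edge
    anc = sim.random_sequence(rng, 1000)
    late = sim.evolve(anc, 0.06, rng)
    inserts = {}
    for i in range(10):
        inserts[f"e{i}"] = sim.evolve(anc, 0.01, rng)
        inserts[f"l{i}"] = sim.evolve(late, 0.01, rng)
    p_of = dict.fromkeys(inserts, "V")
    fams = classify.define_families(inserts, p_of, n_boot=80, seed=3)
    assert len(fams) == 2


def test_short_alignment_refused(rng):
    inserts = {f"x{i}": "ACGT" * 20 for i in range(5)}
    with pytest.raises(ValueError, match="shorter"):
        classify.define_families(inserts, dict.fromkeys(inserts, "A"),
                                 min_len=200)


def test_family_definition_invariant_to_input_order(rng):
    inserts, p_of = _two_family_inputs(rng)
    fams1 = classify.define_families(inserts, p_of, n_boot=50, seed=4)
    shuffled = dict(reversed(list(inserts.items())))
    fams2 = classify.define_families(shuffled, p_of, n_boot=50, seed=4)
    m1 = sorted(tuple(sorted(f.members)) for f in fams1)
    m2 = sorted(tuple(sorted(f.members)) for f in fams2)
    assert m1 == m2


# ---------------------------------------------------------------------------
# naming


def _fam(members, promoter):
    return classify.Family(name="", members=members, promoter=promoter)


def test_roman_numerals():
    assert [classify.roman(i) for i in (1, 2, 3, 4, 9, 14)] == \
        ["I", "II", "III", "IV", "IX", "XIV"]


def test_names_ordered_by_age_within_promoter_type():
    fams = [_fam(["x1", "x2"], "A"), _fam(["y1", "y2"], "A"),
            _fam(["z1", "z2"], "A")]
    ages = {("x1", "x2"): 1.6, ("y1", "y2"): 0.2, ("z1", "z2"): 2.2}
    classify.name_families(fams, ages)
    assert {f.name for f in fams} == {"A_I", "A_II", "A_III"}
    by_name = {f.name: f.age for f in fams}
    assert by_name["A_I"] == 0.2 and by_name["A_III"] == 2.2


def test_single_family_gets_numeral_one():
    fams = [_fam(["m1", "m2"], "Mus")]
    classify.name_families(fams, {("m1", "m2"): 5.0})
    assert fams[0].name == "Mus_I"


def test_age_tie_broken_by_copy_number():
    big = _fam([f"b{i}" for i in range(20)], "F")
    small = _fam([f"s{i}" for i in range(5)], "F")
    ages = {tuple(big.members): 1.0, tuple(small.members): 1.0}
    classify.name_families([small, big], ages)
    assert big.name == "F_I" and small.name == "F_II"
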