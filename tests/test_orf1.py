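"""ORF1 structure: LPR unit decomposition, Sankoff history, coiled coil."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1evo import orf1, phylo, simulate as sim


@pytest.fixture(scope="module")
def units():
    rng = np.random.default_rng(0)
    u66 = sim._encode_protein(rng, sim._heptad_protein(rng, 3) + "E")
    u42 = sim._encode_protein(rng, sim._heptad_protein(rng, 2))
    left = sim.random_sequence(rng, 120)
    right = sim.random_sequence(rng, 120)
    return u66, u42, left, right


def _mk(left, right, *parts):
    return left + "".join(parts) + right


# ---------------------------------------------------------------------------
# LPR annotation


def test_canonical_concatenation_decomposed(units):
    u66, u42, left, right = units
    s = orf1.annotate_lpr(_mk(left, right, u66, u42), [u66, u42],
                          (left, right))
    assert s.structure == "66-42"


def test_internal_deletion_reported_as_45(units):
    u66, u42, left, right = units
    u45 = u66[:20] + u66[41:]   # 21 bp internal deletion
    s = orf1.annotate_lpr(_mk(left, right, u45, u66), [u66, u42],
                          (left, right))
    assert s.structure == "45-66"


def test_four_unit_expansion(units):
    u66, u42, left, right = units
    s = orf1.annotate_lpr(_mk(left, right, u66, u42, u42, u42), [u66, u42],
                          (left, right))
    assert s.structure == "66-42-42-42"


def test_annotation_idempotent_and_flank_invariant(units):
    u66, u42, left, right = units
    seq = _mk(left, right, u66, u42)
    s1 = orf1.annotate_lpr(seq, [u66, u42], (left, right))
    s2 = orf1.annotate_lpr("GGCCA" * 30 + seq + "TTAAC" * 30, [u66, u42],
                           (left, right))
    assert s1.structure == s2.structure == "66-42"


def test_unmatchable_region_unresolved(units):
    u66, u42, left, right = units
    rng = np.random.default_rng(5)
    noise = sim.random_sequence(rng, 108)
    s = orf1.annotate_lpr(_mk(left, right, noise), [u66, u42], (left, right))
    assert s.structure == "unresolved"


def test_mutated_units_still_resolved(units):
    u66, u42, left, right = units
    rng = np.random.default_rng(6)
    seq = sim.evolve(_mk(left, right, u66, u42, u42), 0.08, rng)
    s = orf1.annotate_lpr(seq, [u66, u42], (left, right))
    assert s.structure == "66-42-42"


# ---------------------------------------------------------------------------
# unit-edit distance and Sankoff


def test_unit_edit_distance_examples():
    d = orf1.unit_edit_distance
    assert d("66-66", "66-66") == 0
    assert d("66-66", "66-42") == 1       # length change
    assert d("66-42", "66-42-42") == 1    # duplication
    assert d("66-66", "66-42-42") == 2


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["66", "42", "45", "56"]), min_size=1,
                max_size=4),
       st.lists(st.sampled_from(["66", "42", "45", "56"]), min_size=1,
                max_size=4))
def test_unit_edit_distance_is_symmetric_metric(a, b):
    sa, sb = "-".join(a), "-".join(b)
    d = orf1.unit_edit_distance
    assert d(sa, sb) == d(sb, sa)
    assert (d(sa, sb) == 0) == (sa == sb)
    assert d(sa, sb) <= max(len(a), len(b))


def _brute_sankoff(tree, structs):
    states = sorted(set(structs.values()))
    internals = [n for n in tree.walk() if not n.is_leaf]
    best = 10 ** 9
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        total = 0
        for node in internals:
            for child in node.children:
                cs = structs[child.name] if child.is_leaf else assign[id(child)]
                total += orf1.unit_edit_distance(assign[id(node)], cs)
        best = min(best, total)
    return best


def test_uniform_leaves_need_no_events():
    tree = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    total, events = orf1.reconstruct_lpr_history(
        tree, dict.fromkeys("abcd", "66-66"))
    assert total == 0 and events == []


def test_sankoff_matches_exhaustive_minimum():
    tree = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    structs = {"a": "66-66", "b": "66-66", "c": "66-42", "d": "66-42-42",
               "e": "66-66"}
    total, events = orf1.reconstruct_lpr_history(tree, structs)
    assert total == _brute_sankoff(tree, structs)
    assert sum(c for _, _, c in events) == total


def test_sankoff_random_cases_match_brute_force():
    rng = np.random.default_rng(7)
    tree = phylo.parse_newick("((a:1,b:1):1,((c:1,d:1):1,e:1):1,f:1);")
    pool = ["66-66", "66-42", "66-42-42", "45-66", "66"]
    for _ in range(10):
        structs = {l: pool[rng.integers(0, len(pool))] for l in "abcdef"}
        total, _ = orf1.reconstruct_lpr_history(tree, structs)
        assert total == _brute_sankoff(tree, structs)


def test_unresolved_leaves_excluded():
    tree = phylo.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
    structs = {"a": "66-66", "b": "66-66", "c": "unresolved", "d": "66-66"}
    total, events = orf1.reconstruct_lpr_history(tree, structs)
    assert total == 0


# ---------------------------------------------------------------------------
# coiled coil


def _ideal(n_heptads):
    return "LSELSEK" * n_heptads   # hydrophobic L at registers a and d


def test_ideal_heptads_full_span():
    cc = orf1.predict_coiled_coil(_ideal(10))
    assert cc.span == (0, 70)
    assert cc.heptads == 10


def test_poly_serine_has_no_coiled_coil():
    cc = orf1.predict_coiled_coil("S" * 100)
    assert cc.span is None and cc.heptads == 0


def test_heptad_count_monotone_in_inserted_heptads():
    counts = [orf1.predict_coiled_coil(_ideal(k)).heptads
              for k in range(4, 13)]
    assert counts == sorted(counts)
    assert counts[-1] == 12


def test_short_protein_returns_empty():
    cc = orf1.predict_coiled_coil("LSELS")
    assert cc.span is None


def test_simulated_orf1_coiled_coil_found_at_lpr():
    from Bio.Seq import Seq

    element, _ = sim.build_ancestral_element(0, ("Lx",))
    reg = sim.element_regions()
    orf1_nt = element[slice(*reg["orf1"])]
    prot = str(Seq(orf1_nt[:-3]).translate())
    cc = orf1.predict_coiled_coil(prot)
    lpr_aa = ((reg["lpr"][0] - reg["orf1"][0]) // 3,
              (reg["lpr"][1] - reg["orf1"][0]) // 3)
    assert cc.span is not None
    overlap = min(cc.span[1], lpr_aa[1]) - max(cc.span[0], lpr_aa[0])
    assert overlap >= 30   # the LPR-encoded heptads dominate the span
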