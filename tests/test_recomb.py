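"""Recombination detection: MaxChi, bootscan, triplet scan, verification,
segmentation."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from l1evo import recomb, simulate as sim


def test_chi_square_matches_hand_computed_table():
    # left window: 20 mismatches / 5 matches; right: 0 / 25
    assert recomb.chi2_2x2(20, 5, 0, 25) == pytest.approx(100 / 3, abs=1e-9)


def test_chi_square_matches_scipy_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b, c, d = rng.integers(1, 40, size=4)
        ours = recomb.chi2_2x2(a, b, c, d)
        ref = chi2_contingency(np.array([[a, b], [c, d]]),
                               correction=False).statistic
        assert ours == pytest.approx(ref, abs=1e-9)


def test_homogeneous_pair_not_significant(rng):
    false_calls = 0
    n_reps = 20
    for rep in range(n_reps):
        a = sim.random_sequence(rng, 1500)
        b = sim.evolve(a, 0.10, rng)
        res = recomb.maxchi_scan({"a": a, "b": b}, n_perm=200, seed=rep)
        if res is not None and res["p_perm"] <= 0.05:
            false_calls += 1
    assert false_calls <= 1   # <=5% of 20


def test_constructed_mosaic_breakpoint_within_window(rng):
    hits = 0
    n = 30
    for rep in range(n):
        a = sim.random_sequence(rng, 1000)
        b = sim.evolve(a, 0.107, rng)   # ~10% observed divergence
        c = a[:500] + b[500:]
        res = recomb.maxchi_scan({"c": c, "a": a, "b": b}, n_perm=100,
                                 seed=rep)
        mid = (res["interval"][0] + res["interval"][1]) // 2
        hits += abs(mid - 500) <= recomb.WINDOW_BP
    assert hits >= 0.9 * n


def test_too_few_variable_sites_gives_no_call(rng):
    a = sim.random_sequence(rng, 500)
    res = recomb.maxchi_scan({"a": a, "b": a}, n_perm=50, seed=0)
    assert res is None


# ---------------------------------------------------------------------------
# bootscan


@pytest.fixture(scope="module")
def bootscan_setup():
    rng = np.random.default_rng(3)
    anc = sim.random_sequence(rng, 2000)
    refs = {f"r{i}": sim.evolve(anc, 0.10, rng) for i in range(3)}
    clean = sim.evolve(refs["r0"], 0.01, rng)
    mosaic = refs["r0"][:1000] + refs["r2"][1000:]
    mosaic = sim.evolve(mosaic, 0.01, rng)
    return refs, clean, mosaic


def test_bootscan_traces_bounded_and_no_crossover_for_clean_query(
        bootscan_setup):
    refs, clean, _ = bootscan_setup
    centres, traces, crossings = recomb.bootscan(
        clean, refs, window_bp=400, step_bp=100, n_boot=40, seed=0)
    stack = np.vstack([traces[l] for l in sorted(traces)])
    valid = ~np.isnan(stack)
    assert (stack[valid] >= 0).all() and (stack[valid] <= 100).all()
    assert np.nansum(stack, axis=0).max() <= 100.0 + 1e-9
    assert crossings == []


def test_bootscan_finds_single_crossover_in_mosaic(bootscan_setup):
    refs, _, mosaic = bootscan_setup
    centres, traces, crossings = recomb.bootscan(
        mosaic, refs, window_bp=400, step_bp=50, n_boot=40, seed=1)
    assert len(crossings) == 1
    pos, left, right = crossings[0]
    assert {left, right} == {"r0", "r2"}
    assert abs(pos - 1000) <= 400


def test_bootscan_requires_three_references():
    with pytest.raises(ValueError, match="at least 3"):
        recomb.bootscan("ACGT", {"a": "ACGT", "b": "ACGT"})


# ---------------------------------------------------------------------------
# triplet scan and verification


def test_equidistant_sequences_give_no_events(rng):
    anc = sim.random_sequence(rng, 2000)
    aln = {f"s{i}": sim.evolve(anc, 0.05, rng) for i in range(3)}
    events = recomb.triplet_scan(aln, n_perm=200, seed=0)
    assert events == []


def test_simulated_template_switch_recovered_with_orientation():
    cfg = sim.SimConfig(
        seed=3, n_families=8,
        family_activity_times=(9.2, 7.5, 6.4, 4.6, 3.2, 2.2, 1.2, 0.25),
        promoter_replacement_events=((1, "Fanc"), (2, "F"), (4, "A"),
                                     (6, "Mus")),
        recombination_events=((6, 2, 2500),))
    fams = sim.simulate_family_history(cfg)
    o1 = sim.element_regions()["orf1"][0]
    aln = {f.label: f.progenitor[o1:] for f in fams}
    ages = {f.label: f.activity_time for f in fams}
    events = recomb.detect_events(aln, n_perm=300, seed=7, ages=ages)
    verified = [e for e in events if e.verified]
    assert verified
    true_bp = 2500 - o1
    matching = [e for e in verified
                if abs(e.breakpoint - true_bp) <= 150
                and {"fam6", "fam2"} & {e.recipient, e.donor}]
    assert matching
    # age orientation: the younger family is the recipient
    for e in matching:
        if {e.recipient, e.donor} == {"fam6", "fam2"}:
            assert e.recipient == "fam6"


def test_duplicate_events_collapse(rng):
    ev = [recomb.RecombinationEvent("x", "y", (100, 120), {"triplet"},
                                    10, 0.01, 0.01),
          recomb.RecombinationEvent("x", "z", (110, 130), {"chimaera-like"},
                                    9, 0.02, 0.02)]
    kept = recomb._dedupe(ev)
    assert len(kept) == 1
    assert kept[0].methods == {"triplet", "chimaera-like"}


def test_breakpoint_at_alignment_edge_unverifiable(rng):
    aln = {f"s{i}": sim.random_sequence(rng, 1000) for i in range(4)}
    ev = recomb.RecombinationEvent("s0", "s1", (50, 60))
    assert recomb.verify_breakpoint(aln, ev) is False
    assert ev.reason == "flank shorter than 200 bp"


def test_injected_false_candidate_rarely_verifies(rng):
    wrong = 0
    n_reps = 20
    for rep in range(n_reps):
        anc = sim.random_sequence(rng, 2000)
        aln = {f"s{i}": sim.evolve(anc, 0.05, rng) for i in range(5)}
        ev = recomb.RecombinationEvent("s0", "s1", (995, 1005))
        if recomb.verify_breakpoint(aln, ev, seed=rep):
            wrong += 1
    assert wrong <= 0.05 * n_reps


# ---------------------------------------------------------------------------
# segmentation


def test_segments_whole_alignment_without_events():
    assert recomb.segment_alignment(5000, []) == [(1, 5000)]


def test_segments_split_at_breakpoint_midpoints():
    ev = recomb.RecombinationEvent("a", "b", (1000, 1000), verified=True)
    assert recomb.segment_alignment(5000, [ev]) == [(1, 1000), (1001, 5000)]
    ev2 = recomb.RecombinationEvent("a", "c", (3000, 3000), verified=True)
    assert recomb.segment_alignment(5000, [ev, ev2]) == \
        [(1, 1000), (1001, 3000), (3001, 5000)]


def test_unverified_events_do_not_split():
    ev = recomb.RecombinationEvent("a", "b", (1000, 1000), verified=False)
    assert recomb.segment_alignment(5000, [ev]) == [(1, 5000)]
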