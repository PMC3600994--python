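"""Structural analysis of ORF1: the length polymorphism region (LPR) and the
coiled-coil domain.

The LPR is a tandem array of ~66 bp and ~42 bp units inside the coiled-coil
portion of ORF1 whose unit composition differs between families (66-66
ancestrally, duplications and internal deletions later).  ``annotate_lpr``
decomposes a family's LPR into canonical units by greedy left-to-right
prefix alignment, labelling each unit by the length it actually occupies, so
deletion variants surface as 45 or 56 bp units without being pre-declared.
``reconstruct_lpr_history`` places unit-edit events on a family tree by
Sankoff parsimony.  ``predict_coiled_coil`` scores heptad periodicity
(hydrophobic residues at registers a and d) with a sliding window over a
normalised Kyte-Doolittle propensity and reports the maximal span and its
heptad count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .phylo import Node

__all__ = [
    "LprStructure",
    "CoiledCoilAnnotation",
    "annotate_lpr",
    "unit_edit_distance",
    "reconstruct_lpr_history",
    "predict_coiled_coil",
]

IDENTITY_FLOOR = 0.60
MIN_UNIT = 21
CC_THRESHOLD = 0.70
CC_WINDOW = 21

# normalised Kyte-Doolittle hydropathy, mapped to [0, 1]
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
HYDRO = {aa: (kd + 4.5) / 9.0 for aa, kd in _KD.items()}


@dataclass
class LprStructure:
    units: list                  # occupied lengths, 5'->3'
    identities: list             # per-unit identity to its canonical unit
    span: tuple                  # (start, end) on the ORF1 nucleotide
    resolved: bool = True

    @property
    def structure(self) -> str:
        if not self.resolved:
            return "unresolved"
        return "-".join(str(u) for u in self.units)


@dataclass
class CoiledCoilAnnotation:
    span: tuple | None           # (start, end) aa interval on the protein
    heptads: int
    scores: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# LPR


def _prefix_fit(unit: str, target: str):
    """Align the full unit to a prefix of target (free end in target);
    returns (consumed target length, identity)."""
    if not target:
        return None
    res = edlib.align(unit, target, mode="SHW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    end = res["locations"][0][1] + 1
    ident = 1.0 - res["editDistance"] / len(unit)
    return end, ident


def annotate_lpr(orf1_nt: str, canonical_units: list, flanks: tuple,
                 identity_floor: float = IDENTITY_FLOOR) -> LprStructure:
    """Decompose the LPR of one ORF1 into canonical units.

    ``canonical_units`` are the unit nucleotide sequences of the ancestral
    state (typically one 66 bp and one 42 bp unit); ``flanks`` is a pair of
    conserved ORF1 sequences bounding the LPR, located by alignment so the
    decomposition is invariant to coordinate shifts.  Units are labelled by
    the target length they occupy, so internal deletions of a canonical unit
    appear as shorter labels (e.g. 45 = 66 - 21).
    """
    left, right = flanks
    lres = edlib.align(left, orf1_nt, mode="HW", task="locations")
    rres = edlib.align(right, orf1_nt, mode="HW", task="locations")
    if lres["editDistance"] < 0 or rres["editDistance"] < 0 \
            or not lres["locations"] or not rres["locations"]:
        return LprStructure([], [], (0, 0), resolved=False)
    span_lo = lres["locations"][0][1] + 1
    span_hi = rres["locations"][0][0]
    if span_hi - span_lo < MIN_UNIT:
        return LprStructure([], [], (span_lo, span_hi), resolved=False)
    region = orf1_nt[span_lo:span_hi]

    units = []
    idents = []
    pos = 0
    while len(region) - pos >= MIN_UNIT:
        best = None
        for unit in canonical_units:
            fit = _prefix_fit(unit, region[pos:pos + len(unit) + 15])
            if fit is None:
                continue
            consumed, ident = fit
            if consumed < MIN_UNIT:
                continue
            if best is None or ident > best[1]:
                best = (consumed, ident, len(unit))
        if best is None or best[1] < identity_floor:
            break
        consumed, ident, canon = best
        # a substitution at a unit boundary can shift the consumed length by
        # a base or two; snap to the canonical length in that case (true
        # deletion variants differ by far more and keep their length label)
        label = canon if abs(consumed - canon) <= 2 else consumed
        units.append(label)
        idents.append(ident)
        pos += consumed
    if not units:
        return LprStructure([], [], (span_lo, span_hi), resolved=False)
    return LprStructure(units, idents, (span_lo, span_lo + pos))


# ---------------------------------------------------------------------------
# history by Sankoff parsimony


def unit_edit_distance(s1: str, s2: str) -> int:
    """Edit distance between unit structures (e.g. '66-42' vs '66-42-42'):
    unit insertion, deletion and length change each cost 1."""
    if s1 == "unresolved" or s2 == "unresolved":
        raise ValueError("unresolved structure")
    a = s1.split("-") if s1 else []
    b = s2.split("-") if s2 else []
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dp[i - 1, j - 1] + (a[i - 1] != b[j - 1])
            dp[i, j] = min(sub, dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    return int(dp[n, m])


def reconstruct_lpr_history(tree: Node, structures: dict):
    """Sankoff parsimony of LPR structures on a fixed tree.

    The state space is the set of observed (resolved) leaf structures and
    transition cost is the unit-edit distance.  Leaves with unresolved
    structures are excluded.  Returns (total event cost, per-edge events) as
    a list of (parent state, child state, cost) for edges with change.
    """
    usable = {k: v for k, v in structures.items() if v != "unresolved"}
    states = sorted(set(usable.values()))
    if not states:
        raise ValueError("no resolved structures")
    cost = {(x, y): unit_edit_distance(x, y) for x in states for y in states}
    INF = 10 ** 9
    tables: dict = {}

    def down(node):
        if node.is_leaf:
            if node.name not in usable:
                return None
            tables[id(node)] = {s: (0 if s == usable[node.name] else INF)
                                for s in states}
            return tables[id(node)]
        child_tables = [t for t in (down(c) for c in node.children)
                        if t is not None]
        if not child_tables:
            return None
        out = {s: sum(min(t[x] + cost[(s, x)] for x in states)
                      for t in child_tables)
               for s in states}
        tables[id(node)] = out
        return out

    root_table = down(tree)
    if root_table is None:
        raise ValueError("no resolved structures on the tree")
    total = min(root_table.values())

    events = []

    def up(node, state):
        for child in node.children:
            table = tables.get(id(child))
            if table is None:
                continue
            best = min(states, key=lambda x: (table[x] + cost[(state, x)], x))
            if best != state:
                events.append((state, best, cost[(state, best)]))
            if not child.is_leaf:
                up(child, best)

    root_state = min(states, key=lambda s: (root_table[s], s))
    up(tree, root_state)
    return total, events


# ---------------------------------------------------------------------------
# coiled coil


def predict_coiled_coil(protein: str, window: int = CC_WINDOW,
                        threshold: float = CC_THRESHOLD) -> CoiledCoilAnnotation:
    """Heptad-periodicity scan of a protein.

    Every window is scored under each of the 7 register phases as the mean
    hydrophobicity at the a/d positions minus the mean elsewhere, rescaled to
    [0, 1]; a residue's score is the best score of any window covering it.
    The longest contiguous run of residues above ``threshold`` is reported
    with its heptad count (span length div 7).
    """
    n = len(protein)
    if n < window:
        return CoiledCoilAnnotation(None, 0)
    h = np.array([HYDRO.get(aa, 0.5) for aa in protein])
    scores = np.zeros(n)
    for start in range(0, n - window + 1):
        seg = h[start:start + window]
        best = 0.0
        for phase in range(7):
            reg = (np.arange(window) + phase) % 7
            ad = (reg == 0) | (reg == 3)
            if ad.sum() == 0 or (~ad).sum() == 0:
                continue
            diff = seg[ad].mean() - seg[~ad].mean()
            best = max(best, (diff + 1.0) / 2.0)
        scores[start:start + window] = np.maximum(
            scores[start:start + window], best)
    above = scores >= threshold
    best_span = None
    run_start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if best_span is None or i - run_start > best_span[1] - best_span[0]:
                best_span = (run_start, i)
            run_start = None
    if best_span is None:
        return CoiledCoilAnnotation(None, 0, scores)
    heptads = (best_span[1] - best_span[0]) // 7
    return CoiledCoilAnnotation(best_span, heptads, scores)
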