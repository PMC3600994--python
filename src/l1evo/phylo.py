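"""Distance-based phylogenetics: substitution-model distances, neighbor joining,
bootstrap support, and parsimony counting of discrete character changes.

All trees are unrooted and represented by a :class:`Node` rooted at a basal
trifurcation (the usual convention for neighbor-joining output).  Distances are
substitutions/site under the p, Jukes-Cantor (JC), Kimura 2-parameter (K2P) or
Tamura-Nei (TN93) corrections, computed with pairwise deletion of gap and
ambiguous columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Node",
    "DistanceMatrix",
    "encode_alignment",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "fitch_changes",
    "parse_newick",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MODELS = ("p", "JC", "K2P", "TN93")


# ---------------------------------------------------------------------------
# tree structure


class Node:
    """A tree node.  ``length`` is the branch to the parent; ``support`` is the
    bootstrap percentage of that branch (internal edges only)."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name=None, length=0.0, children=None, support=None):
        self.name = name
        self.length = float(length)
        self.children = list(children) if children else []
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> dict[frozenset, "Node"]:
        """Map each internal edge (edge above a non-root internal node) to the
        frozenset of leaf names on its child side."""
        out = {}
        for child in self.children:
            for node in child.walk():
                if not node.is_leaf and node.children:
                    out[frozenset(node.leaf_names())] = node
        # drop trivial splits (all leaves)
        all_leaves = frozenset(self.leaf_names())
        out.pop(all_leaves, None)
        return out

    def newick(self, include_support: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaves."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        n = len(leaves)
        dist = np.zeros((n, n))
        index = {id(l): i for i, l in enumerate(leaves)}

        def below(node):
            # returns {leaf_index: depth from node}
            if node.is_leaf:
                return {index[id(node)]: 0.0}
            merged = {}
            groups = []
            for c in node.children:
                d = {k: v + c.length for k, v in below(c).items()}
                groups.append(d)
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i, di in groups[a].items():
                        for j, dj in groups[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            for g in groups:
                merged.update(g)
            return merged

        below(self)
        return names, dist


def parse_newick(text: str) -> Node:
    """Minimal newick parser (names, branch lengths, internal support labels)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node():
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    return parse_node()


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    model: str = "p"
    saturated: np.ndarray | None = None  # boolean mask of saturated pairs

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.saturated is None:
            self.saturated = np.zeros_like(self.values, dtype=bool)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.model, self.saturated[np.ix_(idx, idx)])

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def encode_alignment(seqs: list[str]) -> np.ndarray:
    """Encode sequences as uint8 (A=0,C=1,G=2,T=3, anything else=4)."""
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal aligned length")
    table = np.full(256, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return table[arr].reshape(len(seqs), -1)


def _pair_counts(enc: np.ndarray):
    """Pairwise comparable-site, mismatch, transition and transversion counts
    via indicator matrix products."""
    valid = (enc < 4).astype(np.float64)
    comparable = np.rint(valid @ valid.T)
    ind = [(enc == b).astype(np.float64) for b in range(4)]
    matches = np.rint(sum(ib @ ib.T for ib in ind))
    mismatch = comparable - matches
    ag = ind[0] @ ind[2].T
    ct = ind[1] @ ind[3].T
    transitions = np.rint(ag + ag.T + ct + ct.T)
    transversions = mismatch - transitions
    return comparable, mismatch, transitions, transversions


def pairwise_distance(labels, seqs, model: str = "JC") -> DistanceMatrix:
    """Pairwise substitution-model distances with pairwise deletion.

    Saturated pairs (where the model's log argument is <= 0) are flagged in
    ``saturated`` and set to NaN.  A pair with zero comparable sites raises.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    enc = seqs if isinstance(seqs, np.ndarray) else encode_alignment(list(seqs))
    comparable, mismatch, transitions, transversions = _pair_counts(enc)
    n = len(labels)
    bad = (comparable == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(comparable > 0, mismatch / comparable, 0.0)
        P = np.where(comparable > 0, transitions / comparable, 0.0)
        Q = np.where(comparable > 0, transversions / comparable, 0.0)
        if model == "p":
            d = p
        elif model == "JC":
            arg = 1.0 - 4.0 * p / 3.0
            d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        elif model == "K2P":
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            ok = (a1 > 0) & (a2 > 0)
            d = np.where(
                ok,
                -0.5 * np.log(np.where(a1 > 0, a1, 1.0))
                - 0.25 * np.log(np.where(a2 > 0, a2, 1.0)),
                np.nan,
            )
        else:  # TN93 with empirical base frequencies over the whole alignment
            d = _tn93(enc, P, Q, comparable,
                      (pairwise_transition_split(enc)))
    np.fill_diagonal(d, 0.0)
    sat = np.isnan(d)
    np.fill_diagonal(sat, False)
    return DistanceMatrix(labels, d, model, sat)


def pairwise_transition_split(enc: np.ndarray):
    """Purine (A<->G) and pyrimidine (C<->T) transition proportions per pair."""
    valid = (enc < 4).astype(np.float64)
    comparable = np.rint(valid @ valid.T)
    ind = [(enc == b).astype(np.float64) for b in range(4)]
    ag = ind[0] @ ind[2].T
    ct = ind[1] @ ind[3].T
    with np.errstate(invalid="ignore"):
        P1 = np.where(comparable > 0, (ag + ag.T) / comparable, 0.0)
        P2 = np.where(comparable > 0, (ct + ct.T) / comparable, 0.0)
    return P1, P2


def _tn93(enc, P, Q, comparable, split):
    P1, P2 = split
    counts = np.bincount(enc[enc < 4].ravel(), minlength=4).astype(float)
    freqs = counts / counts.sum()
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
    w3 = 1.0 - Q / (2.0 * gR * gY)
    ok = (w1 > 0) & (w2 > 0) & (w3 > 0)
    safe = lambda w: np.where(w > 0, w, 1.0)
    d = np.where(ok, -k1 * np.log(safe(w1)) - k2 * np.log(safe(w2))
                 - k3 * np.log(safe(w3)), np.nan)
    return d


# closed forms for two-sequence convenience ---------------------------------

def jc_distance(p: float) -> float:
    """JC correction of a raw proportion of differences."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken deterministically by the lexicographically smallest
    (label, label) pair.  Negative branch lengths are clamped to zero.
    """
    d = np.array(matrix.values, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains saturated/NaN entries")
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(name=l) for l in labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        # deterministic tie-break on label pair
        def key(ij):
            a, b = nodes[active[ij[0]]], nodes[active[ij[1]]]
            la = a.name if a.name else min(a.leaf_names())
            lb = b.name if b.name else min(b.leaf_names())
            return tuple(sorted((la, lb)))
        i, j = min(map(tuple, ties), key=key)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[ai].length = li
        nodes[aj].length = lj
        parent = Node(children=[nodes[ai], nodes[aj]])
        # distances from new node to remaining
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    i, j = active
    dij = d[i, j]
    if nodes[i].is_leaf and not nodes[j].is_leaf:
        i, j = j, i
    root = nodes[i]
    if root.is_leaf:
        # two-leaf edge case cannot occur (n >= 3) but keep safe
        root = Node(children=[nodes[i], nodes[j]])
        nodes[j].length = dij
    else:
        nodes[j].length = max(dij, 0.0)
        root.children.append(nodes[j])
    return root


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(labels, seqs, model: str = "JC", n_reps: int = 100,
                      seed: int | None = 0, tree: Node | None = None) -> Node:
    """Attach bootstrap percentages to the NJ tree of an alignment.

    Columns are resampled with replacement ``n_reps`` times; support of each
    internal edge is the percentage of replicate trees containing the same
    bipartition.  Replicates whose resampled matrix is saturated are redrawn
    (up to 10x oversampling) and otherwise skipped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = list(labels)
    enc = seqs if isinstance(seqs, np.ndarray) else encode_alignment(list(seqs))
    if tree is None:
        tree = neighbor_joining(pairwise_distance(labels, enc, model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    L = enc.shape[1]
    done = 0
    attempts = 0
    while done < n_reps and attempts < 10 * n_reps:
        attempts += 1
        cols = rng.integers(0, L, size=L)
        try:
            dm = pairwise_distance(labels, enc[:, cols], model)
            rep = neighbor_joining(dm)
        except ValueError:
            continue
        done += 1
        rep_bps = set(rep.bipartitions())
        full = frozenset(labels)
        for bp in counts:
            if bp in rep_bps or (full - bp) in rep_bps:
                counts[bp] += 1
    if done == 0:
        raise ValueError("all bootstrap replicates failed (saturation)")
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / done
    return tree


# ---------------------------------------------------------------------------
# parsimony


def fitch_changes(tree: Node, leaf_states: dict) -> int:
    """Minimum number of state changes of a discrete character on a fixed
    topology (Hartigan's generalization of Fitch parsimony, exact for
    multifurcating nodes such as the basal trifurcation)."""
    changes = 0

    def up(node) -> set:
        nonlocal changes
        if node.is_leaf:
            if node.name not in leaf_states:
                raise ValueError(f"leaf {node.name!r} has no state")
            return {leaf_states[node.name]}
        tally: dict = {}
        for child in node.children:
            for s in up(child):
                tally[s] = tally.get(s, 0) + 1
        k = max(tally.values())
        changes += len(node.children) - k
        return {s for s, c in tally.items() if c == k}

    up(tree)
    return changes
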