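"""Detection of inter-family recombination among consensus sequences.

Template-switch recombination between L1 families leaves mosaic consensuses:
one stretch of the element groups with one family, the rest with another.
Three complementary scans locate such mosaics on an alignment of family
consensuses:

* ``maxchi_scan`` - the MaxChi statistic: a 2x2 chi-square of match/mismatch
  counts of a sequence pair in 50 bp windows flanking each candidate point,
  maximised along the alignment, with significance from permutation of
  column order.
* a Chimaera-like variant - the same flank chi-square restricted to
  informative sites where the putative recombinant matches exactly one of
  two putative parents; this is the engine of the triplet scan.
* ``bootscan`` - sliding-window bootstrap neighbor joining of a query
  against references, calling a crossover where the best-supported
  relative changes.

Candidate events are verified by comparing bootstrap NJ trees built from the
alignment on each side of the putative breakpoint: a true recombinant changes
its supported sister group between flanks.  Verified breakpoints partition
the alignment into recombination-free segments for downstream phylogenetic
and selection analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from . import phylo

__all__ = [
    "RecombinationEvent",
    "maxchi_scan",
    "bootscan",
    "triplet_scan",
    "verify_breakpoint",
    "segment_alignment",
    "detect_events",
    "chi2_2x2",
]

WINDOW_BP = 50
STEP_BP = 10
N_PERM = 1000
TRACE_THRESHOLD = 70.0
VERIFY_SUPPORT = 70.0
MIN_SEGMENT = 300
MIN_VAR_SITES = 20
ALPHA = 0.05


@dataclass
class RecombinationEvent:
    recipient: str
    donor: str                      # family label or "unknown"
    interval: tuple                 # 1-based inclusive (lo, hi) on alignment
    methods: set = field(default_factory=set)
    max_chi: float = 0.0
    p_perm: float = 1.0
    p_corrected: float = 1.0        # analytic, Bonferroni over positions+tests
    verified: bool = False
    reason: str = ""

    @property
    def breakpoint(self) -> int:
        return (self.interval[0] + self.interval[1]) // 2


def chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Chi-square of the 2x2 table [[a, b], [c, d]] (no continuity
    correction): n*(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


# ---------------------------------------------------------------------------
# MaxChi


def _comparable_mismatch(x: str, y: str):
    """(alignment positions, mismatch indicator) over columns where both
    sequences have unambiguous bases."""
    ex = phylo.encode_alignment([x, y])
    ok = (ex[0] < 4) & (ex[1] < 4)
    pos = np.nonzero(ok)[0]
    mism = (ex[0, ok] != ex[1, ok]).astype(np.int64)
    return pos, mism


MIN_FLANK_SITES = 10


def _window_chi(mism: np.ndarray, window: int):
    """Chi-square trace over candidate split points (in comparable-column
    index space); split k compares [k-lw, k) with [k, k+rw) where the flank
    windows are ``window`` sites, truncated near the edges (>= MIN_FLANK_SITES
    so breakpoints close to the alignment ends remain detectable)."""
    n = mism.size
    if n < 2 * MIN_FLANK_SITES:
        return None, None
    cs = np.concatenate([[0], np.cumsum(mism)])
    ks = np.arange(MIN_FLANK_SITES, n - MIN_FLANK_SITES + 1)
    lw = np.minimum(window, ks)
    rw = np.minimum(window, n - ks)
    left_mis = cs[ks] - cs[ks - lw]
    right_mis = cs[ks + rw] - cs[ks]
    a, b = left_mis, lw - left_mis
    c, d = right_mis, rw - right_mis
    tot = (lw + rw).astype(float)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, tot * (a * d - b * c) ** 2 / denom, 0.0)
    return ks, chi


def maxchi_scan(seqs: dict, window_bp: int = WINDOW_BP, n_perm: int = N_PERM,
                seed: int = 0, min_var: int = MIN_VAR_SITES):
    """MaxChi scan of a pair (or Chimaera-like scan of a triplet).

    ``seqs`` maps 2 labels (pair mode: mismatch indicator along comparable
    columns) or 3 labels (triplet mode: the first label is the putative
    recombinant; sites restricted to those where it matches exactly one of
    the other two).  Returns a dict with the maximising position (1-based
    alignment coordinate interval), the chi-square, a permutation p for the
    maximum, and the analytic position-corrected p; or None when fewer than
    ``min_var`` variable sites are available.
    """
    labels = list(seqs)
    rng = np.random.default_rng(seed)
    if len(labels) == 2:
        pos, vec = _comparable_mismatch(seqs[labels[0]], seqs[labels[1]])
        if vec.sum() < min_var:
            return None
    elif len(labels) == 3:
        child, pa, pb = labels
        enc = phylo.encode_alignment([seqs[child], seqs[pa], seqs[pb]])
        ok = (enc < 4).all(axis=0)
        informative = ok & (enc[1] != enc[2]) & \
            ((enc[0] == enc[1]) | (enc[0] == enc[2]))
        pos = np.nonzero(informative)[0]
        if pos.size < min_var:
            return None
        vec = (enc[0, pos] == enc[1, pos]).astype(np.int64)
    else:
        raise ValueError("maxchi_scan takes 2 or 3 sequences")

    window = window_bp
    ks, chi = _window_chi(vec, window)
    if ks is None:
        return None
    i = int(np.argmax(chi))
    obs = float(chi[i])
    k = int(ks[i])
    p_perm = _perm_pvalue(vec, window, obs, n_perm, rng)
    n_positions = len(ks)
    p_corr = min(1.0, float(chi2_dist.sf(obs, 1)) * n_positions)
    lo = int(pos[k - 1]) + 1
    hi = int(pos[k]) + 1
    return {
        "interval": (lo, hi),
        "chi": obs,
        "p_perm": p_perm,
        "p_corrected": p_corr,
        "split_index": k,
        "positions": pos,
        "vector": vec,
    }


def _perm_pvalue(vec: np.ndarray, window: int, obs: float, n_perm: int,
                 rng) -> float:
    """P(max window chi-square >= obs) under permutation of column order,
    all permutations evaluated vectorised."""
    n = vec.size
    mat = np.tile(vec, (n_perm, 1))
    mat = rng.permuted(mat, axis=1)
    cs = np.zeros((n_perm, n + 1))
    np.cumsum(mat, axis=1, out=cs[:, 1:])
    ks = np.arange(MIN_FLANK_SITES, n - MIN_FLANK_SITES + 1)
    lw = np.minimum(window, ks)
    rw = np.minimum(window, n - ks)
    left = cs[:, ks] - cs[:, ks - lw]
    right = cs[:, ks + rw] - cs[:, ks]
    a, b = left, lw - left
    c, d = right, rw - right
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0,
                       (lw + rw) * (a * d - b * c) ** 2 / denom, 0.0)
    exceed = int(np.sum(chi.max(axis=1) >= obs))
    return (exceed + 1) / (n_perm + 1)


def consolidate_events(events: list, gap: int = 150) -> list:
    """Collapse verified events into distinct breakpoint clusters.

    Echo detections (one recombination surfacing in several triplets and in
    descendants of the recipient) share a breakpoint; clustering breakpoints
    closer than ``gap`` and keeping each cluster's most significant event
    yields the minimum number of distinct recombination events.
    """
    ver = sorted((e for e in events if e.verified), key=lambda e: e.breakpoint)
    clusters: list[list] = []
    for ev in ver:
        if clusters and ev.breakpoint - clusters[-1][-1].breakpoint <= gap:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    out = []
    for cl in clusters:
        best = min(cl, key=lambda e: (e.p_corrected, e.p_perm, e.recipient))
        for e in cl:
            best.methods |= e.methods
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# bootscan


def bootscan(query: str, references: dict, window_bp: int = 400,
             step_bp: int = STEP_BP, n_boot: int = 100, seed: int = 0,
             trace_threshold: float = TRACE_THRESHOLD, model: str = "JC"):
    """Sliding-window bootstrap NJ support for the query grouping with each
    reference.

    Returns (window centres, traces dict label -> % support, crossovers)
    where a crossover is (position, left label, right label), called where
    the top-supported reference changes with both sides >= trace_threshold.
    Windows with <5 variable sites yield a trace gap (NaN).
    """
    if len(references) < 3:
        raise ValueError("bootscan needs at least 3 references")
    labels = ["query"] + sorted(references)
    seqs = [query] + [references[l] for l in labels[1:]]
    enc = phylo.encode_alignment(seqs)
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    centres = []
    traces = {l: [] for l in labels[1:]}
    for start in range(0, L - window_bp + 1, step_bp):
        sub = enc[:, start:start + window_bp]
        centres.append(start + window_bp // 2)
        var = np.sum((sub < 4).all(axis=0) & (sub != sub[0]).any(axis=0))
        if var < 5:
            for l in labels[1:]:
                traces[l].append(np.nan)
            continue
        wins = {l: 0 for l in labels[1:]}
        good = 0
        for _ in range(n_boot):
            cols = rng.integers(0, window_bp, size=window_bp)
            try:
                dm = phylo.pairwise_distance(labels, sub[:, cols], model)
                tree = phylo.neighbor_joining(dm)
            except ValueError:
                continue
            good += 1
            sister = _sister_leaves(tree, "query")
            if len(sister) == 1:
                wins[next(iter(sister))] += 1
        for l in labels[1:]:
            traces[l].append(100.0 * wins[l] / good if good else np.nan)
    trace_arr = {l: np.array(v) for l, v in traces.items()}
    crossovers = _crossovers(np.array(centres), trace_arr, trace_threshold)
    return np.array(centres), trace_arr, crossovers


def _sister_leaves(tree: phylo.Node, leaf_name: str):
    """Leaf names of the smallest subtree joined to the named leaf."""
    parent = None
    stack = [tree]
    while stack:
        node = stack.pop()
        for child in node.children:
            if child.is_leaf and child.name == leaf_name:
                parent = node
            stack.append(child)
    if parent is None:
        return set()
    return {n for c in parent.children if not (c.is_leaf and c.name == leaf_name)
            for n in ([c.name] if c.is_leaf else c.leaf_names())}


def _crossovers(centres, traces, threshold):
    labels = sorted(traces)
    stack = np.vstack([traces[l] for l in labels])
    out = []
    top = np.full(stack.shape[1], -1)
    for j in range(stack.shape[1]):
        col = stack[:, j]
        if np.all(np.isnan(col)):
            continue
        i = int(np.nanargmax(col))
        if col[i] >= threshold:
            top[j] = i
    prev = None
    prev_j = None
    for j, t in enumerate(top):
        if t < 0:
            continue
        if prev is not None and t != prev:
            out.append((int((centres[prev_j] + centres[j]) // 2),
                        labels[prev], labels[t]))
        prev, prev_j = t, j
    return out


# ---------------------------------------------------------------------------
# triplet scan


def triplet_scan(alignment: dict, window_bp: int = WINDOW_BP,
                 n_perm: int = N_PERM, seed: int = 0,
                 min_segment: int = MIN_SEGMENT, alpha: float = ALPHA,
                 min_var: int = MIN_VAR_SITES):
    """Scan all (recombinant, parent-pair) triplets of consensuses.

    For each candidate recombinant and unordered pair of putative parents,
    the Chimaera-like flank chi-square is maximised over split points of the
    informative-site vector; an event is emitted when the permutation p and
    the analytic p (Bonferroni over positions and over triplets) are both
    below ``alpha``, the flanks are dominated by different parents, and both
    transferred segments are at least ``min_segment`` bp.  Overlapping events
    for one recipient are de-duplicated keeping the lowest p.
    """
    labels = sorted(alignment)
    if len(labels) < 3:
        raise ValueError("triplet scan needs at least 3 sequences")
    L = len(next(iter(alignment.values())))
    combos = [(c, a, b)
              for c in labels
              for i, a in enumerate(labels)
              for b in labels[i + 1:]
              if c != a and c != b]
    n_tests = len(combos)
    events: list[RecombinationEvent] = []
    rng = np.random.default_rng(seed)
    for c, a, b in combos:
        res = maxchi_scan({c: alignment[c], a: alignment[a], b: alignment[b]},
                          window_bp=window_bp, n_perm=n_perm,
                          seed=int(rng.integers(0, 2**31 - 1)),
                          min_var=min_var)
        if res is None:
            continue
        p_corr = min(1.0, res["p_corrected"] * n_tests)
        if res["p_perm"] > alpha or p_corr > alpha:
            continue
        k, vec = res["split_index"], res["vector"]
        f_left = vec[:k].mean()
        f_right = vec[k:].mean()
        if not ((f_left >= 0.7 and f_right <= 0.3)
                or (f_left <= 0.3 and f_right >= 0.7)):
            continue
        bp = res["interval"][0]
        if min(bp, L - bp) < min_segment:
            continue
        donor5 = a if f_left >= 0.7 else b
        events.append(RecombinationEvent(
            recipient=c, donor=donor5, interval=res["interval"],
            methods={"chimaera-like", "triplet"}, max_chi=res["chi"],
            p_perm=res["p_perm"], p_corrected=p_corr))
    return _dedupe(events)


def _dedupe(events):
    events.sort(key=lambda e: (e.p_corrected, e.p_perm, e.recipient, e.donor))
    kept: list[RecombinationEvent] = []
    for ev in events:
        dup = False
        for k in kept:
            overlap = (min(ev.interval[1], k.interval[1])
                       - max(ev.interval[0], k.interval[0]))
            near = abs(ev.breakpoint - k.breakpoint) <= 2 * WINDOW_BP
            if (overlap >= 0 or near) and (
                    ev.recipient == k.recipient
                    or {ev.recipient, ev.donor} == {k.recipient, k.donor}):
                k.methods |= ev.methods
                dup = True
                break
        if not dup:
            kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# verification and segmentation


def verify_breakpoint(alignment: dict, event: RecombinationEvent,
                      verify_support: float = VERIFY_SUPPORT,
                      n_boot: int = 100, seed: int = 0,
                      model: str = "JC",
                      bounds: tuple | None = None) -> bool:
    """Verify an event by comparing flanking trees.

    The event is verified when the recipient's supported sister group (the
    smallest clade containing it with bootstrap >= verify_support) differs
    between the two flanks.  ``bounds`` (lo, hi) restricts the flanks to an
    alignment interval — typically the region delimited by the neighbouring
    detected breakpoints, so that each flanking tree is built from
    recombination-free sequence.  Flanks shorter than 200 bp are
    unverifiable.
    """
    L = len(next(iter(alignment.values())))
    bp = event.breakpoint
    lo, hi = (0, L) if bounds is None else bounds
    lo, hi = max(0, lo), min(L, hi)
    if bp - lo < 200 or hi - bp < 200:
        event.verified = False
        event.reason = "flank shorter than 200 bp"
        return False
    labels = sorted(alignment)
    left = [alignment[l][lo:bp] for l in labels]
    right = [alignment[l][bp:hi] for l in labels]
    placements = []
    for flank_seqs, flank_seed in ((left, seed), (right, seed + 1)):
        try:
            tree = phylo.bootstrap_support(labels, flank_seqs, model=model,
                                           n_reps=n_boot, seed=flank_seed)
        except ValueError:
            event.verified = False
            event.reason = "flank tree failed"
            return False
        placements.append(_supported_sisters(tree, event.recipient,
                                             verify_support))
    ok = (placements[0] is not None and placements[1] is not None
          and placements[0] != placements[1])
    event.verified = ok
    if not ok:
        event.reason = "flanking trees agree or placement unsupported"
    return ok


def _supported_sisters(tree: phylo.Node, leaf: str, support: float):
    """Other members of the smallest clade containing ``leaf`` whose edge has
    bootstrap >= support; None when no such clade exists."""
    best = None
    for bp_set, node in tree.bipartitions().items():
        if node.support is None or node.support < support:
            continue
        if leaf in bp_set:
            if best is None or len(bp_set) < len(best):
                best = bp_set
    if best is None:
        return None
    return frozenset(best - {leaf})


def segment_alignment(length: int, events: list) -> list:
    """Recombination-free segments (1-based inclusive intervals) covering the
    alignment, split at verified breakpoints."""
    bps = sorted({e.breakpoint for e in events if e.verified})
    bounds = [0] + [b for b in bps if 0 < b < length] + [length]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def detect_events(alignment: dict, window_bp: int = WINDOW_BP,
                  n_perm: int = N_PERM, seed: int = 0,
                  min_segment: int = MIN_SEGMENT, alpha: float = ALPHA,
                  verify_support: float = VERIFY_SUPPORT,
                  n_boot: int = 100, run_bootscan: bool = False,
                  ages: dict | None = None) -> list:
    """Full scan: triplet candidates, pairwise MaxChi and optional bootscan
    corroboration, then phylogenetic verification of each event.

    When family ``ages`` are supplied, events are oriented so that the
    younger family is the recipient (a chronologically young element
    recruiting older material), before verification.
    """
    events = triplet_scan(alignment, window_bp=window_bp, n_perm=n_perm,
                          seed=seed, min_segment=min_segment, alpha=alpha)
    if ages:
        for ev in events:
            if (ev.donor in ages and ev.recipient in ages
                    and ages[ev.donor] < ages[ev.recipient]):
                ev.recipient, ev.donor = ev.donor, ev.recipient
    rng = np.random.default_rng(seed + 1)
    n_pairs = max(1, len(alignment) * (len(alignment) - 1) // 2)
    for ev in events:
        if ev.donor != "unknown":
            res = maxchi_scan({ev.recipient: alignment[ev.recipient],
                               ev.donor: alignment[ev.donor]},
                              window_bp=window_bp, n_perm=max(200, n_perm // 5),
                              seed=int(rng.integers(0, 2**31 - 1)))
            if (res is not None and res["p_perm"] <= alpha
                    and min(1.0, res["p_corrected"] * n_pairs) <= alpha
                    and abs((res["interval"][0] + res["interval"][1]) // 2
                            - ev.breakpoint) <= 4 * window_bp):
                ev.methods.add("maxchi")
        if run_bootscan:
            refs = {l: s for l, s in alignment.items() if l != ev.recipient}
            _, _, crossings = bootscan(alignment[ev.recipient], refs,
                                       step_bp=5 * STEP_BP,
                                       n_boot=max(20, n_boot // 5),
                                       seed=int(rng.integers(0, 2**31 - 1)))
            if any(abs(x[0] - ev.breakpoint) <= 500 for x in crossings):
                ev.methods.add("bootscan")
        def _verify(event):
            # full flanks: restricting to the segments delimited by
            # neighbouring breakpoints sounds cleaner but leaves too few
            # informative sites for supported placements in dense
            # multi-event histories; the placement criterion only inspects
            # the recipient, which tolerates heterogeneity elsewhere
            return verify_breakpoint(alignment, event,
                                     verify_support=verify_support,
                                     n_boot=n_boot,
                                     seed=int(rng.integers(0, 2**31 - 1)))

        _verify(ev)
        if not ev.verified and ev.donor != "unknown":
            # the scan cannot orient recombinant vs parent; if the putative
            # donor is the taxon whose placement changes between flanks, the
            # orientation was swapped
            trial = RecombinationEvent(recipient=ev.donor, donor=ev.recipient,
                                       interval=ev.interval,
                                       methods=set(ev.methods),
                                       max_chi=ev.max_chi, p_perm=ev.p_perm,
                                       p_corrected=ev.p_corrected)
            if _verify(trial):
                ev.recipient, ev.donor = trial.recipient, trial.donor
                ev.verified = True
                ev.reason = ""
    return events
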