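"""Counting-based estimation of selective pressure on the L1 ORFs.

Mean dN/dS per region is estimated with Nei-Gojobori-style counting over all
pairs of family consensuses: synonymous and nonsynonymous sites from the
mutational opportunity of each codon (stop-codon mutations excluded from the
opportunity, so S + N = 3 x codons), differences by equal-weight averaging
over shortest substitution pathways that avoid stops, Jukes-Cantor correction
of the proportions, and a jackknife-over-codons standard error.  Per-site
selection classes come from a binomial test of each codon's nonsynonymous
fraction against its neutral expectation, with Benjamini-Hochberg control.

This counting approach reproduces the qualitative selection pattern of
likelihood methods (strong purifying pressure on ORF2 and the ORF1 termini,
weaker constraint in the coiled coil) without an external phylogenetics
stack; it is not expected to match likelihood dN/dS values exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionReport",
    "codon_opportunity",
    "pairwise_codon_counts",
    "count_dnds",
    "site_selection_test",
    "regional_selection_summary",
    "neutral_codon_pair",
]

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
ALPHA = 0.05
MIN_CODONS = 30

_CODON_AA: dict = {}
_OPP_CACHE: dict = {}


def _codon_aa(codon: str):
    if not _CODON_AA:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        _CODON_AA.update(fwd)
        for stop in STOPS:
            _CODON_AA[stop] = "*"
    return _CODON_AA.get(codon)


def codon_opportunity(codon: str):
    """(synonymous sites, nonsynonymous sites) of a codon.

    Each position contributes the fraction of its non-stop single-base
    mutations that are synonymous; the two fractions sum to 1 per position,
    so S + N = 3 for every countable codon.
    """
    if codon in _OPP_CACHE:
        return _OPP_CACHE[codon]
    aa = _codon_aa(codon)
    if aa is None or aa == "*":
        _OPP_CACHE[codon] = (0.0, 0.0)
        return _OPP_CACHE[codon]
    s = 0.0
    for i in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut in STOPS:
                continue
            valid += 1
            if _codon_aa(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    _OPP_CACHE[codon] = (s, 3.0 - s)
    return _OPP_CACHE[codon]


def _pathway_counts(c1: str, c2: str):
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over substitution pathways that avoid stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in STOPS:
                ok = False
                break
            steps.append((_codon_aa(cur) == _codon_aa(nxt)))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        # all pathways pass through a stop: count ignoring the constraint
        for order in itertools.permutations(diff):
            cur = c1
            steps = []
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1:]
                steps.append((_codon_aa(cur) or "*") == (_codon_aa(nxt) or "*"))
                cur = nxt
            paths.append(steps)
    syn = np.mean([sum(p) for p in paths])
    total = len(diff)
    return float(syn), float(total - syn)


def _codons(seq: str):
    return [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def pairwise_codon_counts(seq1: str, seq2: str):
    """Per-codon-site counts for one sequence pair.

    Returns arrays (S, N, Sd, Nd) of length n_codons; codon sites containing
    stops, gaps or ambiguity in either sequence are zero (excluded
    pairwise)."""
    c1, c2 = _codons(seq1), _codons(seq2)
    n = min(len(c1), len(c2))
    S = np.zeros(n)
    N = np.zeros(n)
    Sd = np.zeros(n)
    Nd = np.zeros(n)
    for k in range(n):
        a, b = c1[k], c2[k]
        if (set(a) | set(b)) - set(BASES) or a in STOPS or b in STOPS:
            continue
        sa, na = codon_opportunity(a)
        sb, nb = codon_opportunity(b)
        S[k] = 0.5 * (sa + sb)
        N[k] = 0.5 * (na + nb)
        sd, nd = _pathway_counts(a, b)
        Sd[k] = sd
        Nd[k] = nd
    return S, N, Sd, Nd


def _jc(p: float):
    arg = 1.0 - 4.0 * p / 3.0
    return math.nan if arg <= 0 else -0.75 * math.log(arg)


@dataclass
class DnDsResult:
    dnds: float | None       # None when undefined (no synonymous signal)
    dn: float
    ds: float
    se: float | None
    n_codons: int
    undefined: bool = False
    site_S: np.ndarray | None = None
    site_N: np.ndarray | None = None
    site_Sd: np.ndarray | None = None
    site_Nd: np.ndarray | None = None


def count_dnds(seqs: list, max_pairs: int | None = None,
               seed: int = 0) -> DnDsResult:
    """Mean pairwise dN/dS of codon-aligned sequences.

    All ordered-independent pairs are counted (optionally subsampled to
    ``max_pairs`` for large inputs); the ratio is formed from pooled counts
    and the SE is a delete-one-codon jackknife.  A dataset with no synonymous
    differences (or no differences at all) yields an undefined-flagged
    result rather than an infinite ratio.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = min(len(s) for s in seqs)
    n_cod = L // 3
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pairs = [pairs[i] for i in
                 rng.choice(len(pairs), size=max_pairs, replace=False)]
    S = np.zeros(n_cod)
    N = np.zeros(n_cod)
    Sd = np.zeros(n_cod)
    Nd = np.zeros(n_cod)
    for i, j in pairs:
        s, n, sd, nd = pairwise_codon_counts(seqs[i][:3 * n_cod],
                                             seqs[j][:3 * n_cod])
        S += s
        N += n
        Sd += sd
        Nd += nd

    def ratio(mask):
        s_tot, n_tot = S[mask].sum(), N[mask].sum()
        sd_tot, nd_tot = Sd[mask].sum(), Nd[mask].sum()
        if s_tot == 0 or n_tot == 0:
            return None
        ps, pn = sd_tot / s_tot, nd_tot / n_tot
        ds, dn = _jc(ps), _jc(pn)
        if not (ds and ds > 0) or math.isnan(ds) or math.isnan(dn):
            return None
        return dn / ds, dn, ds

    full = ratio(np.ones(n_cod, dtype=bool))
    if full is None:
        return DnDsResult(None, 0.0, 0.0, None, n_cod, undefined=True,
                          site_S=S, site_N=N, site_Sd=Sd, site_Nd=Nd)
    w, dn, ds = full
    # jackknife over codons
    est = []
    mask = np.ones(n_cod, dtype=bool)
    for k in range(n_cod):
        mask[k] = False
        r = ratio(mask)
        mask[k] = True
        if r is not None:
            est.append(r[0])
    se = None
    if len(est) > 1:
        est = np.array(est)
        m = len(est)
        se = float(np.sqrt((m - 1) / m * np.sum((est - est.mean()) ** 2)))
    return DnDsResult(w, dn, ds, se, n_cod,
                      site_S=S, site_N=N, site_Sd=Sd, site_Nd=Nd)


def site_selection_test(result: DnDsResult, alpha: float = ALPHA):
    """Per-codon selection classes from the pooled site counts.

    For each codon the observed nonsynonymous fraction of differences is
    tested against the neutral expectation from its mutational opportunity
    (two-sided binomial); Benjamini-Hochberg control at ``alpha`` assigns
    'positive' / 'negative' / 'neutral'.
    """
    from scipy.stats import binomtest, false_discovery_control

    n_cod = result.n_codons
    classes = np.array(["neutral"] * n_cod, dtype=object)
    pvals = np.ones(n_cod)
    idx = []
    for k in range(n_cod):
        nd, sd = result.site_Nd[k], result.site_Sd[k]
        tot = nd + sd
        opp = result.site_S[k] + result.site_N[k]
        if tot == 0 or opp == 0:
            continue
        p0 = result.site_N[k] / opp
        t = binomtest(int(round(nd)), int(round(tot)), p0)
        pvals[k] = t.pvalue
        idx.append(k)
    if idx:
        adj = false_discovery_control(pvals[idx], method="bh")
        for k, p in zip(idx, adj):
            if p <= alpha:
                nd, sd = result.site_Nd[k], result.site_Sd[k]
                p0 = result.site_N[k] / (result.site_S[k] + result.site_N[k])
                obs = nd / (nd + sd)
                classes[k] = "positive" if obs > p0 else "negative"
    return classes, pvals


@dataclass
class SelectionReport:
    region: str
    segment: tuple               # 1-based inclusive interval on alignment
    dnds: float | None
    se: float | None
    n_codons: int
    positive_sites: list = field(default_factory=list)
    negative_sites: list = field(default_factory=list)
    undefined: bool = False
    method: str = "ng-counting"


def regional_selection_summary(alignment: dict, regions: dict,
                               segments: list | None = None,
                               alpha: float = ALPHA,
                               min_codons: int = MIN_CODONS,
                               max_pairs: int | None = None) -> list:
    """One report per region x recombination-free-segment intersection.

    ``alignment`` maps label -> nucleotide sequence (equal length, in frame
    from the start of the coding region); ``regions`` maps region label ->
    (start, end) 0-based half-open, in frame; ``segments`` are 1-based
    inclusive intervals from the recombination module (whole alignment when
    None).  Intersections shorter than ``min_codons`` codons are skipped.
    """
    L = len(next(iter(alignment.values())))
    if segments is None:
        segments = [(1, L)]
    labels = sorted(alignment)
    out = []
    for reg_label, (r_lo, r_hi) in regions.items():
        for seg in segments:
            lo = max(r_lo, seg[0] - 1)
            hi = min(r_hi, seg[1])
            # snap to the region's codon frame
            lo = r_lo + ((lo - r_lo + 2) // 3) * 3
            hi = lo + ((hi - lo) // 3) * 3
            if (hi - lo) // 3 < min_codons:
                continue
            seqs = [alignment[l][lo:hi] for l in labels]
            res = count_dnds(seqs, max_pairs=max_pairs)
            rep = SelectionReport(region=reg_label, segment=(lo + 1, hi),
                                  dnds=res.dnds, se=res.se,
                                  n_codons=res.n_codons,
                                  undefined=res.undefined)
            if not res.undefined:
                classes, _ = site_selection_test(res, alpha=alpha)
                rep.positive_sites = [int(k) + 1 for k in
                                      np.nonzero(classes == "positive")[0]]
                rep.negative_sites = [int(k) + 1 for k in
                                      np.nonzero(classes == "negative")[0]]
            out.append(rep)
    return out


# ---------------------------------------------------------------------------
# neutral simulation helper (used by tests and acceptance)


def neutral_codon_pair(n_codons: int, n_subs: int, rng,
                       accept_nonsyn: float = 1.0):
    """One ancestral codon sequence and a derived copy with ``n_subs``
    random substitutions, every non-stop substitution equally likely;
    nonsynonymous changes are accepted with probability ``accept_nonsyn``
    (1.0 = strict neutrality)."""
    sense = sorted(set(_stop_free_codons()))
    anc = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))
    der = list(anc)
    done = 0
    while done < n_subs:
        pos = int(rng.integers(0, 3 * n_codons))
        old = der[pos]
        new = BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        c0 = pos - pos % 3
        codon = der[c0:c0 + 3]
        before = "".join(codon)
        codon[pos - c0] = new
        after = "".join(codon)
        if after in STOPS:
            continue
        if _codon_aa(before) != _codon_aa(after):
            if rng.random() > accept_nonsyn:
                continue
        der[pos] = new
        done += 1
    return anc, "".join(der)


def _stop_free_codons():
    return [a + b + c for a in BASES for b in BASES for c in BASES
            if a + b + c not in STOPS]
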