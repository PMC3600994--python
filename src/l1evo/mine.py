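"""Recovery of full-length L1 elements from a genome.

The procedure mirrors the classic windowing strategy for autonomous
retrotransposon mining: (1) a translated search of the genome with the
conserved reverse-transcriptase (RT) protein domain; (2) a 14,000 bp window
cut around each RT locus; (3) re-annotation of the window by translated and
nucleotide alignment to locate ORF1, the endonuclease (EN) and RT domains of
ORF2, and the 3'UTR; (4) extraction of up to 3,000 bp upstream of ORF1 as the
5' region.  An element is full length when ORF1 and ORF2 are intact (start
codon, no internal stop, minimum length) and both a 3'UTR and a 5' promoter
region are present.

The translated search is k-mer seeded (exact 5-aa matches) with ungapped
BLOSUM62 maximal-segment extension along the seed diagonal; this recovers
elements at the divergence levels relevant here (<~25 % nucleotide) without
an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .simulate import revcomp

__all__ = [
    "RtHit",
    "Window",
    "L1Insert",
    "find_rt_hits",
    "extract_candidates",
    "annotate_candidate",
    "mine_genome",
]

WINDOW_FLANK = 7000
UPSTREAM_BP = 3000
ORF1_MIN_BP = 1100
ORF2_MIN_BP = 3700
SEED_LEN = 5
MERGE_BP = 500


@dataclass
class RtHit:
    contig: str
    start: int      # nucleotide, 0-based half-open, forward-strand coords
    end: int
    strand: str
    frame: int
    score: float
    coverage: float


@dataclass
class Window:
    contig: str
    start: int
    end: int
    strand: str
    seq: str        # element-oriented (reverse-complemented for '-' hits)
    clipped: bool
    rt_hit: RtHit


@dataclass
class L1Insert:
    contig: str
    window: tuple
    strand: str
    regions: dict = field(default_factory=dict)   # name -> (start, end) on window
    orf1_intact: bool = False
    orf2_intact: bool = False
    utr3_present: bool = False
    utr5_present: bool = False
    full_length: bool = False
    upstream_5p: str = ""
    reject_reason: str = ""
    identities: dict = field(default_factory=dict)
    window_seq: str = ""

    @property
    def insert_id(self) -> str:
        return f"{self.contig}:{self.window[0]}-{self.window[1]}{self.strand}"


# ---------------------------------------------------------------------------
# translated search


_BLOSUM = None


def _blosum():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        _BLOSUM = substitution_matrices.load("BLOSUM62")
    return _BLOSUM


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def _seed_positions(query: str, target: str):
    """(target_pos, query_pos) of exact SEED_LEN-mer matches."""
    kmers: dict = {}
    for q in range(len(query) - SEED_LEN + 1):
        kmers.setdefault(query[q:q + SEED_LEN], []).append(q)
    out = []
    for kmer, qpos in kmers.items():
        start = target.find(kmer)
        while start != -1:
            for q in qpos:
                out.append((start, q))
            start = target.find(kmer, start + 1)
    out.sort()
    return out


def _extend_cluster(query: str, target: str, seeds):
    """Ungapped maximal-scoring segment on the modal seed diagonal."""
    diags: dict = {}
    for t, q in seeds:
        diags[t - q] = diags.get(t - q, 0) + 1
    diag = max(diags, key=lambda k: (diags[k], -k))
    mat = _blosum()
    alpha = set(mat.alphabet)
    # score query positions q aligned to target positions diag+q
    lo = max(0, -diag)
    hi = min(len(query), len(target) - diag)
    if hi <= lo:
        return None
    scores = np.empty(hi - lo)
    for i, q in enumerate(range(lo, hi)):
        a, b = query[q], target[diag + q]
        scores[i] = mat[a, b] if (a in alpha and b in alpha) else -4.0
    # maximal scoring contiguous segment (Kadane)
    best, cur, s0, best_span = -1e9, 0.0, 0, (0, 0)
    for i, v in enumerate(scores):
        if cur <= 0:
            cur, s0 = v, i
        else:
            cur += v
        if cur > best:
            best, best_span = cur, (s0, i + 1)
    q_start, q_end = lo + best_span[0], lo + best_span[1]
    return best, q_start, q_end, diag


def find_rt_hits(genome: dict, rt_query: str, min_score: float = 100.0,
                 min_coverage: float = 0.5, max_ambiguous: float = 0.2) -> list:
    """Six-frame translated search for the RT domain.

    Windows with more than ``max_ambiguous`` non-ACGT bases are skipped with a
    warning.  Overlapping hits on the same strand are merged; hits are sorted
    by contig then start.
    """
    import warnings

    if not genome:
        raise ValueError("empty genome")
    hits: list[RtHit] = []
    for contig, seq in genome.items():
        n = len(seq)
        acgt = sum(seq.count(b) for b in "ACGT")
        if n and (n - acgt) / n > max_ambiguous:
            warnings.warn(f"contig {contig}: skipped (ambiguous bases)")
            continue
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for frame in range(3):
                trans = _translate(s[frame:])
                seeds = _seed_positions(rt_query, trans)
                # cluster seeds along the target
                cluster: list = []
                clusters = []
                for t, q in seeds:
                    if cluster and t - cluster[-1][0] > 300:
                        clusters.append(cluster)
                        cluster = []
                    cluster.append((t, q))
                if cluster:
                    clusters.append(cluster)
                for cl in clusters:
                    ext = _extend_cluster(rt_query, trans, cl)
                    if ext is None:
                        continue
                    score, q_start, q_end, diag = ext
                    coverage = (q_end - q_start) / len(rt_query)
                    if score < min_score or coverage < min_coverage:
                        continue
                    aa_start, aa_end = diag + q_start, diag + q_end
                    nt_start = 3 * aa_start + frame
                    nt_end = 3 * aa_end + frame
                    if strand == "-":
                        nt_start, nt_end = n - nt_end, n - nt_start
                    hits.append(RtHit(contig, nt_start, nt_end, strand,
                                      frame, float(score), coverage))
    return _merge_hits(hits)


def _merge_hits(hits: list) -> list:
    hits.sort(key=lambda h: (h.contig, h.strand, h.start))
    merged: list[RtHit] = []
    for h in hits:
        if (merged and merged[-1].contig == h.contig
                and merged[-1].strand == h.strand
                and h.start - merged[-1].end <= MERGE_BP):
            last = merged[-1]
            last.end = max(last.end, h.end)
            last.score = max(last.score, h.score)
            last.coverage = max(last.coverage, h.coverage)
        else:
            merged.append(h)
    merged.sort(key=lambda h: (h.contig, h.start))
    return merged


# ---------------------------------------------------------------------------
# windowing


def extract_candidates(genome: dict, hits: list,
                       flank: int = WINDOW_FLANK) -> list:
    """One element-oriented window of 2*flank bp per merged RT hit, centred on
    the RT span midpoint and clipped (flagged) at contig boundaries."""
    windows = []
    for h in hits:
        n = len(genome[h.contig])
        center = (h.start + h.end) // 2
        lo, hi = center - flank, center + flank
        clipped = lo < 0 or hi > n
        lo, hi = max(0, lo), min(n, hi)
        seq = genome[h.contig][lo:hi]
        if h.strand == "-":
            seq = revcomp(seq)
        windows.append(Window(h.contig, lo, hi, h.strand, seq, clipped, h))
    return windows


# ---------------------------------------------------------------------------
# annotation


def _locate(query: str, target: str, mode: str = "HW"):
    """Best edlib location of query in target: (start, end, identity)."""
    res = edlib.align(query, target, mode=mode, task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1, 1.0 - res["editDistance"] / len(query)


def _find_orf_span(seq: str, dom_start: int, dom_end: int,
                   max_up: int, max_down: int):
    """Expand an in-frame located domain to the enclosing ORF.

    Returns (orf_start, orf_end_including_stop, has_start, has_internal_stop).
    """
    stops = {"TAA", "TAG", "TGA"}
    # walk upstream codon by codon to the nearest ATG not past a stop
    best_start = None
    pos = dom_start
    while pos >= 0 and dom_start - pos <= max_up:
        codon = seq[pos:pos + 3]
        if codon == "ATG":
            best_start = pos
            break
        if codon in stops:
            break
        pos -= 3
    has_start = best_start is not None
    orf_start = best_start if has_start else dom_start
    # walk downstream to the first stop
    pos = dom_end
    end = None
    steps = 0
    while pos + 3 <= len(seq) and steps * 3 <= max_down:
        codon = seq[pos:pos + 3]
        if codon in stops:
            end = pos + 3
            break
        pos += 3
        steps += 1
    has_end = end is not None
    orf_end = end if has_end else dom_end
    internal_stop = any(seq[i:i + 3] in stops
                        for i in range(orf_start, orf_end - 3, 3))
    return orf_start, orf_end, has_start, internal_stop


def annotate_candidate(window: Window, references: dict,
                       min_identity: float = 0.6,
                       promoter_min_identity: float = 0.7) -> L1Insert:
    """Second-pass annotation of a candidate window.

    ``references`` must provide protein sequences ``orf1``, ``en``, ``rt`` and
    the nucleotide ``utr3``; it may provide ``promoters`` (label -> sequence),
    in which case the full-length call additionally requires a promoter match
    ending at ORF1.  A candidate with neither ORF1 nor a 3'UTR locatable is
    rejected (``reject_reason`` set).
    """
    seq = window.seq
    ins = L1Insert(contig=window.contig, window=(window.start, window.end),
                   strand=window.strand)

    def best_protein(query, nt_lo=0, nt_hi=None):
        """Best translated match of query within seq[nt_lo:nt_hi]; coordinates
        are reported on the whole window."""
        nt_hi = len(seq) if nt_hi is None else nt_hi
        sub = seq[max(0, nt_lo):nt_hi]
        best = None
        for f in range(3):
            trans = _translate(sub[f:])
            loc = _locate(query, trans)
            if loc and (best is None or loc[2] > best[2]):
                a = max(0, nt_lo) + 3 * loc[0] + f
                b = max(0, nt_lo) + 3 * loc[1] + f
                best = (a, b, loc[2])
        return best

    # anchor: RT domain near the window centre, then EN upstream of it
    mid = len(seq) // 2
    rt = best_protein(references["rt"], mid - 2500, mid + 2500)
    if rt is None or rt[2] < min_identity:
        rt = best_protein(references["rt"])
    en = None
    if rt and rt[2] >= min_identity:
        en = best_protein(references["en"], rt[0] - 3500, rt[0])
        ins.regions["rt"] = (rt[0], rt[1])
        ins.identities["rt"] = rt[2]
    if en and en[2] >= min_identity:
        ins.regions["en"] = (en[0], en[1])
        ins.identities["en"] = en[2]
    else:
        en = None

    # ORF2 span by expanding the anchored domains in frame
    orf2_start = None
    if rt and rt[2] >= min_identity:
        dom_lo = en[0] if en else rt[0]
        dom_hi = rt[1]
        start, end, has_start, internal_stop = _find_orf_span(
            seq, dom_lo, dom_hi, max_up=1200, max_down=4000)
        ins.regions["orf2"] = (start, end)
        orf2_start, orf2_end = start, end
        ins.orf2_intact = (has_start and not internal_stop
                           and end - start >= ORF2_MIN_BP)

        # 3'UTR immediately downstream of ORF2
        tail = seq[orf2_end:orf2_end + len(references["utr3"]) + 300]
        utr = _locate(references["utr3"], tail)
        if utr and utr[2] >= min_identity and utr[0] <= 150:
            ins.regions["3utr"] = (orf2_end + utr[0], orf2_end + utr[1])
            ins.identities["3utr"] = utr[2]
            ins.utr3_present = True
    else:
        # no anchor: fall back to a global 3'UTR search
        utr = _locate(references["utr3"], seq)
        if utr and utr[2] >= min_identity:
            ins.regions["3utr"] = (utr[0], utr[1])
            ins.identities["3utr"] = utr[2]
            ins.utr3_present = True

    # ORF1 immediately upstream of ORF2 (inter-ORF spacer allowance 300 bp)
    orf1_hi = orf2_start if orf2_start is not None else len(seq)
    o1 = best_protein(references["orf1"],
                      orf1_hi - 2 * ORF1_MIN_BP - 300, orf1_hi)
    if o1 and o1[2] >= min_identity:
        nt_a, nt_b = o1[0], o1[1]
        start, end, has_start, internal_stop = _find_orf_span(
            seq, nt_a, nt_b, max_up=60, max_down=60)
        ins.regions["orf1"] = (start, end)
        ins.identities["orf1"] = o1[2]
        ins.orf1_intact = (has_start and not internal_stop
                           and end - start >= ORF1_MIN_BP
                           and (orf2_start is None
                                or 0 <= orf2_start - end <= 300))

    if "orf1" not in ins.regions and not ins.utr3_present:
        ins.reject_reason = "no ORF1 and no 3'UTR locatable"
        return ins

    # 5' region: up to 3,000 bp upstream of ORF1
    if "orf1" in ins.regions:
        o1s = ins.regions["orf1"][0]
        up_lo = max(0, o1s - UPSTREAM_BP)
        ins.upstream_5p = seq[up_lo:o1s]
        ins.regions["5p_region"] = (up_lo, o1s)
        promoters = references.get("promoters")
        if promoters:
            best = 0.0
            for label, prom in promoters.items():
                tail = ins.upstream_5p[-(len(prom) + 100):]
                loc = _locate(prom, tail)
                if loc and len(tail) - loc[1] <= 50:
                    # guard against 5'-truncated promoters whose missing
                    # prefix aligns cheaply to genomic background: the
                    # promoter's own 5' end must match where the alignment
                    # starts
                    head = _locate(prom[:100],
                                   tail[max(0, loc[0] - 20):loc[0] + 140])
                    if head and head[2] >= 0.65:
                        best = max(best, loc[2])
            ins.identities["promoter"] = best
            ins.utr5_present = best >= promoter_min_identity
            if ins.utr5_present:
                prom_len = len(next(iter(promoters.values())))
                ins.regions["5utr"] = (max(0, o1s - prom_len), o1s)
        else:
            # without promoter references, require only upstream sequence
            ins.utr5_present = len(ins.upstream_5p) >= 200
    elif ins.utr3_present:
        ins.reject_reason = "5' truncated"

    ins.full_length = (ins.orf1_intact and ins.orf2_intact
                       and ins.utr3_present and ins.utr5_present)
    if not ins.full_length and not ins.reject_reason:
        if "orf1" not in ins.regions or not ins.orf1_intact:
            ins.reject_reason = "5' truncated" if "orf1" not in ins.regions \
                else "ORF1 not intact"
        elif not ins.orf2_intact:
            ins.reject_reason = "ORF2 not intact"
        elif not ins.utr3_present:
            ins.reject_reason = "no 3'UTR"
        elif not ins.utr5_present:
            ins.reject_reason = "no 5'UTR"
    return ins


def mine_genome(genome: dict, references: dict, min_score: float = 100.0,
                min_coverage: float = 0.5) -> list:
    """find_rt_hits -> extract_candidates -> annotate_candidate."""
    hits = find_rt_hits(genome, references["rt"], min_score, min_coverage)
    windows = extract_candidates(genome, hits)
    inserts = []
    for w in windows:
        ins = annotate_candidate(w, references)
        ins.window_seq = w.seq
        inserts.append(ins)
    return inserts


def insert_region_seq(insert: L1Insert, window_seq: str, region: str) -> str:
    a, b = insert.regions[region]
    return window_seq[a:b]
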