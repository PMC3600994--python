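"""Family classification of full-length L1 elements.

Elements are first sorted by the promoter type of their 5' region against a
library of known promoters; regions matching nothing are clustered with each
other to found novel promoter types.  Within each promoter group, families
are defined on a neighbor-joining tree of the 3' terminus: well-supported
clades are provisional families, each validated by the star-phylogeny test
(copies of one family radiate independently from a homogeneous progenitor
pool, so their tree should be devoid of internal structure).  Per-family
consensus sequences approximate the progenitors, and families are named by
promoter type plus a Roman numeral increasing with age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phylo

__all__ = [
    "UtrAssignment",
    "NovelType",
    "Family",
    "assign_utr_type",
    "cluster_novel_utrs",
    "define_families",
    "star_statistic",
    "build_consensus",
    "name_families",
    "roman",
]

MIN_IDENTITY = 80.0      # percent, UTR assignment
MIN_ALIGNED = 200        # bp, UTR assignment
NOVEL_IDENTITY = 85.0    # percent, novel-type clustering
NOVEL_MIN_SIZE = 10
SPLIT_SUPPORT = 70.0     # bootstrap % defining provisional families
STAR_THRESHOLD = 0.10
STAR_SUPPORT = 70.0
MIN_CLADE = 4              # smallest leaf set a supported edge must subtend to split
LOW_COPY = 10            # families below this are flagged non-consensus


@dataclass
class UtrAssignment:
    insert_id: str
    utr_type: str            # library label, "novel-k" or "unassigned"
    identity: float          # percent
    aligned_length: int
    monomer_count: int = 1
    reason: str = ""


@dataclass
class NovelType:
    label: str
    consensus: str
    members: list


@dataclass
class Family:
    name: str                # final name, assigned by name_families
    members: list            # insert ids
    promoter: str
    consensus: str = ""
    star_stat: float = 0.0
    validated: bool = False
    low_copy: bool = False
    age: float | None = None


# ---------------------------------------------------------------------------
# promoter typing


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner()
        a.mode = "local"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -4
        a.extend_gap_score = -1
        _ALIGNER = a
    return _ALIGNER


def _local_identity(query: str, target: str):
    """(percent identity, aligned residue pairs) of the best local alignment."""
    aln = _aligner().align(target, query)
    if len(aln) == 0:
        return 0.0, 0
    best = aln[0]
    counts = best.counts()
    pairs = counts.identities + counts.mismatches
    if pairs == 0:
        return 0.0, 0
    return 100.0 * counts.identities / pairs, pairs


def tandem_monomer_count(region: str, max_period: int = 300,
                         min_period: int = 30,
                         min_identity: float = 0.7) -> int:
    """Number of tandem repeats of the leading monomer unit detected by
    shifted self-comparison; 1 when no tandem structure is found."""
    n = len(region)
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    best_period = None
    for p in range(min_period, min(max_period, n // 2) + 1):
        w = min(p, n - p)
        ident = np.mean(arr[p:p + w] == arr[:w])
        if ident >= 0.8:
            best_period = p
            break
    if best_period is None:
        return 1
    p = best_period
    count = 1
    while (count + 1) * p <= n:
        w = p
        ident = np.mean(arr[count * p:count * p + w] == arr[:w])
        if ident < min_identity:
            break
        count += 1
    return count


def assign_utr_type(five_prime_region: str, library: dict,
                    min_identity: float = MIN_IDENTITY,
                    min_len: int = MIN_ALIGNED,
                    insert_id: str = "") -> UtrAssignment:
    """Best local-alignment assignment of a 5' region to a promoter library."""
    if not library:
        raise ValueError("empty promoter library")
    if not five_prime_region:
        return UtrAssignment(insert_id, "unassigned", 0.0, 0,
                             reason="empty 5' region")
    import edlib

    # cheap edlib prescreen ranks library entries; the best is refined with a
    # proper local alignment for identity over aligned length
    ranked = []
    for label in sorted(library):
        r = edlib.align(library[label], five_prime_region, mode="HW")
        ranked.append((r["editDistance"] / max(1, len(library[label])), label))
    ranked.sort()
    best = ("unassigned", 0.0, 0)
    for _, label in ranked[:2]:
        target = five_prime_region[-(2 * len(library[label])):]
        ident, pairs = _local_identity(library[label], target)
        if pairs >= min_len and ident > best[1]:
            best = (label, ident, pairs)
    label, ident, pairs = best
    if ident < min_identity:
        return UtrAssignment(insert_id, "unassigned", ident, pairs,
                             reason="below identity threshold")
    mono = tandem_monomer_count(five_prime_region[-pairs:] if pairs else
                                five_prime_region)
    return UtrAssignment(insert_id, label, ident, pairs, monomer_count=mono)


def cluster_novel_utrs(regions: dict, identity_threshold: float = NOVEL_IDENTITY,
                       min_cluster_size: int = NOVEL_MIN_SIZE) -> list:
    """Single-linkage clustering of unassigned 5' regions into novel promoter
    types; clusters of at least ``min_cluster_size`` become library entries."""
    import edlib
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    ids = sorted(regions)
    if not ids:
        return []
    # compare the ORF1-proximal ends at a common length
    L = min(len(regions[i]) for i in ids)
    seqs = {i: regions[i][-L:] for i in ids}
    n = len(ids)
    if n == 1:
        return []
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            r = edlib.align(seqs[ids[a]], seqs[ids[b]], mode="NW")
            d = r["editDistance"] / L
            dist[a, b] = dist[b, a] = d
    link = linkage(squareform(dist), method="single")
    labels = fcluster(link, t=1.0 - identity_threshold / 100.0,
                      criterion="distance")
    out = []
    by_cluster: dict = {}
    for i, c in zip(ids, labels):
        by_cluster.setdefault(c, []).append(i)
    k = 0
    for c in sorted(by_cluster, key=lambda c: (-len(by_cluster[c]), c)):
        members = by_cluster[c]
        if len(members) < min_cluster_size:
            continue
        k += 1
        cons = build_consensus([seqs[m] for m in members])
        out.append(NovelType(f"novel-{k}", cons, members))
    return out


# ---------------------------------------------------------------------------
# star phylogeny


def star_statistic(tree: phylo.Node, star_threshold: float = STAR_THRESHOLD,
                   star_support: float = STAR_SUPPORT,
                   min_clade: int = MIN_CLADE):
    """(internal branch length share, pass flag) of a subtree.

    A family of copies radiating independently from one progenitor should
    place nearly all branch length on terminal edges and show no supported
    internal edge.  Supported edges subtending fewer than ``min_clade``
    leaves (chance cherries from coincident substitutions) do not fail the
    test; the length statistic still reflects them.
    """
    n_leaves = len(tree.leaves())
    internal = 0.0
    total = 0.0
    supported = False
    for node in tree.walk():
        if node is tree:
            continue
        total += node.length
        if not node.is_leaf:
            internal += node.length
            side = len(node.leaves())
            if (node.support is not None and node.support >= star_support
                    and min(side, n_leaves - side) >= min_clade):
                supported = True
    stat = internal / total if total > 0 else 0.0
    return stat, (stat <= star_threshold and not supported)


# ---------------------------------------------------------------------------
# consensus


def build_consensus(rows: list) -> str:
    """Per-column plurality consensus.  Columns with >50 % gap are dropped;
    base ties break in the fixed order A < C < G < T."""
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("rows must have equal aligned length")
    arr = np.array([list(r.upper()) for r in rows])
    out = []
    n = len(rows)
    for col in arr.T:
        gaps = np.sum(col == "-")
        if gaps * 2 > n:
            continue
        counts = {b: int(np.sum(col == b)) for b in "ACGT"}
        best = max("ACGT", key=lambda b: (counts[b], -"ACGT".index(b)))
        if counts[best] == 0:
            continue
        out.append(best)
    return "".join(out)


# ---------------------------------------------------------------------------
# family definition


def _components_by_support(tree: phylo.Node, support: float,
                           min_clade: int = MIN_CLADE):
    """Partition leaves into components obtained by cutting every internal
    edge with bootstrap >= support whose smaller side has >= min_clade
    leaves."""
    comps: list[list] = []
    n_total = len(tree.leaves())

    def walk(node, comp):
        for child in node.children:
            if child.is_leaf:
                comp.append(child.name)
            elif (child.support is not None and child.support >= support
                  and min(len(child.leaves()),
                          n_total - len(child.leaves())) >= min_clade):
                new: list = []
                comps.append(new)
                walk(child, new)
            else:
                walk(child, comp)

    root_comp: list = []
    comps.append(root_comp)
    walk(tree, root_comp)
    return [sorted(c) for c in comps if c]


def _strongest_split(tree: phylo.Node, min_clade: int = MIN_CLADE):
    """Bipartition of the internal edge with highest (support, length) whose
    smaller side has at least min_clade leaves."""
    n_total = len(tree.leaves())
    best = None
    for bp, node in tree.bipartitions().items():
        if min(len(bp), n_total - len(bp)) < min_clade:
            continue
        key = (node.support if node.support is not None else -1.0, node.length)
        if best is None or key > best[0]:
            best = (key, bp)
    return None if best is None else best[1]


def define_families(inserts: dict, promoter_of: dict, *,
                    second_region: dict | None = None,
                    split_support: float = SPLIT_SUPPORT,
                    star_threshold: float = STAR_THRESHOLD,
                    star_support: float = STAR_SUPPORT,
                    model: str = "JC", n_boot: int = 100,
                    seed: int = 0, min_len: int = 200) -> list:
    """Define families from 3'-terminus phylogeny within promoter groups.

    ``inserts`` maps insert id -> 3'-terminus sequence (equal length within a
    group); ``promoter_of`` maps insert id -> promoter type.  Optional
    ``second_region`` (id -> sequence of another L1 region) re-checks each
    family and splits those with supported internal structure there.
    """
    groups: dict = {}
    for iid in sorted(inserts):
        groups.setdefault(promoter_of[iid], []).append(iid)

    families: list[Family] = []
    for ptype in sorted(groups):
        members = groups[ptype]
        if len(members) < 3:
            families.append(Family(name="", members=members, promoter=ptype,
                                   validated=False))
            continue
        L = len(inserts[members[0]])
        if L < min_len:
            raise ValueError(f"3'-terminus alignment shorter than {min_len} bp")

        pools = [members]
        final: list[tuple] = []   # (member ids, star stat, validated)
        guard = 0
        while pools and guard < 10 * len(members):
            guard += 1
            pool = pools.pop()
            if len(pool) < 4:
                final.append((pool, 0.0, len(pool) >= 2))
                continue
            seqs = [inserts[i] for i in pool]
            tree = phylo.bootstrap_support(pool, seqs, model=model,
                                           n_reps=n_boot, seed=seed)
            comps = _components_by_support(tree, split_support)
            if len(comps) > 1:
                pools.extend(comps)
                continue
            stat, ok = star_statistic(tree, star_threshold, star_support)
            if ok:
                final.append((pool, stat, True))
                continue
            split = _strongest_split(tree)
            if split is None:
                final.append((pool, stat, False))
                continue
            inside = sorted(split)
            outside = sorted(set(pool) - split)
            if not inside or not outside:
                final.append((pool, stat, False))
                continue
            pools.extend([inside, outside])

        for pool, stat, ok in sorted(final):
            fam = Family(name="", members=pool, promoter=ptype,
                         star_stat=stat, validated=ok,
                         low_copy=len(pool) < LOW_COPY)
            families.append(fam)

    if second_region is not None:
        families = _recheck_on_region(families, second_region, split_support,
                                      model, n_boot, seed)
    for fam in families:
        if len(fam.members) >= 2:
            fam.consensus = build_consensus([inserts[i] for i in fam.members
                                             if i in inserts])
    return families


def _recheck_on_region(families, region_seqs, split_support, model,
                       n_boot, seed):
    """Split families whose members show supported structure on a second
    region of the element."""
    out = []
    for fam in families:
        usable = [m for m in fam.members if m in region_seqs]
        if len(usable) < 4 or len(usable) != len(fam.members):
            out.append(fam)
            continue
        seqs = [region_seqs[i] for i in usable]
        tree = phylo.bootstrap_support(usable, seqs, model=model,
                                       n_reps=n_boot, seed=seed)
        comps = _components_by_support(tree, split_support)
        if len(comps) <= 1:
            out.append(fam)
            continue
        for comp in comps:
            out.append(Family(name="", members=comp, promoter=fam.promoter,
                              star_stat=fam.star_stat, validated=fam.validated,
                              low_copy=len(comp) < LOW_COPY))
    return out


# ---------------------------------------------------------------------------
# naming


_ROMAN = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
          (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"),
          (4, "IV"), (1, "I")]


def roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def name_families(families: list, ages: dict) -> list:
    """Assign names <promoter>_<roman>, numeral increasing with age within
    each promoter type; age ties order by descending copy number."""
    by_type: dict = {}
    for fam in families:
        by_type.setdefault(fam.promoter, []).append(fam)
    for ptype in sorted(by_type):
        ordered = sorted(
            by_type[ptype],
            key=lambda f: (_age_of(f, ages), -len(f.members), f.members))
        for k, fam in enumerate(ordered, start=1):
            fam.age = _age_of(fam, ages)
            fam.name = f"{ptype}_{roman(k)}"
    return families


def _age_of(fam: Family, ages: dict) -> float:
    if fam.name and fam.name in ages:
        return round(float(ages[fam.name]), 2)
    key = tuple(fam.members)
    if key in ages:
        return round(float(ages[key]), 2)
    return 0.0
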