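"""Synthetic L1 amplification under a master-lineage model.

A chain of families succeeds itself toward the present: each family's
progenitor derives from its parent's by neutral Jukes-Cantor substitutions
accumulated over the inter-family time gap, occasionally swapping its internal
promoter (5'UTR), recombining with another family's progenitor
(a young 3' end recruiting an older 5' terminus), or entering the genome
laterally with extra stem divergence.  Each family then deposits genomic
copies that accumulate neutral substitutions in proportion to their insertion
age and are 5'-truncated with some probability, as real reverse transcription
mostly is.  A truth table records every copy and every historical event so
downstream stages (mining, classification, recombination detection, dating)
can be scored against known answers.

Reading frames of ORF1/ORF2 are preserved during neutral evolution by default
(substitutions that would create a premature stop are redirected to another
base); this keeps the simulator's full-length flag consistent with an
ORF-intactness definition of "full length".
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SimConfig",
    "SimError",
    "CapacityError",
    "FamilyRecord",
    "CopyRecord",
    "SimTruth",
    "build_ancestral_element",
    "simulate_family_history",
    "emit_genome",
    "simulate",
    "write_simulation",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
CODON_TABLE = {}  # filled lazily from Bio.Data

# element layout (bp); promoters are fixed-length so that element coordinates
# are shared across families
PROMOTER_LEN = 600
MONOMER_LEN = 200
ORF1_LEN = 1218          # includes the stop codon
SPACER_LEN = 43
ORF2_LEN = 3834          # includes the stop codon
UTR3_LEN = 652
LPR_OFFSET = 300         # LPR start within ORF1 (in frame)
EN_CODONS = (10, 240)    # endonuclease domain, codons of ORF2
RT_CODONS = (500, 731)   # reverse transcriptase domain, codons of ORF2

HYDROPHOBIC = "LIVMF"
POLAR = "STEKQND"


class SimError(ValueError):
    pass


class CapacityError(SimError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated L1 amplification history.

    ``family_activity_times`` run from the oldest family to the youngest (MY,
    strictly decreasing).  ``per_lineage_rate`` is the neutral substitution
    rate per site per MY along one lineage, so two copies inserted at age t
    diverge by ~2*r*t; the default 0.009093 makes divergence/age equal
    1.8186 %/MY, the constant implied by the published family table.
    """

    seed: int = 0
    genome_length: int = 3_000_000
    n_families: int = 6
    family_activity_times: tuple = (9.2, 6.4, 4.6, 2.2, 1.2, 0.25)
    per_lineage_rate: float = 0.009093
    copies_per_family: int = 25
    truncation_prob: float = 0.4
    truncation_point_distribution: str = "uniform"
    promoter_library: tuple = ("Lx", "Fanc", "Mus", "V", "F", "A", "N")
    promoter_replacement_events: tuple = ((1, "Fanc"), (2, "F"), (4, "A"))
    recombination_events: tuple = ()   # (recipient, donor, breakpoint bp)
    lateral_families: tuple = ()
    lateral_extra_divergence: float = 0.02
    background_gc: float = 0.42
    random_strand: bool = False
    preserve_orfs: bool = True
    contig_name: str = "chrSim1"

    def validate(self):
        t = tuple(self.family_activity_times)
        if len(t) != self.n_families:
            raise SimError("family_activity_times length must equal n_families")
        if any(x < 0 for x in t):
            raise SimError("activity times must be >= 0")
        if any(a <= b for a, b in zip(t, t[1:])):
            raise SimError("family_activity_times must be strictly decreasing toward the present")
        if not (0.0 <= self.truncation_prob <= 1.0):
            raise SimError("truncation_prob must be in [0,1]")
        if not (0.0 <= self.background_gc <= 1.0):
            raise SimError("background_gc must be in [0,1]")
        if self.per_lineage_rate < 0:
            raise SimError("per_lineage_rate must be >= 0")
        elem_len = element_length()
        for rec, don, bp in self.recombination_events:
            for idx in (rec, don):
                if not (0 <= idx < self.n_families):
                    raise SimError(f"recombination references undefined family {idx}")
            if not (0 < bp < elem_len):
                raise SimError(f"breakpoint {bp} outside element coordinates")
        lib = set(self.promoter_library)
        for idx, label in self.promoter_replacement_events:
            if not (0 <= idx < self.n_families):
                raise SimError(f"promoter replacement references undefined family {idx}")
            if label not in lib:
                raise SimError(f"promoter label {label!r} not in promoter_library")
        for idx in self.lateral_families:
            if not (0 <= idx < self.n_families):
                raise SimError(f"lateral family {idx} undefined")
        return self


def element_length() -> int:
    return PROMOTER_LEN + ORF1_LEN + SPACER_LEN + ORF2_LEN + UTR3_LEN


def element_regions() -> dict:
    """0-based half-open spans of each region on element coordinates."""
    p0 = 0
    o1 = PROMOTER_LEN
    sp = o1 + ORF1_LEN
    o2 = sp + SPACER_LEN
    u3 = o2 + ORF2_LEN
    end = u3 + UTR3_LEN
    return {
        "5utr": (p0, o1),
        "orf1": (o1, sp),
        "spacer": (sp, o2),
        "orf2": (o2, u3),
        "en": (o2 + 3 * EN_CODONS[0], o2 + 3 * EN_CODONS[1]),
        "rt": (o2 + 3 * RT_CODONS[0], o2 + 3 * RT_CODONS[1]),
        "3utr": (u3, end),
        "lpr": (o1 + LPR_OFFSET, o1 + LPR_OFFSET + 132),
    }


# ---------------------------------------------------------------------------
# truth records


@dataclass
class FamilyRecord:
    index: int
    label: str
    parent: int | None
    promoter: str
    activity_time: float
    progenitor: str
    lateral: bool = False
    promoter_replaced: bool = False
    recombination: list = field(default_factory=list)  # (donor_index, breakpoint)


@dataclass
class CopyRecord:
    copy_id: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    promoter: str
    age: float
    truncation_offset: int

    @property
    def is_full_length(self) -> bool:
        return self.truncation_offset == 0


@dataclass
class SimTruth:
    copies: list
    families: list
    regions: dict
    config: SimConfig

    def copy_table(self):
        import pandas as pd

        rows = [dataclasses.asdict(c) | {"is_full_length": c.is_full_length}
                for c in self.copies]
        return pd.DataFrame(rows)

    def extract(self, genome: dict, record: CopyRecord) -> str:
        seq = genome[record.contig][record.start:record.end]
        if record.strand == "-":
            seq = revcomp(seq)
        return seq


# ---------------------------------------------------------------------------
# sequence helpers


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _codon_table():
    if not CODON_TABLE:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        by_aa: dict = {}
        for codon, aa in fwd.items():
            by_aa.setdefault(aa, []).append(codon)
        for v in by_aa.values():
            v.sort()
        CODON_TABLE.update(by_aa)
    return CODON_TABLE


def random_sequence(rng, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def _random_codons(rng, n_aa: int) -> str:
    sense = sorted(c for v in _codon_table().values() for c in v)
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_aa))


def _encode_protein(rng, protein: str) -> str:
    table = _codon_table()
    out = []
    for aa in protein:
        choices = table[aa]
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _heptad_protein(rng, n_heptads: int) -> str:
    """Ideal coiled-coil heptads: hydrophobic at registers a and d."""
    out = []
    for _ in range(n_heptads):
        for pos in range(7):
            pool = HYDROPHOBIC if pos in (0, 3) else POLAR
            out.append(pool[rng.integers(0, len(pool))])
    return "".join(out)


def evolve(seq: str, d: float, rng, orfs=(), protect=frozenset(),
           preserve_orfs: bool = True) -> str:
    """Jukes-Cantor evolution for branch length ``d`` substitutions/site.

    Within ``orfs`` (list of (start, end) in-frame spans), substitutions that
    would create a premature stop codon are redirected when
    ``preserve_orfs``; positions in ``protect`` (e.g. start codons) are
    immutable.
    """
    if d <= 0:
        return seq
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    orfs = list(orfs)
    for idx in hits:
        idx = int(idx)
        if idx in protect:
            continue
        old = arr[idx]
        if old not in BASES:
            continue
        choices = [b for b in BASES if b != old]
        pick = choices[rng.integers(0, 3)]
        if preserve_orfs:
            frame = None
            for start, end in orfs:
                if start <= idx < end - 3:  # final codon (stop) free to vary
                    frame = start
                    break
            if frame is not None:
                c0 = idx - (idx - frame) % 3
                codon = arr[c0:c0 + 3]
                codon[idx - c0] = pick
                if "".join(codon) in STOPS:
                    ok = [b for b in choices
                          if _no_stop(arr, c0, idx - c0, b)]
                    if not ok:
                        continue
                    pick = ok[rng.integers(0, len(ok))]
        arr[idx] = pick
    return "".join(arr)


def _no_stop(arr, c0, off, base):
    codon = arr[c0:c0 + 3]
    codon[off] = base
    return "".join(codon) not in STOPS


# ---------------------------------------------------------------------------
# ancestral element and references


def build_ancestral_element(seed: int, promoter_library=("Lx",)):
    """Deterministically build the ancestral element and promoter sequences.

    Returns (element string with the first library promoter installed,
    promoters dict label->sequence)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    promoters = {}
    for label in promoter_library:
        monomer = random_sequence(rng, MONOMER_LEN)
        tail = random_sequence(rng, PROMOTER_LEN - 2 * MONOMER_LEN)
        promoters[label] = monomer + monomer + tail

    # ORF1: conserved 5' part, LPR (two 66 bp units of ideal heptads), 3' part
    n_aa = ORF1_LEN // 3 - 2  # minus start and stop codons
    pre_aa = (LPR_OFFSET // 3) - 1
    lpr_aa = 44  # 2 x 22 aa units
    unit_aa = _heptad_protein(rng, 3) + "E"  # 22 aa, 3 heptads + spacer residue
    post_aa = n_aa - pre_aa - lpr_aa
    body = _random_codons(rng, pre_aa)
    lpr_nt = _encode_protein(rng, unit_aa) + _encode_protein(rng, unit_aa)
    post = _random_codons(rng, post_aa)
    orf1 = "ATG" + body + lpr_nt + post + "TAA"
    assert len(orf1) == ORF1_LEN

    spacer = random_sequence(rng, SPACER_LEN)

    n2_aa = ORF2_LEN // 3 - 2
    orf2 = "ATG" + _random_codons(rng, n2_aa) + "TAG"
    assert len(orf2) == ORF2_LEN

    # 3'UTR with a 30 bp polypurine tract and background composition
    pre = random_sequence(rng, 300)
    tract = "".join("AG"[i] for i in rng.integers(0, 2, size=30))
    post3 = random_sequence(rng, UTR3_LEN - 330)
    utr3 = pre + tract + post3

    element = promoters[promoter_library[0]] + orf1 + spacer + orf2 + utr3
    assert len(element) == element_length()
    return element, promoters


def reference_set(element: str) -> dict:
    """Protein/nucleotide references for mining, derived from an element."""
    from Bio.Seq import Seq

    reg = element_regions()
    orf1 = element[slice(*reg["orf1"])]
    orf2 = element[slice(*reg["orf2"])]
    orf2_prot = str(Seq(orf2[:-3]).translate())
    return {
        "orf1": str(Seq(orf1[:-3]).translate()),
        "en": orf2_prot[EN_CODONS[0]:EN_CODONS[1]],
        "rt": orf2_prot[RT_CODONS[0]:RT_CODONS[1]],
        "utr3": element[slice(*reg["3utr"])],
    }




def _orf_anchor_positions(reg) -> frozenset:
    """Start and stop codon positions of both ORFs (kept immutable under
    preserve_orfs: progenitors and copies descend from replication-competent
    elements whose ORFs initiate and terminate properly)."""
    pos = set()
    for key in ("orf1", "orf2"):
        a, b = reg[key]
        pos.update(range(a, a + 3))
        pos.update(range(b - 3, b))
    return frozenset(pos)

# ---------------------------------------------------------------------------
# history and genome


def simulate_family_history(config: SimConfig) -> list:
    """Progenitor sequence and ancestry for each family (oldest first)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    element, promoters = build_ancestral_element(config.seed,
                                                 config.promoter_library)
    reg = element_regions()
    orfs = [reg["orf1"], reg["orf2"]]
    protect = _orf_anchor_positions(reg)
    repl = dict(config.promoter_replacement_events)
    times = list(config.family_activity_times)
    lateral = set(config.lateral_families)
    recomb_by_recipient: dict = {}
    for rec, don, bp in config.recombination_events:
        recomb_by_recipient.setdefault(rec, []).append((don, bp))

    families: list[FamilyRecord] = []
    current_promoter = config.promoter_library[0]
    for i in range(config.n_families):
        if i == 0:
            seq = element
            parent = None
            dt = 0.0
        else:
            parent = i - 1
            dt = times[i - 1] - times[i]
            seq = families[parent].progenitor
        replaced = False
        if i in repl and repl[i] != current_promoter:
            replaced = True
        if i in repl:
            current_promoter = repl[i]
        promoter = current_promoter
        if replaced or (i == 0):
            seq = promoters[promoter] + seq[PROMOTER_LEN:]
        d = config.per_lineage_rate * dt
        seq = evolve(seq, d, rng, orfs=orfs, protect=protect,
                     preserve_orfs=config.preserve_orfs)
        families.append(FamilyRecord(
            index=i, label=f"fam{i}", parent=parent, promoter=promoter,
            activity_time=times[i], progenitor=seq, lateral=i in lateral,
            promoter_replaced=replaced and i > 0))

    # lateral families branch off the chain with extra stem divergence; the
    # chain itself (their descendants) is unaffected, as a laterally acquired
    # family invades alongside the resident lineage
    for i in lateral:
        families[i].progenitor = evolve(
            families[i].progenitor, config.lateral_extra_divergence, rng,
            orfs=orfs, protect=protect, preserve_orfs=config.preserve_orfs)

    # recombination: donor 5' of the breakpoint spliced onto recipient 3'
    for rec, don, bp in config.recombination_events:
        donor = families[don].progenitor
        recip = families[rec].progenitor
        families[rec].progenitor = donor[:bp] + recip[bp:]
        families[rec].recombination.append((don, bp))
        if bp > PROMOTER_LEN:
            # the transferred 5' terminus carries the donor's promoter
            families[rec].promoter = families[don].promoter
    return families


def emit_genome(families: list, config: SimConfig):
    """Place mutated, possibly truncated copies of each family into background
    sequence.  Returns (genome dict contig->sequence, SimTruth)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 31]))
    reg = element_regions()
    orfs = [reg["orf1"], reg["orf2"]]
    protect = _orf_anchor_positions(reg)
    genome = np.frombuffer(
        random_sequence(rng, config.genome_length, config.background_gc).encode(),
        dtype=np.uint8).copy()

    elem_len = element_length()
    n_total = config.n_families * config.copies_per_family
    copies: list[CopyRecord] = []
    occupied: list[tuple] = []
    margin = 8000  # keep windows clip-free for planted copies

    def place(length):
        for _ in range(200):
            start = int(rng.integers(margin, config.genome_length - length - margin)) \
                if config.genome_length > length + 2 * margin else None
            if start is None:
                break
            if all(start + length + 100 <= s or e + 100 <= start
                   for s, e in occupied):
                occupied.append((start, start + length))
                return start
        raise CapacityError(
            f"genome of {config.genome_length} bp cannot host {n_total} copies")

    for fam in families:
        for j in range(config.copies_per_family):
            age = fam.activity_time
            seq = evolve(fam.progenitor, config.per_lineage_rate * age, rng,
                         orfs=orfs, protect=protect,
                         preserve_orfs=config.preserve_orfs)
            offset = 0
            if config.truncation_prob > 0 and rng.random() < config.truncation_prob:
                offset = int(rng.integers(1, elem_len))
                seq = seq[offset:]
            strand = "+"
            if config.random_strand and rng.random() < 0.5:
                strand = "-"
            placed = seq if strand == "+" else revcomp(seq)
            start = place(len(placed))
            genome[start:start + len(placed)] = np.frombuffer(
                placed.encode(), dtype=np.uint8)
            copies.append(CopyRecord(
                copy_id=f"{fam.label}_c{j}", contig=config.contig_name,
                start=start, end=start + len(placed), strand=strand,
                family=fam.label, promoter=fam.promoter, age=age,
                truncation_offset=offset))

    genome_s = {config.contig_name: genome.tobytes().decode()}
    truth = SimTruth(copies=copies, families=families, regions=reg,
                     config=config)
    return genome_s, truth


def simulate(config: SimConfig):
    """Full simulation: history + genome.  Returns (genome, truth)."""
    families = simulate_family_history(config)
    return emit_genome(families, config)


# ---------------------------------------------------------------------------
# output


def write_simulation(outdir, genome: dict, truth: SimTruth):
    """Write genome FASTA, truth BED6 + TSV, progenitor FASTA, ancestry newick
    and event TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "genome.fa", genome.items())
    _write_fasta(out / "progenitors.fa",
                 [(f.label, f.progenitor) for f in truth.families])
    with open(out / "copies.bed", "w") as fh:
        for c in truth.copies:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.family}\t0\t{c.strand}\n")
    truth.copy_table().to_csv(out / "copies.tsv", sep="\t", index=False)
    with open(out / "families.tsv", "w") as fh:
        fh.write("label\tparent\tpromoter\tactivity_time\tlateral\t"
                 "promoter_replaced\trecombination\n")
        for f in truth.families:
            rec = ";".join(f"{d}@{bp}" for d, bp in f.recombination)
            par = "" if f.parent is None else truth.families[f.parent].label
            fh.write(f"{f.label}\t{par}\t{f.promoter}\t{f.activity_time}\t"
                     f"{int(f.lateral)}\t{int(f.promoter_replaced)}\t{rec}\n")
    with open(out / "ancestry.nwk", "w") as fh:
        fh.write(ancestry_newick(truth.families) + "\n")


def ancestry_newick(families: list) -> str:
    """Caterpillar newick of the family chain, oldest at the base."""
    tip = families[-1]
    tree = f"{tip.label}:0"
    for fam in reversed(families[:-1]):
        dt = fam.activity_time - (families[fam.index + 1].activity_time)
        tree = f"({fam.label}:0,{tree}):{dt:g}"
    return tree + ";"


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
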