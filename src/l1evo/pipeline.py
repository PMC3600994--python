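"""End-to-end orchestration: simulate -> mine -> classify -> ages -> recomb
-> orf1 -> selection -> lateral-transfer, with TSV reports, a run manifest
and (on simulated input) a truth-comparison block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ages as ages_mod
from . import classify, mine, orf1, recomb
from . import selection as selection_mod
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "adjusted_rand_index"]

ALL_STAGES = ("simulate", "mine", "classify", "ages", "recomb", "orf1",
              "selection", "lateral", "report")


@dataclass
class PipelineConfig:
    outdir: str = "l1evo_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    n_boot: int = 100
    n_perm: int = 500
    recomb_window: int = recomb.WINDOW_BP
    min_segment: int = recomb.MIN_SEGMENT
    conversion_factor: float = ages_mod.CONVERSION_FACTOR
    age_n_boot: int = 300
    null_reps: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("family_activity_times", "promoter_library",
                    "promoter_replacement_events", "recombination_events",
                    "lateral_families", "stages"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(
                    tuple(x) if isinstance(x, list) else x
                    for x in sim_raw[key])
        if "stages" in raw and isinstance(raw["stages"], list):
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        if sim_raw:
            cfg.sim = dataclasses.replace(sim.SimConfig(seed=cfg.seed),
                                          **sim_raw)
        return cfg


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    from collections import Counter

    pairs = Counter(zip(labels_a, labels_b))
    ca, cb = Counter(labels_a), Counter(labels_b)
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = sum(comb2(v) for v in pairs.values())
    sum_a = sum(comb2(v) for v in ca.values())
    sum_b = sum(comb2(v) for v in cb.values())
    n = comb2(len(labels_a))
    if n == 0:
        return 1.0
    expected = sum_a * sum_b / n
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        return 1.0
    return (sum_ij - expected) / denom


def _element_profile(ins: mine.L1Insert):
    """Element-oriented sequence of an insert anchored on ORF1 start, from
    600 bp upstream of ORF1 over one full element length.  Anchoring on the
    located ORF1 start keeps columns homologous across inserts (the
    simulator introduces substitutions only, so coordinates are rigid)."""
    if "orf1" not in ins.regions or "3utr" not in ins.regions:
        return None
    lo = ins.regions["orf1"][0] - 600
    hi = lo + sim.element_length()
    if lo < 0 or hi > len(ins.window_seq):
        return None
    return ins.window_seq[lo:hi], 600


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns a result
    bundle and writes TSV reports plus a manifest under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    res: dict = {"outputs": []}
    manifest = {"seed": config.seed, "stages": sorted(stages),
                "parameters": {
                    "n_boot": config.n_boot, "n_perm": config.n_perm,
                    "recomb_window": config.recomb_window,
                    "conversion_factor": config.conversion_factor,
                }}

    def emit(name, write):
        path = out / name
        write(path)
        res["outputs"].append(name)

    # ---------------------------------------------------------------- simulate
    genome = truth = None
    refs = None
    if "simulate" in stages:
        cfg = dataclasses.replace(config.sim, seed=config.seed)
        genome, truth = sim.simulate(cfg)
        element, promoters = sim.build_ancestral_element(
            cfg.seed, cfg.promoter_library)
        refs = sim.reference_set(element)
        refs["promoters"] = promoters
        sim.write_simulation(out / "sim", genome, truth)
        res["genome"], res["truth"], res["refs"] = genome, truth, refs
        res["outputs"].append("sim/")
    if not stages - {"simulate"}:
        _write_manifest(out, manifest, res)
        return res

    # -------------------------------------------------------------------- mine
    inserts = []
    if "mine" in stages and genome is not None:
        inserts = mine.mine_genome(genome, refs)
        fl = [i for i in inserts if i.full_length]
        res["inserts"] = inserts
        res["full_length"] = fl
        emit("inserts.tsv", lambda p: _write_inserts(p, inserts))
        logger.info("mined %d candidates, %d full length", len(inserts),
                    len(fl))

    # ---------------------------------------------------------------- classify
    families = []
    consensus: dict = {}
    if "classify" in stages and inserts:
        fl = res["full_length"]
        assigns = {}
        for ins in fl:
            assigns[ins.insert_id] = classify.assign_utr_type(
                ins.upstream_5p, refs["promoters"], insert_id=ins.insert_id)
        unassigned = {i.insert_id: i.upstream_5p for i in fl
                      if assigns[i.insert_id].utr_type == "unassigned"}
        novel = classify.cluster_novel_utrs(unassigned) if unassigned else []
        for ntype in novel:
            for m in ntype.members:
                assigns[m] = classify.UtrAssignment(m, ntype.label, 100.0,
                                                    len(ntype.consensus))
        profiles = {}
        for ins in fl:
            prof = _element_profile(ins)
            if prof is not None:
                profiles[ins.insert_id] = prof[0]
        usable = [i for i in fl if i.insert_id in profiles]
        L = min(len(profiles[i.insert_id]) for i in usable)
        profiles = {k: v[:L] for k, v in profiles.items()}
        three = {k: v[-(500 + sim.UTR3_LEN):] for k, v in profiles.items()}
        second = {k: v[600:600 + sim.ORF1_LEN] for k, v in profiles.items()}
        p_of = {k: assigns[k].utr_type for k in profiles}
        families = classify.define_families(
            three, p_of, second_region=second, n_boot=config.n_boot,
            seed=config.seed)
        for fam in families:
            fam.consensus = classify.build_consensus(
                [profiles[m] for m in fam.members])
        res["families"] = families
        res["assignments"] = assigns
        res["profiles"] = profiles
        res["novel_types"] = novel

    # -------------------------------------------------------------------- ages
    age_of: dict = {}
    if "ages" in stages and families:
        profiles = res["profiles"]
        L = len(next(iter(profiles.values())))
        estimates = []
        for k, fam in enumerate(families):
            rows = {m: profiles[m][L - sim.UTR3_LEN:] for m in fam.members}
            if len(rows) < 2:
                estimates.append(None)
                continue
            est = ages_mod.estimate_family_age(
                rows, family=f"prov{k}",
                conversion_factor=config.conversion_factor,
                n_boot=config.age_n_boot, seed=config.seed + k)
            age_of[tuple(fam.members)] = est.age
            fam.age = est.age
            estimates.append(est)
        res["age_estimates"] = estimates
        classify.name_families(families, age_of)
        emit("families.tsv", lambda p: _write_families(p, families))

    # ------------------------------------------------------------------ recomb
    events = []
    segments = None
    cons_aln: dict = {}
    if "recomb" in stages and families:
        for fam in families:
            name = fam.name or f"prov{families.index(fam)}"
            if len(fam.members) >= 2 and fam.consensus:
                cons_aln[name] = fam.consensus[600:]
        if len(cons_aln) >= 3:
            fam_ages = {(f.name or f"prov{families.index(f)}"): (f.age or 0.0)
                        for f in families}
            events = recomb.detect_events(
                cons_aln, window_bp=config.recomb_window,
                n_perm=config.n_perm, seed=config.seed,
                min_segment=config.min_segment, n_boot=config.n_boot,
                ages=fam_ages)
            L = len(next(iter(cons_aln.values())))
            segments = recomb.segment_alignment(L, events)
            res["events"] = events
            res["segments"] = segments
            res["consensus_alignment"] = cons_aln
            emit("events.tsv", lambda p: _write_events(p, events))
            emit("segments.bed", lambda p: _write_segments(p, segments))

    # -------------------------------------------------------------------- orf1
    if "orf1" in stages and families:
        from Bio.Seq import Seq

        element, promoters = sim.build_ancestral_element(
            config.seed, config.sim.promoter_library)
        reg = sim.element_regions()
        anc_orf1 = element[slice(*reg["orf1"])]
        lpr_lo, lpr_hi = reg["lpr"]
        o1_lo = reg["orf1"][0]
        u66 = element[lpr_lo:lpr_lo + 66]
        u42_like = element[lpr_lo + 66:lpr_hi]  # ancestral second unit
        flanks = (anc_orf1[lpr_lo - o1_lo - 120:lpr_lo - o1_lo],
                  anc_orf1[lpr_hi - o1_lo:lpr_hi - o1_lo + 120])
        lpr_rows = []
        cc_rows = []
        structures = {}
        for fam in families:
            name = fam.name or f"prov{families.index(fam)}"
            orf1_nt = fam.consensus[600:600 + sim.ORF1_LEN]
            s = orf1.annotate_lpr(orf1_nt, [u66, u42_like], flanks)
            structures[name] = s.structure
            prot = str(Seq(orf1_nt[:len(orf1_nt) - len(orf1_nt) % 3])
                       .translate()).rstrip("*")
            cc = orf1.predict_coiled_coil(prot)
            lpr_rows.append((name, s.structure, s.span))
            cc_rows.append((name, cc.span, cc.heptads))
        res["lpr"] = lpr_rows
        res["coiled_coil"] = cc_rows
        res["lpr_structures"] = structures
        emit("lpr.tsv", lambda p: _write_rows(
            p, ("family", "structure", "span"), lpr_rows))
        emit("cc.tsv", lambda p: _write_rows(
            p, ("family", "span", "heptads"), cc_rows))

    # --------------------------------------------------------------- selection
    if "selection" in stages and cons_aln:
        cc_spans = {name: span for name, span, _ in res.get("coiled_coil", [])}
        spans = [s for s in cc_spans.values() if s]
        if spans:
            cc_lo = 3 * int(np.median([s[0] for s in spans]))
            cc_hi = 3 * int(np.median([s[1] for s in spans]))
        else:
            cc_lo, cc_hi = 300, 450
        o1_len = sim.ORF1_LEN - 3
        o2_lo = sim.ORF1_LEN + sim.SPACER_LEN
        o2_len = sim.ORF2_LEN - 3
        regions = {
            "ORF1 5' terminus": (0, cc_lo),
            "ORF1 coiled coil": (cc_lo, cc_hi),
            "ORF1 3' terminus": (cc_hi, o1_len),
            "ORF2 5' terminus": (o2_lo, o2_lo + 3 * 1170),
            "ORF2 3' terminus": (o2_lo + 3 * 1170, o2_lo + o2_len),
        }
        regions = {k: (lo, min(hi, len(next(iter(cons_aln.values())))))
                   for k, (lo, hi) in regions.items() if lo < hi}
        reports = selection_mod.regional_selection_summary(
            cons_aln, regions, segments=segments)
        res["selection"] = reports
        emit("selection.tsv", lambda p: _write_selection(p, reports))

    # ----------------------------------------------------------------- lateral
    if "lateral" in stages and families and truth is not None:
        profiles = res["profiles"]
        L = len(next(iter(profiles.values())))
        rows = {}
        family_of = {}
        for fam in families:
            name = fam.name or f"prov{families.index(fam)}"
            for m in fam.members:
                rows[m] = profiles[m][L - sim.UTR3_LEN:]
                family_of[m] = name
        named = [f.name or f"prov{families.index(f)}" for f in families]
        order = sorted(named, key=lambda n: next(
            (f.age or 0.0) for f in families
            if (f.name or f"prov{families.index(f)}") == n), reverse=True)
        rank_of = {n: i for i, n in enumerate(order)}
        null = ages_mod.simulate_null_stems(
            tuple(sorted((f.age or 0.01 for f in families), reverse=True)),
            config.sim.per_lineage_rate,
            max(2, int(np.median([len(f.members) for f in families]))),
            sim.UTR3_LEN, n_reps=config.null_reps, seed=config.seed)
        calls = ages_mod.detect_lateral_transfer(rows, family_of, null,
                                                 rank_of=rank_of)
        res["lateral"] = calls
        emit("lateral.tsv", lambda p: _write_rows(
            p, ("family", "stem_length", "null_q99", "flagged"),
            [(c.family, f"{c.stem_length:.5f}", f"{c.null_quantile:.5f}",
              int(c.flagged)) for c in calls]))

    # ------------------------------------------------------------------ report
    if "report" in stages and truth is not None and families:
        res["truth_comparison"] = _truth_comparison(res, truth)
        emit("truth_comparison.tsv", lambda p: _write_rows(
            p, ("metric", "value"),
            sorted(res["truth_comparison"].items())))

    _write_manifest(out, manifest, res)
    return res


# ---------------------------------------------------------------------------
# truth comparison


def _truth_of(ins: mine.L1Insert, truth):
    """Planted copy an insert corresponds to: windows are centred on the
    mined element's RT domain, so of the copies contained in the window the
    one nearest the centre is the mined one."""
    centre = (ins.window[0] + ins.window[1]) / 2
    best = None
    for c in truth.copies:
        if ins.window[0] <= c.start and c.end <= ins.window[1]:
            d = abs((c.start + c.end) / 2 - centre)
            if best is None or d < best[0]:
                best = (d, c)
    return None if best is None else best[1]


def _truth_comparison(res: dict, truth) -> dict:
    out: dict = {}
    inserts = res.get("inserts", [])
    fl_called = [i for i in inserts if i.full_length]
    fl_truth = [c for c in truth.copies if c.is_full_length]
    tp = sum(1 for i in fl_called
             if (c := _truth_of(i, truth)) is not None and c.is_full_length)
    if fl_truth:
        out["mining_recall"] = round(tp / len(fl_truth), 4)
    if fl_called:
        out["mining_precision"] = round(tp / len(fl_called), 4)
    families = res.get("families", [])
    if families:
        idx = {i.insert_id: i for i in fl_called}
        lt, lp = [], []
        for k, fam in enumerate(families):
            for m in fam.members:
                c = _truth_of(idx[m], truth) if m in idx else None
                if c is not None:
                    lt.append(c.family)
                    lp.append(k)
        if lt:
            out["family_ari"] = round(adjusted_rand_index(lt, lp), 4)
        out["n_families_detected"] = len(families)
        out["n_families_true"] = len(truth.families)
    if "age_estimates" in res:
        fam_truth = {f.label: f.activity_time for f in truth.families}
        idx = {i.insert_id: i for i in fl_called}
        covered = total = 0
        for fam, est in zip(families, res["age_estimates"]):
            members = [m for m in fam.members if m in idx]
            if not members or est is None:
                continue
            c = _truth_of(idx[members[0]], truth)
            if c is None:
                continue
            true_age = fam_truth.get(c.family)
            if true_age is None:
                continue
            total += 1
            if est.interval[0] <= true_age <= est.interval[1]:
                covered += 1
        if total:
            out["age_interval_coverage"] = round(covered / total, 4)
    if "events" in res:
        out["n_verified_events"] = sum(1 for e in res["events"] if e.verified)
        out["n_true_recomb_events"] = len(truth.config.recombination_events)
    return out


# ---------------------------------------------------------------------------
# writers


def _write_manifest(out: Path, manifest: dict, res: dict):
    manifest["outputs"] = res["outputs"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _write_rows(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_inserts(path, inserts):
    rows = [(i.insert_id, i.contig, i.window[0], i.window[1], i.strand,
             int(i.full_length), int(i.orf1_intact), int(i.orf2_intact),
             int(i.utr3_present), int(i.utr5_present), i.reject_reason)
            for i in inserts]
    _write_rows(path, ("insert_id", "contig", "window_start", "window_end",
                       "strand", "full_length", "orf1_intact", "orf2_intact",
                       "utr3_present", "utr5_present", "reject_reason"), rows)


def _write_families(path, families):
    rows = [(f.name, f.promoter, len(f.members), f"{f.star_stat:.4f}",
             int(f.validated), int(f.low_copy), f.age)
            for f in families]
    _write_rows(path, ("name", "promoter", "n_members", "star_stat",
                       "validated", "low_copy", "age_my"), rows)


def _write_events(path, events):
    rows = [(e.recipient, e.donor, e.interval[0], e.interval[1],
             ",".join(sorted(e.methods)), f"{e.max_chi:.2f}",
             f"{e.p_perm:.4g}", f"{e.p_corrected:.4g}", int(e.verified),
             e.reason) for e in events]
    _write_rows(path, ("recipient", "donor", "interval_lo", "interval_hi",
                       "methods", "max_chi", "p_perm", "p_corrected",
                       "verified", "reason"), rows)


def _write_segments(path, segments):
    with open(path, "w") as fh:
        for k, (lo, hi) in enumerate(segments, 1):
            fh.write(f"consensus_alignment\t{lo - 1}\t{hi}\tsegment_{k}\n")


def _write_selection(path, reports):
    rows = [(r.region, f"{r.segment[0]}-{r.segment[1]}",
             "NA" if r.dnds is None else f"{r.dnds:.3f}",
             "NA" if r.se is None else f"{r.se:.3f}", r.n_codons,
             len(r.positive_sites), len(r.negative_sites),
             ";".join(map(str, r.positive_sites)))
            for r in reports]
    _write_rows(path, ("region", "segment", "dnds", "se", "n_codons",
                       "n_positive", "n_negative", "positive_sites"), rows)
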