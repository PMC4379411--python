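"""End-to-end orchestration: simulate -> map introns -> call events ->
classify NMD -> infer history -> scan conservation -> report.

Each stage reads and writes plain files in the output directory, records a
hash of its parameters and inputs in ``manifest.json``, and is skipped on
rerun when nothing changed, so a repeated run with the same seed reproduces
the identical report.  Timestamps go only to the log file, never into stage
outputs, keeping reruns byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from skbio import TreeNode

from . import conservation as cons
from . import intron_homology as ih
from . import phylogeny as phy
from . import splice_events as se
from .errors import ConfigurationError, InputError
from .gene_models import read_bed12, read_fasta, read_gff
from .report import (
    ConservationReport,
    GroupHistory,
    HostIntronPercentile,
    OriginReport,
    PerfectRunReport,
    RunReport,
    StageRecord,
    SubfamilyCall,
)
from .simulate import SimulationConfig, read_truth, simulate_family, write_family

logger = logging.getLogger("splicevo")

DEFAULT_PARAMS = {
    "nmd_threshold": 50,
    "window": 0,
    "max_gap_fraction": 0.5,
    "min_overhang": 10,
    "min_fold": 2.0,
    "min_len": 200,
    "profile_window": 25,
    "bootstrap_reps": 0,
    "bootstrap_seed": 0,
    "linkage": "strict",
}

TOP_KEYS = {
    "simulate",
    "inputs",
    "params",
    "outgroup",
    "subfamily_references",
    "tree",
    "score_truth",
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, Mapping):
        raise ConfigurationError("pipeline config must be a mapping")
    unknown = set(config) - TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(config)
    params = dict(DEFAULT_PARAMS)
    extra = set(cfg.get("params", {})) - set(DEFAULT_PARAMS)
    if extra:
        raise ConfigurationError(f"unknown parameter keys: {sorted(extra)}")
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    return cfg


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Manifest:
    """Stage ledger; paths are stored relative to the run directory."""

    def __init__(self, path: Path):
        self.path = path
        self.root = path.parent
        self.data = {}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)

    def fresh(self, stage: str, h: str, outputs: list[str]) -> bool:
        rec = self.data.get(stage)
        return (
            rec is not None
            and rec["hash"] == h
            and all((self.root / p).exists() for p in rec["outputs"])
            and rec["outputs"] == outputs
        )

    def record(self, stage: str, h: str, outputs: list[str]) -> None:
        self.data[stage] = {"hash": h, "outputs": outputs}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def run_pipeline(config, out_dir, seed: int | None = None) -> RunReport:
    """Run all stages and return (and write) the machine-readable report."""
    cfg = load_config(config)
    params = cfg["params"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        return _run(cfg, params, out, seed)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, params: dict, out: Path, seed: int | None) -> RunReport:
    manifest = _Manifest(out / "manifest.json")
    stages: list[StageRecord] = []

    # ---- stage: simulate or locate inputs ---------------------------------
    if "simulate" in cfg:
        simcfg = SimulationConfig.from_dict(cfg["simulate"])
        if seed is not None:
            simcfg.seed = seed
        logger.info("simulate: seed=%d", simcfg.seed)
        h = _hash(simcfg.to_dict())
        simdir = out / "sim"
        rel_paths = {
            k: f"sim/{v}"
            for k, v in {
                "genome": "genome.fasta", "gff": "models.gff3",
                "proteins": "proteins.fasta", "msa": "msa.fasta",
                "gene_tree": "gene_tree.nwk", "ests_wt": "ests_wt.bed",
                "ests_nmd_deficient": "ests_nmd_deficient.bed",
                "abundances": "abundances.tsv", "truth": "truth",
            }.items()
        }
        paths = {k: str(out / v) for k, v in rel_paths.items()}
        outputs = sorted(p for k, p in rel_paths.items() if k != "truth")
        if manifest.fresh("simulate", h, outputs):
            logger.info("simulate: unchanged, skipped")
            stages.append(StageRecord(name="simulate", hash=h, outputs=rel_paths))
        else:
            family = simulate_family(simcfg)
            write_family(family, simdir)
            manifest.record("simulate", h, outputs)
            stages.append(StageRecord(name="simulate", hash=h, outputs=rel_paths))
        run_seed = simcfg.seed
    elif "inputs" in cfg:
        paths = dict(cfg["inputs"])
        required = {"genome", "gff", "msa"}
        missing = required - set(paths)
        if missing:
            raise ConfigurationError(f"inputs missing keys: {sorted(missing)}")
        absent = [p for k, p in paths.items() if k != "truth" and not Path(p).exists()]
        if absent:
            raise InputError(f"missing input files: {absent}")
        stages.append(StageRecord(name="inputs", hash=_hash(paths), outputs=paths))
        run_seed = seed
    else:
        raise ConfigurationError("config needs a 'simulate' or 'inputs' section")

    genome = read_fasta(paths["genome"])
    genes = read_gff(paths["gff"])
    gene_by_id = {g.gene_id: g for g in genes}
    msa = read_fasta(paths["msa"])

    truth = None
    truth_dir = paths.get("truth")
    if truth_dir and Path(truth_dir).exists():
        truth = read_truth(truth_dir)

    # ---- stage: map introns onto the alignment ---------------------------
    logger.info("map-introns: %d genes", len(genes))
    sites_by_gene = {}
    for g in genes:
        sites, n_utr = ih.intron_sites(g)
        sites_by_gene[g.gene_id] = sites
        if n_utr:
            logger.info("%s: %d UTR introns excluded from characters", g.gene_id, n_utr)
    anchored, n_dropped = ih.anchor_sites(sites_by_gene, msa)
    if n_dropped:
        logger.info("map-introns: %d sites beyond trim boundary dropped", n_dropped)
    cm = ih.build_character_matrix(
        anchored,
        window=params["window"],
        max_gap_fraction=params["max_gap_fraction"],
        msa=msa,
        gene_ids=[g.gene_id for g in genes],
    )
    # per-site merged character, for event homology grouping
    key_by_site = {}
    col_to_key = _merge_map(anchored, params["window"])
    site_rows = []
    for s in anchored:
        key = col_to_key[(s.column, s.phase)]
        key_by_site[(s.gene_id, s.intron_index)] = key
        site_rows.append(
            (s.gene_id, s.intron_index, s.column, s.phase, ih.character_label(key))
        )
    sites_df = pd.DataFrame(
        site_rows, columns=["gene_id", "intron_index", "column", "phase", "character"]
    )
    sites_path = out / "anchored_sites.tsv"
    sites_df.to_csv(sites_path, sep="\t", index=False)
    matrix_path = out / "character_matrix.tsv"
    ih.write_character_matrix(cm, matrix_path)

    # subfamily classification against reference profiles
    subfam_calls: list[SubfamilyCall] = []
    refs_cfg = cfg.get("subfamily_references") or {}
    if refs_cfg:
        references = {}
        for label, ref_gene in refs_cfg.items():
            if ref_gene not in cm.matrix.index:
                raise ConfigurationError(f"reference gene {ref_gene!r} not found")
            references[label] = cm.profile(ref_gene)
        for g in genes:
            label, score = ih.classify_subfamily(cm.profile(g.gene_id), references)
            subfam_calls.append(
                SubfamilyCall(gene_id=g.gene_id, label=label, score=round(score, 4))
            )
        pd.DataFrame([c.model_dump() for c in subfam_calls]).to_csv(
            out / "subfamilies.tsv", sep="\t", index=False
        )

    # ---- stage: call events ----------------------------------------------
    ests = []
    for key in ("ests_wt", "ests_nmd_deficient"):
        if key in paths and Path(paths[key]).exists():
            ests.extend(read_bed12(paths[key]))
    events: list[se.SpliceEvent] = []
    n_skipped = 0
    if ests:
        for g in genes:
            mine = [
                r
                for r in ests
                if r.chrom == g.locus.chrom
                and g.locus.start <= r.start
                and r.end <= g.locus.end
            ]
            ev, skipped = se.call_events(mine, g, min_overhang=params["min_overhang"])
            events.extend(ev)
            n_skipped += skipped
    logger.info("call-events: %d events, %d ESTs skipped", len(events), n_skipped)
    events_df = se.events_to_frame(events)
    events_df.to_csv(out / "events.tsv", sep="\t", index=False)

    # ---- stage: classify NMD ---------------------------------------------
    calls: list[se.NMDCall] = []
    event_verdicts: list[str] = []
    for ev in events:
        iso = se.build_isoform(gene_by_id[ev.gene_id], ev)
        call = se.classify_nmd(
            iso, genome, gene=gene_by_id[ev.gene_id], threshold_nt=params["nmd_threshold"]
        )
        calls.append(call)
        event_verdicts.append(call.verdict)
    nmd_df = pd.concat(
        [events_df, se.nmd_calls_to_frame(calls)], axis=1
    ) if events else pd.DataFrame()
    nmd_df.to_csv(out / "nmd_calls.tsv", sep="\t", index=False)

    n_stabilized = None
    if "abundances" in paths and Path(paths["abundances"]).exists():
        ab = pd.read_csv(paths["abundances"], sep="\t")
        stab = se.stabilization_report(ab, min_fold=params["min_fold"])
        pd.DataFrame([vars(s) for s in stab]).to_csv(
            out / "stabilization.tsv", sep="\t", index=False
        )
        n_stabilized = sum(s.stabilized for s in stab)

    # ---- stage: tree support (optional bootstrap) ------------------------
    if params["bootstrap_reps"] > 0:
        support = phy.bootstrap_support(
            msa, n_reps=params["bootstrap_reps"], seed=params["bootstrap_seed"]
        )
        rows = [
            (",".join(sorted(split)), frac)
            for split, frac in sorted(support.items(), key=lambda kv: sorted(kv[0]))
        ]
        pd.DataFrame(rows, columns=["split", "support"]).to_csv(
            out / "split_support.tsv", sep="\t", index=False
        )
        logger.info("bootstrap: %d splits assessed", len(rows))

    # ---- stage: infer history --------------------------------------------
    origin_report = None
    tree = _resolve_tree(cfg, paths, msa)
    if tree is not None:
        groups: dict[str, set[str]] = {}
        for ev in events:
            key = key_by_site.get((ev.gene_id, ev.host_intron))
            if key is None:
                continue  # e.g. UTR intron: not a protein-anchored character
            groups.setdefault(ih.character_label(key), set()).add(ev.gene_id)
        model = phy.infer_origin_model(tree, groups, linkage=params["linkage"])
        origin_report = OriginReport(
            verdict=model.verdict,
            n_groups=len(groups),
            linked_pairs=[
                [gi, gj, ",".join(sorted(branch))] for gi, gj, branch in model.linked_pairs
            ],
            histories=[
                GroupHistory(
                    group=name,
                    gain_branch=sorted(h.gain_branch) if h.gain_branch else None,
                    loss_branches=sorted(sorted(b) for b in h.loss_branches),
                    cost=h.cost,
                    fitch_cost=h.fitch_cost,
                    present_leaves=sorted(h.present_leaves),
                )
                for name, h in sorted(model.histories.items())
            ],
            ambiguous_groups=sorted(model.ambiguous),
        )
        with open(out / "history.json", "w") as fh:
            fh.write(json.dumps(origin_report.model_dump(), indent=1, sort_keys=True))
        logger.info("infer-history: verdict=%s", model.verdict)

    # ---- stage: conservation ---------------------------------------------
    conservation_report = _scan_conservation(
        events, genes, genome, params, key_by_site, out
    )

    # ---- stage: report ----------------------------------------------------
    verdict_counts: dict[str, int] = {}
    for v in event_verdicts:
        verdict_counts[v] = verdict_counts.get(v, 0) + 1
    kind_counts = (
        events_df["kind"].value_counts().to_dict() if len(events_df) else {}
    )
    report = RunReport(
        seed=run_seed,
        parameters=params,
        stages=stages,
        n_genes=len(genes),
        n_characters=len(cm.characters),
        subfamilies=subfam_calls,
        event_counts={k: int(v) for k, v in kind_counts.items()},
        nmd_verdict_counts=verdict_counts,
        n_stabilized=n_stabilized,
        origin=origin_report,
        conservation=conservation_report,
        files={
            "character_matrix": "character_matrix.tsv",
            "anchored_sites": "anchored_sites.tsv",
            "events": "events.tsv",
            "nmd_calls": "nmd_calls.tsv",
        },
    )
    if truth is not None and cfg.get("score_truth", True):
        report.metrics = score_against_truth(
            truth,
            sites_df=sites_df,
            events_df=events_df,
            nmd_df=nmd_df,
            subfam_calls=subfam_calls,
            origin=origin_report,
        )
    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report


def _merge_map(anchored, window: int):
    """(column, phase) -> merged character key, same linkage as the matrix."""
    by_phase: dict[int, list[int]] = {}
    for s in anchored:
        by_phase.setdefault(s.phase, []).append(s.column)
    out = {}
    for phase, cols in by_phase.items():
        uniq = sorted(set(cols))
        cluster = [uniq[0]]
        for c in uniq[1:]:
            if c - cluster[-1] <= window:
                cluster.append(c)
            else:
                for m in cluster:
                    out[(m, phase)] = (cluster[0], phase)
                cluster = [c]
        for m in cluster:
            out[(m, phase)] = (cluster[0], phase)
    return out


def _resolve_tree(cfg: dict, paths: dict, msa: dict) -> TreeNode | None:
    mode = cfg.get("tree", "truth" if "gene_tree" in paths else "nj")
    if mode == "truth":
        if "gene_tree" not in paths:
            raise ConfigurationError("tree: truth requires a simulated run")
        tree = TreeNode.read(
            [open(paths["gene_tree"]).read().strip()], convert_underscores=False
        )
        return tree
    if mode == "nj":
        tree = phy.nj_tree(phy.p_distance_matrix(msa))
        outgroup = cfg.get("outgroup")
        if not outgroup:
            raise ConfigurationError("NJ trees must be rooted: set 'outgroup'")
        return phy.root_with_outgroup(tree, outgroup)
    # otherwise: a newick file path
    tree = TreeNode.read([open(mode).read().strip()], convert_underscores=False)
    outgroup = cfg.get("outgroup")
    if outgroup and len(tree.children) > 2:
        tree = phy.root_with_outgroup(tree, outgroup)
    return tree


def _scan_conservation(events, genes, genome, params, key_by_site, out: Path):
    from .gene_models import reverse_complement

    gene_by_id = {g.gene_id: g for g in genes}
    # alignment of cassette-exon sequences per homology group
    by_group: dict[str, dict[str, str]] = {}
    for ev in events:
        if ev.kind != se.CASSETTE_EXON:
            continue
        key = key_by_site.get((ev.gene_id, ev.host_intron))
        if key is None:
            continue
        seq = genome[ev.interval.chrom][ev.interval.start : ev.interval.end]
        if ev.interval.strand == "-":
            seq = reverse_complement(seq)
        by_group.setdefault(ih.character_label(key), {})[ev.gene_id] = seq

    runs: list[PerfectRunReport] = []
    mean_ident: dict[str, float] = {}
    profile_rows = []
    for group in sorted(by_group):
        seqs = by_group[group]
        if len(seqs) < 2 or len({len(s) for s in seqs.values()}) != 1:
            continue
        for r in cons.perfect_identity_runs(seqs, min_len=params["min_len"]):
            runs.append(
                PerfectRunReport(
                    group=group, start=r.start, end=r.end,
                    length=r.length, n_sequences=len(seqs),
                )
            )
        prof = cons.column_identity_profile(seqs, window=params["profile_window"])
        mean_ident[group] = round(float(prof.mean()), 4)
        profile_rows.extend((group, i, round(float(p), 4)) for i, p in enumerate(prof))
    pd.DataFrame(profile_rows, columns=["group", "column", "identity"]).to_csv(
        out / "conservation_profiles.tsv", sep="\t", index=False
    )

    # intron-length standing of each event's host intron within its species
    lengths_by_species: dict[str, list[int]] = {}
    for g in genes:
        lengths_by_species.setdefault(g.species, []).extend(
            i.length for i in g.introns
        )
    percentiles: list[HostIntronPercentile] = []
    seen = set()
    for ev in events:
        key = key_by_site.get((ev.gene_id, ev.host_intron))
        if key is None or (ev.gene_id, ev.host_intron) in seen:
            continue
        seen.add((ev.gene_id, ev.host_intron))
        g = gene_by_id[ev.gene_id]
        host_len = g.introns[ev.host_intron].length
        pct, top = cons.intron_length_percentile(
            lengths_by_species[g.species], host_len
        )
        percentiles.append(
            HostIntronPercentile(
                gene_id=ev.gene_id,
                group=ih.character_label(key),
                host_intron=ev.host_intron,
                intron_length=host_len,
                percentile=round(pct, 4),
                top_fraction=round(top, 4),
            )
        )
    report = ConservationReport(
        perfect_runs=runs,
        mean_identity_by_group=mean_ident,
        host_intron_percentiles=percentiles,
    )
    with open(out / "conservation.json", "w") as fh:
        fh.write(json.dumps(report.model_dump(), indent=1, sort_keys=True))
    return report


def origin_from_family(family, linkage: str = "strict"):
    """In-memory origin-model inference for a simulated family.

    Draws ESTs for both conditions, calls events against the gene models,
    groups events by the protein-alignment character of their host intron,
    and runs Dollo-based origin-model inference on the family's gene tree.
    Equivalent to the file-based pipeline stages, without the I/O.
    """
    from .simulate import emit_ests

    ests = emit_ests(family, "wt") + emit_ests(family, "nmd_deficient")
    sites_by_gene = {}
    for g in family.genes:
        sites_by_gene[g.gene_id], _ = ih.intron_sites(g)
    anchored, _ = ih.anchor_sites(sites_by_gene, family.msa)
    col_to_key = _merge_map(anchored, window=0)
    key_by_site = {
        (s.gene_id, s.intron_index): col_to_key[(s.column, s.phase)] for s in anchored
    }
    groups: dict[str, set[str]] = {}
    for g in family.genes:
        mine = [
            r
            for r in ests
            if r.chrom == g.locus.chrom
            and g.locus.start <= r.start
            and r.end <= g.locus.end
        ]
        events, _ = se.call_events(mine, g)
        for ev in events:
            key = key_by_site.get((ev.gene_id, ev.host_intron))
            if key is not None:
                groups.setdefault(ih.character_label(key), set()).add(ev.gene_id)
    return phy.infer_origin_model(family.gene_tree, groups, linkage=linkage)


# ---------------------------------------------------------------------------
# Scoring against simulator truth
# ---------------------------------------------------------------------------


def score_against_truth(
    truth,
    sites_df: pd.DataFrame,
    events_df: pd.DataFrame,
    nmd_df: pd.DataFrame,
    subfam_calls,
    origin,
) -> dict[str, float]:
    """Recovery metrics of each inference stage against simulation truth."""
    metrics: dict[str, float] = {}

    # subfamily labels
    truth_sub = {g["gene_id"]: g["subfamily"] for g in truth.genes}
    if subfam_calls:
        correct = sum(1 for c in subfam_calls if c.label == truth_sub.get(c.gene_id))
        metrics["subfamily_accuracy"] = correct / len(subfam_calls)

    # intron sites: (gene, codon/column, phase) -- the simulator's alignment
    # is ungapped so column index equals codon index
    pred_sites = {
        (r.gene_id, int(r.column), int(r.phase)) for r in sites_df.itertuples()
    }
    true_sites = {
        (r["gene_id"], int(r["codon_index"]), int(r["phase"])) for r in truth.introns
    }
    tp = len(pred_sites & true_sites)
    metrics["intron_site_precision"] = tp / len(pred_sites) if pred_sites else 0.0
    metrics["intron_site_recall"] = tp / len(true_sites) if true_sites else 0.0

    # character grouping: intron instances co-clustered iff same truth key
    pred_key = {
        (r.gene_id, int(r.intron_index)): r.character for r in sites_df.itertuples()
    }
    true_key = {
        (r["gene_id"], int(r["intron_index"])): r["key"] for r in truth.introns
    }
    shared = sorted(set(pred_key) & set(true_key))
    pred_pairs = set()
    true_pairs = set()
    for ai in range(len(shared)):
        for bi in range(ai + 1, len(shared)):
            a, b = shared[ai], shared[bi]
            if pred_key[a] == pred_key[b]:
                pred_pairs.add((a, b))
            if true_key[a] == true_key[b]:
                true_pairs.add((a, b))
    both = len(pred_pairs & true_pairs)
    metrics["character_pair_precision"] = both / len(pred_pairs) if pred_pairs else 1.0
    metrics["character_pair_recall"] = both / len(true_pairs) if true_pairs else 1.0

    # events
    pred_ev = {
        (r.gene_id, r.kind, int(r.host_intron)) for r in events_df.itertuples()
    } if len(events_df) else set()
    true_ev = {(e["gene_id"], e["kind"], int(e["host_intron"])) for e in truth.events}
    tp = len(pred_ev & true_ev)
    metrics["event_precision"] = tp / len(pred_ev) if pred_ev else 0.0
    metrics["event_recall"] = tp / len(true_ev) if true_ev else 0.0

    # NMD verdicts of event isoforms
    truth_verdict = {
        (i["gene_id"], i["kind"], i["host_intron"]): i["nmd_verdict"]
        for i in truth.isoforms
        if i["kind"] != "productive"
    }
    if len(nmd_df):
        n_match = n_tot = 0
        for r in nmd_df.itertuples():
            key = (r.gene_id, r.kind, int(r.host_intron))
            if key in truth_verdict:
                n_tot += 1
                if r.verdict == truth_verdict[key]:
                    n_match += 1
        if n_tot:
            metrics["nmd_verdict_accuracy"] = n_match / n_tot

    if origin is not None:
        metrics["origin_verdict_correct"] = float(origin.verdict == truth.regime)
    return metrics
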