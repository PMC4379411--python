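"""Simulation of an SR-like gene family with unproductive splicing, with truth.

The simulator evolves a single ancestral splicing-factor gene down a species
tree spanning animals and fungi, duplicating it on configured branches (a
chordate duplication followed by a vertebrate duplication mirrors the
SRSF4/5/6 expansion).  Along each branch the coding sequence accumulates
substitutions (rejecting any that create an in-frame stop in the productive
frame), introns are gained at codon boundaries and lost precisely, and
"poison" cassette exons — alternative exons carrying an in-frame stop codon —
are born into introns, die, or are replaced (a death coupled to a birth on
the same branch).  Every structural event is logged so each downstream
inference stage can be scored against ground truth.

The generator also emits EST-like spliced reads drawn from each gene's
isoform mixture (productive / exon-included / intron-retained /
polyA-truncated), thinned by NMD efficiency in the wild-type condition, and
per-isoform abundance tables for two conditions.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .errors import ConfigurationError, InputError
from .gene_models import (
    Bed12Record,
    GeneModel,
    GenomicInterval,
    Isoform,
    reverse_complement,
    write_bed12,
    write_fasta,
    write_gff,
)

STOPS = ("TAA", "TAG", "TGA")
NT = "ACGT"

TRUTH_SCHEMA_VERSION = 1

# Opisthokont-like species tree: a fungal outgroup clade and nine animals,
# with named internal nodes used to address duplication and event branches.
DEFAULT_SPECIES_TREE = (
    "((neurospora:0.5,aspergillus:0.5)fungi:0.5,"
    "(anemone:0.85,((fly:0.7,worm:0.7)protostomes:0.1,"
    "(urchin:0.75,(lancelet:0.7,(zebrafish:0.5,(frog:0.4,(chicken:0.3,"
    "(human:0.15,mouse:0.15)mammals:0.15)amniotes:0.1)tetrapods:0.1)"
    "vertebrates:0.2)chordates:0.05)deuterostomes:0.05)bilateria:0.1)"
    "animals:0.15)opisthokonts;"
)

DEFAULT_DUPLICATIONS = [
    {"node": "chordates", "lineage": "g"},
    {"node": "vertebrates", "lineage": "g.2"},
]

DEFAULT_SUBFAMILY_LABELS = {
    "g": "SRSF5-like",
    "g.1": "SRSF5-like",
    "g.2": "SRSF46-like",
}

# (codon_index, phase) of the seven ancestral introns; ordinal 4 is the
# deep host intron of the ancestral unproductive splicing.
DEFAULT_ANCESTRAL_INTRONS = [
    (25, 0), (55, 1), (90, 0), (120, 2), (150, 0), (180, 1), (210, 0),
]


@dataclass
class PlacedEvent:
    """A structural event pinned to a branch of the gene tree.

    ``node`` is a named species-tree node and ``lineage`` the gene-copy label
    (e.g. ``g.2`` for the post-duplication paralog); the event applies on the
    branch leading into that node for that copy.  ``intron`` addresses an
    intron by homology key.  Kinds: intron_gain, intron_loss, poison_birth,
    poison_death, exon_loss (drop the cassette exon but keep the intron's
    alternative/retention status, the fungal configuration).
    """

    node: str
    lineage: str
    kind: str
    intron: str | None = None
    group: str | None = None
    codon: int | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    species_tree: str = DEFAULT_SPECIES_TREE
    outgroup: str = "neurospora"
    duplications: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_DUPLICATIONS])
    subfamily_labels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SUBFAMILY_LABELS))
    placed_events: list[PlacedEvent] = field(default_factory=list)
    regime: str | None = None

    # ancestral gene structure
    protein_length: int = 240
    ancestral_introns: list[tuple[int, int]] = field(
        default_factory=lambda: [tuple(x) for x in DEFAULT_ANCESTRAL_INTRONS]
    )
    ancestral_poison_intron: int | None = 4
    host_intron_up_length: int = 80  # 5' intronic part of the ancestral host
    poison_exon_length: int = 241  # 3k+1; long enough to hold a perfect-identity run
    poison_conserved: bool = True

    # evolutionary rates (per unit branch length; substitutions per site)
    substitution_rate: float = 0.05
    intron_gain_rate: float = 0.02
    intron_loss_rate: float = 0.02
    poison_birth_rate: float = 0.0
    poison_death_rate: float = 0.0
    replacement_coupling: float = 0.0
    intron_length_mu: float = 4.0  # ln-nt
    intron_length_sigma: float = 0.6

    # expression / sampling
    inclusion_rate: float = 0.3
    retention_rate: float = 0.15
    polyA_rate: float = 0.05
    n_ests: int = 150
    est_length: int = 800
    nmd_efficiency: float = 0.8
    nmd_threshold: int = 50
    n_reads: int = 2000

    # realization
    utr_length: int = 30
    spacer_length: int = 60
    trim_end: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ancestral_introns"] = [list(x) for x in self.ancestral_introns]
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        data = dict(data)
        if "placed_events" in data:
            data["placed_events"] = [
                e if isinstance(e, PlacedEvent) else PlacedEvent(**e)
                for e in data["placed_events"]
            ]
        if "ancestral_introns" in data:
            data["ancestral_introns"] = [tuple(x) for x in data["ancestral_introns"]]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Evolving gene state
# ---------------------------------------------------------------------------


@dataclass
class SimIntron:
    key: str
    codon: int
    phase: int
    up: str  # GT..AG; carries an embedded in-frame stop for retention
    up_stop: int  # offset of that stop triplet within `up`
    exon: str | None = None  # poison cassette exon, if any
    exon_stop: int | None = None
    down: str | None = None  # GT..AG after the exon
    group: str | None = None  # unproductive-splicing homology group
    conserved: bool = False

    @property
    def seq(self) -> str:
        if self.exon is None:
            return self.up
        return self.up + self.exon + self.down

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def cds_upstream(self) -> int:
        return 3 * self.codon + self.phase


@dataclass
class SimGene:
    cds: str  # ATG ... stop, frame 0, no internal stop
    introns: list[SimIntron]
    lineage: str

    def clone(self, lineage: str | None = None) -> "SimGene":
        g = copy.deepcopy(self)
        if lineage is not None:
            g.lineage = lineage
        return g

    @property
    def n_aa(self) -> int:
        return len(self.cds) // 3 - 1


def _random_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        c = "".join(NT[i] for i in rng.integers(0, 4, 3))
        if c not in STOPS and c != "ATG":
            out.append(c)
    return "".join(out)


def _frame_offset(cds_upstream: int, minimum: int) -> int:
    """Smallest offset >= minimum that is in frame given upstream CDS nt."""
    o = minimum
    while (cds_upstream + o) % 3 != 0:
        o += 1
    return o


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, n))


def _make_intron_part(
    rng: np.random.Generator, length: int, stop_offset: int | None
) -> str:
    """A GT..AG intronic segment, optionally with a stop triplet embedded."""
    length = max(length, (stop_offset + 8) if stop_offset is not None else 12)
    body = list("GT" + _random_nt(rng, length - 4) + "AG")
    if stop_offset is not None:
        body[stop_offset : stop_offset + 3] = "TAA"
    return "".join(body)


def _make_poison_exon(
    rng: np.random.Generator, length: int, cds_upstream: int
) -> tuple[str, int]:
    """A cassette exon with its first in-frame stop at a known offset."""
    stop_off = _frame_offset(cds_upstream, 6)
    exon = list(_random_nt(rng, max(length, stop_off + 6)))
    # clear accidental in-frame stops upstream of the designated one
    first_inframe = _frame_offset(cds_upstream, 0)
    for i in range(first_inframe, stop_off, 3):
        if "".join(exon[i : i + 3]) in STOPS:
            exon[i + 1] = "C"
    exon[stop_off : stop_off + 3] = "TAA"
    return "".join(exon), stop_off


def _sample_intron_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return max(20, int(round(np.exp(rng.normal(cfg.intron_length_mu, cfg.intron_length_sigma)))))


def make_ancestral_gene(cfg: SimulationConfig, rng: np.random.Generator) -> SimGene:
    cds = "ATG" + _random_codons(rng, cfg.protein_length - 1) + "TAA"
    introns: list[SimIntron] = []
    for i, (codon, phase) in enumerate(cfg.ancestral_introns):
        if codon >= cfg.protein_length:
            raise ConfigurationError("ancestral intron beyond protein end")
        upstream = 3 * codon + phase
        stop_off = _frame_offset(upstream, 4)
        if i == cfg.ancestral_poison_intron:
            up = _make_intron_part(rng, cfg.host_intron_up_length, stop_off)
        else:
            up = _make_intron_part(rng, _sample_intron_length(rng, cfg), stop_off)
        introns.append(
            SimIntron(key=f"I{i + 1}", codon=codon, phase=phase, up=up, up_stop=stop_off)
        )
    gene = SimGene(cds=cds, introns=introns, lineage="g")
    if cfg.ancestral_poison_intron is not None:
        _insert_poison(
            gene.introns[cfg.ancestral_poison_intron], cfg, rng, group="P1"
        )
    return gene


def _insert_poison(
    intron: SimIntron, cfg: SimulationConfig, rng: np.random.Generator, group: str
) -> None:
    # frame inside the inclusion isoform continues through upstream CDS only
    exon, stop_off = _make_poison_exon(rng, cfg.poison_exon_length, intron.cds_upstream)
    intron.exon = exon
    intron.exon_stop = stop_off
    intron.down = _make_intron_part(rng, 40, None)
    intron.group = group
    intron.conserved = cfg.poison_conserved


def _remove_poison(intron: SimIntron) -> None:
    intron.exon = None
    intron.exon_stop = None
    intron.down = None
    intron.group = None
    intron.conserved = False


def _drop_exon_keep_alternative(intron: SimIntron) -> None:
    """Fungal configuration: no cassette exon, but the intron remains an
    alternative (retained) intron belonging to the same homology group."""
    if intron.exon is not None:
        intron.up = intron.up + intron.down
        intron.exon = None
        intron.exon_stop = None
        intron.down = None
        intron.conserved = False


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------


def _protected_intron_positions(intron: SimIntron) -> set[int]:
    prot = {0, 1}
    up_len = len(intron.up)
    prot |= {up_len - 2, up_len - 1}
    prot |= set(range(intron.up_stop, intron.up_stop + 3))
    if intron.exon is not None:
        ex_start = up_len
        ex_len = len(intron.exon)
        if intron.conserved:
            prot |= set(range(ex_start, ex_start + ex_len))
        elif intron.exon_stop is not None:
            prot |= set(range(ex_start + intron.exon_stop, ex_start + intron.exon_stop + 3))
        dn_start = ex_start + ex_len
        dn_len = len(intron.down)
        prot |= {dn_start, dn_start + 1, dn_start + dn_len - 2, dn_start + dn_len - 1}
    return prot


def _mutate_branch(
    gene: SimGene, t: float, cfg: SimulationConfig, rng: np.random.Generator
) -> None:
    lens = [len(gene.cds)] + [i.length for i in gene.introns]
    total = sum(lens)
    n_sub = rng.poisson(cfg.substitution_rate * total * t)
    if n_sub == 0:
        return
    cds = list(gene.cds)
    intron_seqs = [list(i.seq) for i in gene.introns]
    protected = [None] * len(gene.introns)  # computed lazily
    n_codons = len(cds) // 3
    for _ in range(n_sub):
        applied = False
        for _attempt in range(30):
            if applied:
                break
            pos = int(rng.integers(0, total))
            new = NT[int(rng.integers(0, 4))]
            if pos < lens[0]:
                # CDS site: keep start and stop codons; never create an
                # internal stop in the productive frame
                if pos < 3 or pos >= lens[0] - 3 or cds[pos] == new:
                    continue
                ci = pos // 3
                codon = cds[3 * ci : 3 * ci + 3]
                codon[pos % 3] = new
                if "".join(codon) in STOPS and ci < n_codons - 1:
                    continue
                cds[pos] = new
                applied = True
                continue
            off = pos - lens[0]
            for k, intron in enumerate(gene.introns):
                if off < lens[k + 1]:
                    if protected[k] is None:
                        protected[k] = _protected_intron_positions(intron)
                    if off not in protected[k] and intron_seqs[k][off] != new:
                        intron_seqs[k][off] = new
                        applied = True
                    break
                off -= lens[k + 1]
    gene.cds = "".join(cds)
    for intron, seq in zip(gene.introns, intron_seqs):
        s = "".join(seq)
        up_len = len(intron.up)
        intron.up = s[:up_len]
        if intron.exon is not None:
            ex_len = len(intron.exon)
            intron.exon = s[up_len : up_len + ex_len]
            intron.down = s[up_len + ex_len :]


def _do_intron_gain(
    gene: SimGene,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    counters: dict,
    codon: int | None = None,
    key: str | None = None,
) -> SimIntron | None:
    occupied = {(i.codon, i.phase) for i in gene.introns}
    if codon is None:
        candidates = [c for c in range(1, gene.n_aa) if (c, 0) not in occupied]
        if not candidates:
            return None
        codon = int(candidates[int(rng.integers(0, len(candidates)))])
    elif (codon, 0) in occupied:
        return None
    if key is None:
        counters["gain"] += 1
        key = f"N{counters['gain']}"
    stop_off = _frame_offset(3 * codon, 4)
    up = _make_intron_part(rng, _sample_intron_length(rng, cfg), stop_off)
    intron = SimIntron(key=key, codon=codon, phase=0, up=up, up_stop=stop_off)
    gene.introns.append(intron)
    gene.introns.sort(key=lambda i: (i.codon, i.phase))
    return intron


def _find_intron(gene: SimGene, ref: str | int) -> SimIntron | None:
    if isinstance(ref, int):
        return gene.introns[ref] if 0 <= ref < len(gene.introns) else None
    for i in gene.introns:
        if i.key == ref:
            return i
    return None


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedIsoform:
    isoform_id: str
    gene_id: str
    kind: str  # productive / CASSETTE_EXON / INTRON_RETENTION / ALT_POLYA
    group: str | None
    host_intron: int | None
    weight: float
    nmd_verdict: str
    isoform: Isoform


@dataclass
class SyntheticTruth:
    regime: str
    genes: list[dict]
    introns: list[dict]
    events: list[dict]
    isoforms: list[dict]
    branch_log: list[dict]
    gene_tree_newick: str
    species_tree_newick: str
    config: dict
    schema_version: int = TRUTH_SCHEMA_VERSION


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    genomes: dict[str, str]  # chrom -> sequence
    genes: list[GeneModel]
    proteins: dict[str, str]
    msa: dict[str, str]
    isoforms: dict[str, list[SimulatedIsoform]]
    truth: SyntheticTruth
    gene_tree: TreeNode


def _parse_tree(newick: str) -> TreeNode:
    # underscores are literal in our identifiers, not spaces
    return TreeNode.read([newick], convert_underscores=False)


def gene_tree_skeleton(cfg: SimulationConfig) -> TreeNode:
    """The gene tree implied by the species tree and duplication settings.

    Leaves are gene ids (``species_lineage``); internal nodes are named
    ``node@lineage``.
    """
    species_tree = _parse_tree(cfg.species_tree)
    dups = {(d["node"], d["lineage"]) for d in cfg.duplications}

    def build(snode: TreeNode, lineage: str, length: float | None) -> TreeNode:
        name = snode.name
        if (name, lineage) in dups:
            parent = TreeNode(name=f"{name}@{lineage}", length=length)
            for child_lin in (f"{lineage}.1", f"{lineage}.2"):
                parent.append(build(snode, child_lin, 0.0))
            return parent
        if snode.is_tip():
            return TreeNode(name=f"{name}_{lineage}", length=length)
        node = TreeNode(name=f"{name}@{lineage}", length=length)
        for c in snode.children:
            node.append(build(c, lineage, c.length))
        return node

    return build(species_tree, "g", None)


def _subfamily_for(lineage: str, labels: Mapping[str, str]) -> str:
    best = ""
    for prefix, label in labels.items():
        if (lineage == prefix or lineage.startswith(prefix + ".")) and len(prefix) > len(best):
            best = prefix
    return labels.get(best, lineage)


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Run the full simulation; identical config+seed gives identical output."""
    rng = np.random.default_rng(cfg.seed)
    species_tree = _parse_tree(cfg.species_tree)
    dups = {(d["node"], d["lineage"]) for d in cfg.duplications}
    placed: dict[tuple[str, str], list[PlacedEvent]] = {}
    for ev in cfg.placed_events:
        placed.setdefault((ev.node, ev.lineage), []).append(ev)

    counters = {"gain": 0, "group": 1}  # P1 reserved for the ancestral group
    branch_log: list[dict] = []
    leaf_states: dict[str, list[SimGene]] = {}

    def log(node: str, lineage: str, kind: str, **extra) -> None:
        branch_log.append({"node": node, "lineage": lineage, "type": kind, **extra})

    def apply_placed(gene: SimGene, node: str) -> None:
        for ev in placed.get((node, gene.lineage), []):
            if ev.kind == "intron_gain":
                intron = _do_intron_gain(
                    gene, cfg, rng, counters, codon=ev.codon, key=ev.intron
                )
                if intron is not None:
                    log(node, gene.lineage, "intron_gain", key=intron.key)
            elif ev.kind == "intron_loss":
                intron = _find_intron(gene, ev.intron)
                if intron is not None:
                    if intron.group:
                        log(node, gene.lineage, "poison_death", group=intron.group,
                            key=intron.key, via="intron_loss")
                    gene.introns.remove(intron)
                    log(node, gene.lineage, "intron_loss", key=intron.key)
            elif ev.kind == "poison_birth":
                intron = _find_intron(gene, ev.intron)
                if intron is not None and intron.group is None:
                    group = ev.group
                    if group is None:
                        counters["group"] += 1
                        group = f"P{counters['group']}"
                    _insert_poison(intron, cfg, rng, group)
                    log(node, gene.lineage, "poison_birth", group=group, key=intron.key)
            elif ev.kind == "poison_death":
                intron = _find_intron(gene, ev.intron)
                if intron is not None and intron.group:
                    log(node, gene.lineage, "poison_death", group=intron.group,
                        key=intron.key)
                    _remove_poison(intron)
            elif ev.kind == "exon_loss":
                intron = _find_intron(gene, ev.intron)
                if intron is not None and intron.exon is not None:
                    _drop_exon_keep_alternative(intron)
                    log(node, gene.lineage, "exon_loss", group=intron.group,
                        key=intron.key)
            else:
                raise ConfigurationError(f"unknown placed event kind {ev.kind!r}")

    def rate_events(gene: SimGene, node: str, t: float) -> None:
        for _ in range(rng.poisson(cfg.intron_gain_rate * t)):
            intron = _do_intron_gain(gene, cfg, rng, counters)
            if intron is not None:
                log(node, gene.lineage, "intron_gain", key=intron.key)
        for _ in range(rng.poisson(cfg.intron_loss_rate * t)):
            if not gene.introns:
                warnings.warn("intron loss drawn on intron-free gene; skipped")
                continue
            intron = gene.introns[int(rng.integers(0, len(gene.introns)))]
            if intron.group:
                log(node, gene.lineage, "poison_death", group=intron.group,
                    key=intron.key, via="intron_loss")
            gene.introns.remove(intron)
            log(node, gene.lineage, "intron_loss", key=intron.key)
        for _ in range(rng.poisson(cfg.poison_birth_rate * t)):
            free = [i for i in gene.introns if i.group is None]
            if not free:
                warnings.warn("poison birth drawn with no free intron; skipped")
                continue
            intron = free[int(rng.integers(0, len(free)))]
            counters["group"] += 1
            group = f"P{counters['group']}"
            _insert_poison(intron, cfg, rng, group)
            log(node, gene.lineage, "poison_birth", group=group, key=intron.key)
        for _ in range(rng.poisson(cfg.poison_death_rate * t)):
            with_group = [i for i in gene.introns if i.group]
            if not with_group:
                continue
            intron = with_group[int(rng.integers(0, len(with_group)))]
            log(node, gene.lineage, "poison_death", group=intron.group, key=intron.key)
            _remove_poison(intron)
            if rng.random() < cfg.replacement_coupling:
                free = [i for i in gene.introns if i.group is None]
                if free:
                    target = free[int(rng.integers(0, len(free)))]
                    counters["group"] += 1
                    group = f"P{counters['group']}"
                    _insert_poison(target, cfg, rng, group)
                    log(node, gene.lineage, "poison_birth", group=group,
                        key=target.key, coupled=True)

    def descend(snode: TreeNode, gene: SimGene) -> None:
        name = snode.name
        if (name, gene.lineage) in dups:
            for child_lin in (f"{gene.lineage}.1", f"{gene.lineage}.2"):
                child_gene = gene.clone(lineage=child_lin)
                log(name, child_lin, "duplication")
                apply_placed(child_gene, name)
                descend_children(snode, child_gene)
            return
        apply_placed(gene, name)
        descend_children(snode, gene)

    def descend_children(snode: TreeNode, gene: SimGene) -> None:
        if snode.is_tip():
            leaf_states.setdefault(snode.name, []).append(gene)
            return
        for child in snode.children:
            child_gene = gene.clone()
            _mutate_branch(child_gene, child.length or 0.0, cfg, rng)
            rate_events(child_gene, child.name, child.length or 0.0)
            descend(child, child_gene)

    root_gene = make_ancestral_gene(cfg, rng)
    descend(species_tree, root_gene)

    # ---- realization ------------------------------------------------------
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    isoforms: dict[str, list[SimulatedIsoform]] = {}
    truth_genes: list[dict] = []
    truth_introns: list[dict] = []
    truth_events: list[dict] = []
    truth_isoforms: list[dict] = []

    species_order = [t.name for t in species_tree.tips()]
    gene_index = 0
    for species in species_order:
        chrom = f"{species}_chr"
        parts: list[str] = []
        offset = 0
        for gene_state in sorted(leaf_states[species], key=lambda g: g.lineage):
            gene_id = f"{species}_{gene_state.lineage}"
            strand = "+" if gene_index % 2 == 0 else "-"
            gene_index += 1
            spacer = _random_nt(rng, cfg.spacer_length)
            parts.append(spacer)
            offset += len(spacer)
            model, gene_chrom_seq, sim_isos, intron_rows, event_rows, protein = (
                _realize_gene(gene_state, gene_id, species, chrom, offset, strand, cfg, rng)
            )
            parts.append(gene_chrom_seq)
            offset += len(gene_chrom_seq)
            genes.append(model)
            proteins[gene_id] = protein
            isoforms[gene_id] = sim_isos
            truth_genes.append(
                {
                    "gene_id": gene_id,
                    "species": species,
                    "lineage": gene_state.lineage,
                    "subfamily": _subfamily_for(gene_state.lineage, cfg.subfamily_labels),
                    "chrom": chrom,
                    "strand": strand,
                    "trim_end": cfg.trim_end or len(protein),
                }
            )
            truth_introns.extend(intron_rows)
            truth_events.extend(event_rows)
            truth_isoforms.extend(
                {
                    "isoform_id": s.isoform_id,
                    "gene_id": s.gene_id,
                    "kind": s.kind,
                    "group": s.group,
                    "host_intron": s.host_intron,
                    "weight": s.weight,
                    "nmd_verdict": s.nmd_verdict,
                }
                for s in sim_isos
            )
        parts.append(_random_nt(rng, cfg.spacer_length))
        genomes[chrom] = "".join(parts)

    gene_tree = gene_tree_skeleton(cfg)
    regime = cfg.regime or _derive_regime(branch_log)
    truth = SyntheticTruth(
        regime=regime,
        genes=truth_genes,
        introns=truth_introns,
        events=truth_events,
        isoforms=truth_isoforms,
        branch_log=branch_log,
        gene_tree_newick=str(gene_tree).strip(),
        species_tree_newick=cfg.species_tree,
        config=cfg.to_dict(),
    )
    msa = dict(sorted(proteins.items()))
    if cfg.trim_end is not None:
        msa = {k: v[: cfg.trim_end] for k, v in msa.items()}
    return SimulatedFamily(
        config=cfg,
        genomes=genomes,
        genes=genes,
        proteins=proteins,
        msa=msa,
        isoforms=isoforms,
        truth=truth,
        gene_tree=gene_tree,
    )


def _derive_regime(branch_log: list[dict]) -> str:
    births = [e for e in branch_log if e["type"] == "poison_birth"]
    groups = {e.get("group") for e in births} | {"P1"}
    if len(groups) <= 1:
        return "SINGLE_ORIGIN"
    if any(e.get("coupled") for e in births):
        return "REPLACEMENT"
    return "INDEPENDENT"


# ---------------------------------------------------------------------------
# Gene realization
# ---------------------------------------------------------------------------


def _realize_gene(
    state: SimGene,
    gene_id: str,
    species: str,
    chrom: str,
    offset: int,
    strand: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
):
    utr5 = _random_nt(rng, cfg.utr_length)
    utr3 = _random_nt(rng, cfg.utr_length)
    introns = sorted(state.introns, key=lambda i: (i.codon, i.phase))

    # transcription-coordinate layout
    t_parts: list[str] = [utr5]
    exon_t: list[tuple[int, int]] = []
    intron_t: list[tuple[int, int]] = []
    pos = len(utr5)
    exon_start = 0
    prev_cut = 0
    for intron in introns:
        cut = intron.cds_upstream
        seg = state.cds[prev_cut:cut]
        t_parts.append(seg)
        pos += len(seg)
        exon_t.append((exon_start, pos))
        t_parts.append(intron.seq)
        intron_t.append((pos, pos + intron.length))
        pos += intron.length
        exon_start = pos
        prev_cut = cut
    t_parts.append(state.cds[prev_cut:])
    pos += len(state.cds) - prev_cut
    t_parts.append(utr3)
    pos += len(utr3)
    exon_t.append((exon_start, pos))
    t_seq = "".join(t_parts)
    gene_len = len(t_seq)
    assert pos == gene_len

    def to_genomic(a: int, b: int) -> GenomicInterval:
        if strand == "+":
            return GenomicInterval(chrom, offset + a, offset + b, strand)
        return GenomicInterval(chrom, offset + gene_len - b, offset + gene_len - a, strand)

    locus = to_genomic(0, gene_len)
    exons = [to_genomic(a, b) for a, b in exon_t]
    if strand == "+":
        cds_start = offset + len(utr5)
        cds_end = offset + gene_len - len(utr3)
    else:
        cds_start = offset + len(utr3)
        cds_end = offset + gene_len - len(utr5)
    model = GeneModel(
        gene_id=gene_id,
        species=species,
        locus=locus,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        subfamily_label=_subfamily_for(state.lineage, cfg.subfamily_labels),
    ).validate()

    protein = _translate_cds(state.cds)

    # isoforms and their truth verdicts
    cds_offset = len(utr5)
    ref_stop_mrna = len(utr5) + len(state.cds) - 3  # in productive mRNA

    def verdict_for(blocks_t: list[tuple[int, int]], polyA: bool) -> str:
        mrna = "".join(t_seq[a:b] for a, b in blocks_t)
        junctions, acc = [], 0
        for a, b in blocks_t[:-1]:
            acc += b - a
            junctions.append(acc)
        stop_pos = None
        for i in range(cds_offset, len(mrna) - 2, 3):
            if mrna[i : i + 3] in STOPS:
                stop_pos = i + 3
                break
        if stop_pos is None:
            return "no_stop"
        last_j = junctions[-1] if junctions else None
        if last_j is None or last_j < stop_pos:
            return "ESCAPE_TRUNCATED" if polyA else "ESCAPE_LAST_EXON"
        return "NMD_TARGET" if last_j - stop_pos >= cfg.nmd_threshold else "PRODUCTIVE"

    raw: list[tuple[str, str, str | None, int | None, list[tuple[int, int]], bool, float]] = [
        (f"{gene_id}:productive", "productive", None, None, exon_t, False, 1.0)
    ]
    event_rows: list[dict] = []
    for h, intron in enumerate(introns):
        if intron.group is None:
            continue
        s, e = intron_t[h]
        if intron.exon is not None:
            ex_a = s + len(intron.up)
            ex_b = ex_a + len(intron.exon)
            inc_blocks = exon_t[: h + 1] + [(ex_a, ex_b)] + exon_t[h + 1 :]
            raw.append(
                (f"{gene_id}:cassette_i{h}", "CASSETTE_EXON", intron.group, h,
                 inc_blocks, False, cfg.inclusion_rate)
            )
            ivl = to_genomic(ex_a, ex_b)
            event_rows.append(
                {"gene_id": gene_id, "kind": "CASSETTE_EXON", "host_intron": h,
                 "group": intron.group, "host_key": intron.key,
                 "start": ivl.start, "end": ivl.end}
            )
        ret_blocks = exon_t[:h] + [(exon_t[h][0], exon_t[h + 1][1])] + exon_t[h + 2 :]
        raw.append(
            (f"{gene_id}:ri_i{h}", "INTRON_RETENTION", intron.group, h,
             ret_blocks, False, cfg.retention_rate)
        )
        ivl = to_genomic(s, e)
        event_rows.append(
            {"gene_id": gene_id, "kind": "INTRON_RETENTION", "host_intron": h,
             "group": intron.group, "host_key": intron.key,
             "start": ivl.start, "end": ivl.end}
        )
        if intron.exon is not None and cfg.polyA_rate > 0:
            term = s + len(intron.up) + len(intron.exon) // 2
            pa_blocks = exon_t[:h] + [(exon_t[h][0], term)]
            raw.append(
                (f"{gene_id}:pA_i{h}", "ALT_POLYA", intron.group, h,
                 pa_blocks, True, cfg.polyA_rate)
            )
            ivl = to_genomic(s, term)
            event_rows.append(
                {"gene_id": gene_id, "kind": "ALT_POLYA", "host_intron": h,
                 "group": intron.group, "host_key": intron.key,
                 "start": ivl.start, "end": ivl.end}
            )

    total_w = sum(w for *_, w in raw)
    sim_isos: list[SimulatedIsoform] = []
    for iso_id, kind, group, host, blocks_t, polyA, w in raw:
        blocks = [to_genomic(a, b) for a, b in blocks_t]
        iso = Isoform(
            parent=gene_id,
            blocks=blocks,
            cds_offset=cds_offset,
            polyA_truncated=polyA,
            isoform_id=iso_id,
        )
        verdict = "PRODUCTIVE" if kind == "productive" else verdict_for(blocks_t, polyA)
        sim_isos.append(
            SimulatedIsoform(
                isoform_id=iso_id,
                gene_id=gene_id,
                kind=kind,
                group=group,
                host_intron=host,
                weight=w / total_w,
                nmd_verdict=verdict,
                isoform=iso,
            )
        )

    intron_rows = [
        {"gene_id": gene_id, "intron_index": h, "key": i.key,
         "codon_index": i.codon, "phase": i.phase,
         "length": i.length, "group": i.group}
        for h, i in enumerate(introns)
    ]
    chrom_seq = t_seq if strand == "+" else reverse_complement(t_seq)
    return model, chrom_seq, sim_isos, intron_rows, event_rows, protein


def _translate_cds(cds: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(cds).translate())
    if not aa.endswith("*") or "*" in aa[:-1]:
        raise AssertionError("simulated CDS must end with its only stop")
    return aa[:-1]


# ---------------------------------------------------------------------------
# EST and abundance emission
# ---------------------------------------------------------------------------


def condition_weights(
    sim_isos: list[SimulatedIsoform], nmd_efficiency: float
) -> np.ndarray:
    w = np.array([s.weight for s in sim_isos], dtype=float)
    thin = np.array(
        [1.0 - nmd_efficiency if s.nmd_verdict == "NMD_TARGET" else 1.0 for s in sim_isos]
    )
    w = w * thin
    return w / w.sum()


def emit_ests(
    family: SimulatedFamily,
    condition: str = "wt",
    seed: int | None = None,
) -> list[Bed12Record]:
    """Draw EST-like spliced reads from each gene's isoform mixture.

    In the wild-type condition NMD-target isoforms are thinned by
    ``nmd_efficiency`` before sampling; the NMD-deficient condition samples
    the untreated mixture.  Reads from polyA-truncated isoforms are anchored
    at the transcript 3' end (oligo-dT priming) and flagged ``;pA=1``.
    """
    cfg = family.config
    eff = cfg.nmd_efficiency if condition == "wt" else 0.0
    rng = np.random.default_rng(
        cfg.seed + (1_000_003 if condition == "wt" else 2_000_003)
        if seed is None
        else seed
    )
    out: list[Bed12Record] = []
    for gene_id in sorted(family.isoforms):
        sim_isos = family.isoforms[gene_id]
        if cfg.n_ests == 0:
            continue
        weights = condition_weights(sim_isos, eff)
        draws = rng.choice(len(sim_isos), size=cfg.n_ests, p=weights)
        for n, di in enumerate(draws):
            s = sim_isos[int(di)]
            iso = s.isoform
            mlen = iso.mrna_length
            read_len = min(cfg.est_length, mlen)
            if s.kind == "ALT_POLYA":
                w0 = mlen - read_len
            else:
                w0 = int(rng.integers(0, mlen - read_len + 1))
            w1 = w0 + read_len
            blocks = _window_blocks(iso, w0, w1)
            name = f"{gene_id}|{s.isoform_id.split(':', 1)[1]}|{n}"
            if s.kind == "ALT_POLYA" and w1 == mlen:
                name += ";pA=1"
            gstarts = sorted(b[0] for b in blocks)
            gends = sorted(b[1] for b in blocks)
            out.append(
                Bed12Record(
                    chrom=iso.blocks[0].chrom,
                    start=gstarts[0],
                    end=gends[-1],
                    name=name,
                    strand=iso.strand,
                    blocks=sorted(blocks),
                )
            )
    return out


def _window_blocks(iso: Isoform, w0: int, w1: int) -> list[tuple[int, int]]:
    """Genomic blocks covered by the mRNA window [w0, w1)."""
    blocks: list[tuple[int, int]] = []
    acc = 0
    for b in iso.blocks:
        lo = max(w0, acc)
        hi = min(w1, acc + b.length)
        if hi > lo:
            if b.strand == "+":
                blocks.append((b.start + (lo - acc), b.start + (hi - acc)))
            else:
                blocks.append((b.end - (hi - acc), b.end - (lo - acc)))
        acc += b.length
    return blocks


def emit_abundances(
    family: SimulatedFamily,
    seed: int | None = None,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Per-isoform counts in wild-type and NMD-deficient conditions."""
    cfg = family.config
    rng = np.random.default_rng(cfg.seed + 3_000_017 if seed is None else seed)
    rows = []
    for gene_id in sorted(family.isoforms):
        sim_isos = family.isoforms[gene_id]
        w_wt = condition_weights(sim_isos, cfg.nmd_efficiency)
        w_nd = condition_weights(sim_isos, 0.0)
        if deterministic:
            c_wt = cfg.n_reads * w_wt
            c_nd = cfg.n_reads * w_nd
        else:
            c_wt = rng.multinomial(cfg.n_reads, w_wt)
            c_nd = rng.multinomial(cfg.n_reads, w_nd)
        for s, cw, cn in zip(sim_isos, c_wt, c_nd):
            rows.append((gene_id, s.isoform_id, float(cw), float(cn)))
    return pd.DataFrame(
        rows, columns=["gene_id", "isoform_id", "count_wt", "count_nmd_deficient"]
    )


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    pd.DataFrame(truth.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.introns).to_csv(outdir / "introns.tsv", sep="\t", index=False)
    pd.DataFrame(truth.events).to_csv(outdir / "events.tsv", sep="\t", index=False)
    pd.DataFrame(truth.isoforms).to_csv(outdir / "isoforms.tsv", sep="\t", index=False)


def read_truth(outdir) -> SyntheticTruth:
    with open(Path(outdir) / "truth.json") as fh:
        data = json.load(fh)
    if data.get("schema_version") != TRUTH_SCHEMA_VERSION:
        raise InputError("unsupported truth schema version")
    return SyntheticTruth(**data)


def write_family(family: SimulatedFamily, outdir) -> dict[str, str]:
    """Write all simulator outputs; returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fasta"),
        "gff": str(outdir / "models.gff3"),
        "proteins": str(outdir / "proteins.fasta"),
        "msa": str(outdir / "msa.fasta"),
        "gene_tree": str(outdir / "gene_tree.nwk"),
        "ests_wt": str(outdir / "ests_wt.bed"),
        "ests_nmd_deficient": str(outdir / "ests_nmd_deficient.bed"),
        "abundances": str(outdir / "abundances.tsv"),
        "truth": str(outdir / "truth"),
    }
    write_fasta(family.genomes, paths["genome"])
    write_gff(family.genes, paths["gff"])
    write_fasta(dict(sorted(family.proteins.items())), paths["proteins"])
    write_fasta(family.msa, paths["msa"])
    with open(paths["gene_tree"], "w") as fh:
        fh.write(family.truth.gene_tree_newick + "\n")
    write_bed12(emit_ests(family, "wt"), paths["ests_wt"])
    write_bed12(emit_ests(family, "nmd_deficient"), paths["ests_nmd_deficient"])
    emit_abundances(family).to_csv(paths["abundances"], sep="\t", index=False)
    write_truth(family.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Regime scenario generation
# ---------------------------------------------------------------------------


def regime_config(
    regime: str, seed: int, base: SimulationConfig | None = None
) -> SimulationConfig:
    """A randomized scenario generated under one of the three regimes.

    SINGLE_ORIGIN keeps the ancestral poison exon everywhere; INDEPENDENT
    drops it and places two births in disjoint clades (in different host
    introns, as observed for real poison exons); REPLACEMENT couples a loss
    of the ancestral unit with a birth in a different intron on the same
    branch.  Branches are drawn at random from the gene tree.
    """
    cfg = copy.deepcopy(base) if base is not None else SimulationConfig()
    cfg.seed = seed
    cfg.regime = regime
    cfg.placed_events = []
    rng = np.random.default_rng(seed + 77_000_001)
    skeleton = gene_tree_skeleton(cfg)
    dup_addrs = {(d["node"], d["lineage"]) for d in cfg.duplications}
    internal = [
        n
        for n in skeleton.non_tips(include_self=False)
        if n.name and "@" in n.name
        # duplication points split the lineage before any event could apply
        and tuple(n.name.split("@")) not in dup_addrs
    ]
    root_children = set(skeleton.children)

    def node_addr(n: TreeNode) -> tuple[str, str]:
        node, lineage = n.name.split("@")
        return node, lineage

    def leafset(n: TreeNode) -> frozenset:
        return frozenset(t.name for t in n.tips())

    n_anc = len(cfg.ancestral_introns)
    host = cfg.ancestral_poison_intron
    other_introns = [f"I{i + 1}" for i in range(n_anc) if i != host]

    if regime == "SINGLE_ORIGIN":
        pass  # ancestral unit only
    elif regime == "INDEPENDENT":
        cfg.ancestral_poison_intron = None
        while True:
            a, b = rng.choice(len(internal), size=2, replace=False)
            na, nb = internal[int(a)], internal[int(b)]
            if not (leafset(na) & leafset(nb)):
                break
        hosts = rng.choice(len(other_introns), size=2, replace=False)
        for n, hi, grp in ((na, hosts[0], "PA"), (nb, hosts[1], "PB")):
            node, lineage = node_addr(n)
            cfg.placed_events.append(
                PlacedEvent(node=node, lineage=lineage, kind="poison_birth",
                            intron=other_introns[int(hi)], group=grp)
            )
    elif regime == "REPLACEMENT":
        candidates = [n for n in internal if n not in root_children]
        n = candidates[int(rng.integers(0, len(candidates)))]
        node, lineage = node_addr(n)
        hi = other_introns[int(rng.integers(0, len(other_introns)))]
        cfg.placed_events.append(
            PlacedEvent(node=node, lineage=lineage, kind="poison_death",
                        intron=f"I{host + 1}")
        )
        cfg.placed_events.append(
            PlacedEvent(node=node, lineage=lineage, kind="poison_birth",
                        intron=hi, group="P2")
        )
    else:
        raise ConfigurationError(f"unknown regime {regime!r}")
    return cfg
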