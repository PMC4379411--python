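"""Alternative-splicing event calling, isoform construction and NMD logic.

Events are called from spliced EST-like alignments against a reference gene
model.  Three event kinds are recognized: a cassette exon strictly inside a
reference intron whose flanking junctions match the host intron's edges, the
retention of an entire intron, and early polyadenylation inside an intron.
The isoform implied by an event is classified as an NMD target by the 50-nt
junction rule: a stop codon at least ``threshold_nt`` upstream of the last
exon-exon junction marks the transcript for decay.  The threshold is a knob
because the NMD machinery itself differs between clades (fungal NMD does not
follow the metazoan exon-junction rule in detail).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AmbiguousProductError, InputError
from .gene_models import (
    Bed12Record,
    GeneModel,
    GenomicInterval,
    Isoform,
    first_stop_position,
    productive_isoform,
    reverse_complement,
    spliced_sequence,
)

CASSETTE_EXON = "CASSETTE_EXON"
INTRON_RETENTION = "INTRON_RETENTION"
ALT_POLYA = "ALT_POLYA"

NMD_TARGET = "NMD_TARGET"
PRODUCTIVE = "PRODUCTIVE"
ESCAPE_LAST_EXON = "ESCAPE_LAST_EXON"
ESCAPE_TRUNCATED = "ESCAPE_TRUNCATED"
NO_START = "no_start"
NO_STOP = "no_stop"


@dataclass(frozen=True)
class SpliceEvent:
    kind: str
    gene_id: str
    host_intron: int  # 0-based ordinal, transcription order
    interval: GenomicInterval
    support: int = 1


@dataclass
class NMDCall:
    isoform_id: str
    verdict: str
    stop_mrna_pos: int | None = None
    last_junction: int | None = None
    distance: int | None = None


@dataclass
class StabilizationRecord:
    gene_id: str
    isoform_id: str
    fraction_wt: float
    fraction_nmd_deficient: float
    fold_change: float
    stabilized: bool


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------


def call_events(
    ests: Iterable[Bed12Record],
    gene: GeneModel,
    min_overhang: int = 10,
) -> tuple[list[SpliceEvent], int]:
    """Call splicing events from spliced alignments on one gene.

    Returns deduplicated events with EST support counts, plus the number of
    alignments skipped for falling outside the locus (or on the wrong
    strand/sequence).  Calls require exact junction agreement with the
    reference model; alternative 5'/3' splice sites are not considered.
    """
    introns = gene.introns  # transcription order
    intron_spans = [(i.start, i.end) for i in introns]  # genomic
    counts: dict[tuple[str, int, int, int], int] = {}

    n_skipped = 0
    for est in ests:
        if (
            est.chrom != gene.locus.chrom
            or est.strand != gene.strand
            or est.start < gene.locus.start
            or est.end > gene.locus.end
        ):
            n_skipped += 1
            continue
        blocks = est.blocks  # genomic ascending
        for ordinal, (s, e) in enumerate(intron_spans):
            # cassette exon: a block strictly inside the intron whose
            # neighbours land exactly on the intron's donor/acceptor edges
            for bi in range(1, len(blocks) - 1):
                a, b = blocks[bi]
                if s < a and b < e and blocks[bi - 1][1] == s and blocks[bi + 1][0] == e:
                    key = (CASSETTE_EXON, ordinal, a, b)
                    counts[key] = counts.get(key, 0) + 1
            # intron retention: one block covers the whole intron with
            # min_overhang aligned nucleotides on each flanking exon
            for a, b in blocks:
                if a <= s - min_overhang and b >= e + min_overhang:
                    key = (INTRON_RETENTION, ordinal, s, e)
                    counts[key] = counts.get(key, 0) + 1
            # early polyadenylation: a polyA-terminated read whose 3' end
            # falls inside the intron (or a novel exon within it)
            if est.polyA:
                term = est.end if gene.strand == "+" else est.start
                if gene.strand == "+" and s < term < e:
                    key = (ALT_POLYA, ordinal, s, term)
                    counts[key] = counts.get(key, 0) + 1
                elif gene.strand == "-" and s < term < e:
                    key = (ALT_POLYA, ordinal, term, e)
                    counts[key] = counts.get(key, 0) + 1

    events = [
        SpliceEvent(
            kind=kind,
            gene_id=gene.gene_id,
            host_intron=ordinal,
            interval=GenomicInterval(gene.locus.chrom, a, b, gene.strand),
            support=n,
        )
        for (kind, ordinal, a, b), n in sorted(counts.items())
    ]
    return events, n_skipped


# ---------------------------------------------------------------------------
# Isoform construction
# ---------------------------------------------------------------------------


def build_isoform(gene: GeneModel, event: SpliceEvent | None = None) -> Isoform:
    """Construct the mature mRNA implied by an event (or the reference)."""
    if event is None:
        return productive_isoform(gene)
    if event.gene_id != gene.gene_id:
        raise InputError(f"event for {event.gene_id} applied to {gene.gene_id}")
    if event.host_intron >= len(gene.introns):
        raise InputError(f"{gene.gene_id}: host intron {event.host_intron} out of range")

    exons = list(gene.exons)  # transcription order
    h = event.host_intron
    chrom, strand = gene.locus.chrom, gene.strand

    if event.kind == CASSETTE_EXON:
        blocks = exons[: h + 1] + [event.interval] + exons[h + 1 :]
        tag = f"cassette_i{h}"
    elif event.kind == INTRON_RETENTION:
        up, down = exons[h], exons[h + 1]
        fused = GenomicInterval(
            chrom, min(up.start, down.start), max(up.end, down.end), strand
        )
        blocks = exons[:h] + [fused] + exons[h + 2 :]
        tag = f"ri_i{h}"
    elif event.kind == ALT_POLYA:
        up = exons[h]
        if strand == "+":
            extended = GenomicInterval(chrom, up.start, event.interval.end, strand)
        else:
            extended = GenomicInterval(chrom, event.interval.start, up.end, strand)
        blocks = exons[:h] + [extended]
        tag = f"pA_i{h}"
    else:
        raise InputError(f"unknown event kind {event.kind!r}")

    iso = Isoform(
        parent=gene.gene_id,
        blocks=blocks,
        cds_offset=None,
        polyA_truncated=(event.kind == ALT_POLYA),
        isoform_id=f"{gene.gene_id}:{tag}",
    )
    cds_first = gene.cds_start if strand == "+" else gene.cds_end - 1
    iso.cds_offset = iso.genomic_to_mrna(cds_first)
    return iso


# ---------------------------------------------------------------------------
# NMD classification
# ---------------------------------------------------------------------------


def classify_nmd(
    isoform: Isoform,
    genome: Mapping[str, str],
    gene: GeneModel | None = None,
    threshold_nt: int = 50,
) -> NMDCall:
    """Apply the junction rule to one isoform.

    The distance is measured from the first nucleotide 3' of the stop codon
    to the last exon-exon junction, both in mRNA coordinates.  A stop at the
    reference position (the gene's annotated stop codon) is always
    PRODUCTIVE.  With no junction downstream of the stop the transcript
    escapes NMD (``ESCAPE_TRUNCATED`` when polyA-truncated, else
    ``ESCAPE_LAST_EXON``).
    """
    iso_id = isoform.isoform_id or isoform.parent
    if isoform.cds_offset is None:
        return NMDCall(isoform_id=iso_id, verdict=NO_START)
    mrna = spliced_sequence(genome, isoform)
    stop_pos = first_stop_position(mrna, isoform.cds_offset)
    if stop_pos is None:
        return NMDCall(isoform_id=iso_id, verdict=NO_STOP)

    junctions = isoform.junctions
    last_junction = junctions[-1] if junctions else None

    if gene is not None:
        # genomic first nt (transcription order) of the annotated stop codon
        ref_first = gene.cds_end - 3 if gene.strand == "+" else gene.cds_start + 2
        if isoform.mrna_to_genomic(stop_pos - 3) == ref_first:
            return NMDCall(
                isoform_id=iso_id,
                verdict=PRODUCTIVE,
                stop_mrna_pos=stop_pos,
                last_junction=last_junction,
                distance=None if last_junction is None else last_junction - stop_pos,
            )

    if last_junction is None or last_junction < stop_pos:
        verdict = ESCAPE_TRUNCATED if isoform.polyA_truncated else ESCAPE_LAST_EXON
        return NMDCall(
            isoform_id=iso_id,
            verdict=verdict,
            stop_mrna_pos=stop_pos,
            last_junction=last_junction,
            distance=None if last_junction is None else last_junction - stop_pos,
        )
    distance = last_junction - stop_pos
    verdict = NMD_TARGET if distance >= threshold_nt else PRODUCTIVE
    return NMDCall(
        isoform_id=iso_id,
        verdict=verdict,
        stop_mrna_pos=stop_pos,
        last_junction=last_junction,
        distance=distance,
    )


# ---------------------------------------------------------------------------
# NMD-inhibition stabilization comparison
# ---------------------------------------------------------------------------


def stabilization_report(
    abundances: pd.DataFrame,
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[StabilizationRecord]:
    """Compare per-isoform fractions between wild type and NMD-deficient.

    ``abundances`` needs columns gene_id, isoform_id, count_wt,
    count_nmd_deficient.  Isoforms absent from one condition count as zero
    there.  A pseudocount is added to every count before computing per-gene
    fractions; an isoform is stabilized when its fraction rises at least
    ``min_fold``-fold upon NMD inhibition.
    """
    required = {"gene_id", "isoform_id", "count_wt", "count_nmd_deficient"}
    if not required <= set(abundances.columns):
        raise InputError(f"abundance table must have columns {sorted(required)}")
    df = (
        abundances.groupby(["gene_id", "isoform_id"], as_index=False)[
            ["count_wt", "count_nmd_deficient"]
        ]
        .sum()
        .fillna(0)
    )
    records: list[StabilizationRecord] = []
    for gene_id, sub in df.groupby("gene_id"):
        wt = sub["count_wt"].to_numpy(float) + pseudocount
        nd = sub["count_nmd_deficient"].to_numpy(float) + pseudocount
        if wt.sum() <= 0 or nd.sum() <= 0:
            raise InputError(f"{gene_id}: zero total counts")
        f_wt = wt / wt.sum()
        f_nd = nd / nd.sum()
        for iso, fw, fn in zip(sub["isoform_id"], f_wt, f_nd):
            fold = fn / fw
            records.append(
                StabilizationRecord(
                    gene_id=gene_id,
                    isoform_id=iso,
                    fraction_wt=float(fw),
                    fraction_nmd_deficient=float(fn),
                    fold_change=float(fold),
                    stabilized=bool(fold >= min_fold),
                )
            )
    return records


# ---------------------------------------------------------------------------
# In-silico RT-PCR
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def virtual_rt_pcr(
    isoforms: Sequence[Isoform],
    genome: Mapping[str, str],
    fwd: str,
    rev: str,
) -> dict[str, int | None]:
    """Predict RT-PCR product lengths per isoform with exact-match primers.

    The forward primer must occur verbatim in the mRNA and the reverse
    primer in its reverse complement; a primer spanning an exon-exon
    junction therefore only amplifies isoforms that contain that junction.
    Returns product length per isoform id, or None when either primer has no
    site.  Multiple sites for one primer in one mRNA raise
    :class:`AmbiguousProductError`.
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise InputError("primers must be at least 15 nt")
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev.upper())
    out: dict[str, int | None] = {}
    for iso in isoforms:
        iso_id = iso.isoform_id or iso.parent
        mrna = spliced_sequence(genome, iso)
        f_sites = _find_all(mrna, fwd)
        r_sites = _find_all(mrna, rev_rc)
        if len(f_sites) > 1 or len(r_sites) > 1:
            raise AmbiguousProductError(f"multiple primer sites in {iso_id}")
        if not f_sites or not r_sites:
            out[iso_id] = None
            continue
        product = r_sites[0] + len(rev_rc) - f_sites[0]
        out[iso_id] = product if product >= max(len(fwd), len(rev)) else None
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def events_to_frame(events: Sequence[SpliceEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.gene_id, e.kind, e.host_intron,
                e.interval.chrom, e.interval.start, e.interval.end,
                e.interval.strand, e.support,
            )
            for e in events
        ],
        columns=[
            "gene_id", "kind", "host_intron",
            "chrom", "start", "end", "strand", "support",
        ],
    )


def nmd_calls_to_frame(calls: Sequence[NMDCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.isoform_id, c.verdict, c.stop_mrna_pos, c.last_junction, c.distance)
            for c in calls
        ],
        columns=["isoform_id", "verdict", "stop_mrna_pos", "last_junction", "distance"],
    )
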