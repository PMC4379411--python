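"""Intron positions as phylogenetic characters.

The position of an intron within the coding sequence — expressed as the index
of the codon it precedes or interrupts, plus its phase (0, 1 or 2 coding
nucleotides of that codon lying 5' of the intron) — is conserved far beyond
recognizable sequence similarity.  Projecting these positions through a
protein multiple alignment yields binary presence/absence characters shared
across a gene family, which this module builds and uses to classify genes
into subfamilies by their exon-boundary profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError, StructuralError
from .gene_models import GeneModel, GenomicInterval

CharacterKey = tuple[int, int]  # (alignment column, phase)


@dataclass(frozen=True)
class IntronSite:
    """Intron position in the coordinates of the encoded protein."""

    codon_index: int  # 0-based codon the intron precedes (phase 0) or interrupts
    phase: int
    intron_index: int  # ordinal of the intron within its gene, transcription order
    genomic: GenomicInterval


@dataclass(frozen=True)
class AnchoredSite:
    """An intron site projected onto a protein multiple alignment column."""

    gene_id: str
    column: int
    phase: int
    intron_index: int


@dataclass
class IntronCharacterMatrix:
    characters: list[CharacterKey]
    matrix: pd.DataFrame  # genes x characters, entries in {0, 1}
    low_confidence: set[CharacterKey]

    def profile(self, gene_id: str) -> set[CharacterKey]:
        row = self.matrix.loc[gene_id]
        return {key for key, v in zip(self.characters, row) if v}


def character_label(key: CharacterKey) -> str:
    return f"col{key[0]}_p{key[1]}"


# ---------------------------------------------------------------------------


def intron_sites(gene: GeneModel) -> tuple[list[IntronSite], int]:
    """Intron positions of a gene in protein coordinates.

    Returns the coding intron sites plus the number of introns that fall
    entirely within UTRs (excluded from the character matrix but still
    available to event calling through the gene model itself).

    The count of CDS nucleotides 5' of the intron determines the position:
    ``codon_index = cds_upstream // 3`` and ``phase = cds_upstream % 3``, so
    phase-1/2 introns are assigned to the codon they interrupt.
    """
    cds_lo, cds_hi = gene.cds_start, gene.cds_end
    cds_len = 0
    for e in gene.exons:
        cds_len += max(0, min(e.end, cds_hi) - max(e.start, cds_lo))
    if cds_len % 3 != 0:
        raise StructuralError(f"{gene.gene_id}: CDS length {cds_len} not divisible by 3")

    sites: list[IntronSite] = []
    n_utr = 0
    upstream = 0  # CDS nt 5' of the current intron
    introns = gene.introns
    for idx, exon in enumerate(gene.exons[:-1]):
        upstream += max(0, min(exon.end, cds_hi) - max(exon.start, cds_lo))
        if upstream == 0 or upstream == cds_len:
            n_utr += 1
            continue
        sites.append(
            IntronSite(
                codon_index=upstream // 3,
                phase=upstream % 3,
                intron_index=idx,
                genomic=introns[idx],
            )
        )
    return sites, n_utr


def anchor_sites(
    sites_by_gene: Mapping[str, Sequence[IntronSite]],
    msa: Mapping[str, str],
    proteins: Mapping[str, str] | None = None,
) -> tuple[list[AnchoredSite], int]:
    """Project intron sites through each gene's gap pattern onto MSA columns.

    ``proteins``, when given, are the (trimmed) sequences the MSA rows must
    match once gaps are removed.  Sites beyond the trimmed length are dropped;
    the count of dropped sites is returned alongside the anchored list.
    """
    anchored: list[AnchoredSite] = []
    n_dropped = 0
    for gene_id, sites in sites_by_gene.items():
        if gene_id not in msa:
            raise InputError(f"gene {gene_id!r} missing from alignment")
        row = msa[gene_id]
        columns = [i for i, ch in enumerate(row) if ch != "-"]
        if proteins is not None:
            ungapped = row.replace("-", "")
            if ungapped != proteins[gene_id]:
                raise InputError(
                    f"alignment row for {gene_id!r} does not match its protein"
                )
        for site in sites:
            if site.codon_index >= len(columns):
                n_dropped += 1
                continue
            anchored.append(
                AnchoredSite(
                    gene_id=gene_id,
                    column=columns[site.codon_index],
                    phase=site.phase,
                    intron_index=site.intron_index,
                )
            )
    return anchored, n_dropped


def build_character_matrix(
    anchored: Iterable[AnchoredSite],
    window: int = 0,
    max_gap_fraction: float = 0.5,
    msa: Mapping[str, str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> IntronCharacterMatrix:
    """Merge anchored sites into binary intron presence/absence characters.

    Sites sharing a phase whose columns lie within ``window`` of each other
    (single linkage) form one character keyed by the smallest member column.
    With the default ``window=0`` only exact column+phase matches merge.
    Characters sitting on mostly-gap columns (gap fraction above
    ``max_gap_fraction``, assessed when the MSA is supplied) are flagged
    low-confidence rather than removed.
    """
    anchored = list(anchored)
    by_phase: dict[int, list[int]] = {}
    for s in anchored:
        by_phase.setdefault(s.phase, []).append(s.column)

    # single-linkage chains of columns per phase
    column_to_key: dict[tuple[int, int], CharacterKey] = {}
    for phase, cols in by_phase.items():
        uniq = sorted(set(cols))
        cluster = [uniq[0]]
        for c in uniq[1:]:
            if c - cluster[-1] <= window:
                cluster.append(c)
            else:
                for member in cluster:
                    column_to_key[(member, phase)] = (cluster[0], phase)
                cluster = [c]
        for member in cluster:
            column_to_key[(member, phase)] = (cluster[0], phase)

    keys = sorted(set(column_to_key.values()))
    genes = sorted(
        set(gene_ids) if gene_ids is not None else {s.gene_id for s in anchored}
    )
    mat = pd.DataFrame(0, index=genes, columns=[character_label(k) for k in keys])
    for s in anchored:
        key = column_to_key[(s.column, s.phase)]
        mat.loc[s.gene_id, character_label(key)] = 1

    low_conf: set[CharacterKey] = set()
    if msa is not None:
        rows = list(msa.values())
        for col, phase in keys:
            gaps = sum(1 for r in rows if r[col] == "-")
            if gaps / len(rows) > max_gap_fraction:
                low_conf.add((col, phase))

    return IntronCharacterMatrix(characters=keys, matrix=mat, low_confidence=low_conf)


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def classify_subfamily(
    query: set[CharacterKey],
    references: Mapping[str, set[CharacterKey]],
) -> tuple[str, float]:
    """Label a gene by the reference exon-boundary profile it best matches.

    Similarity is the Jaccard index over shared characters; ties and all-zero
    similarity yield ``"unclassified"``.
    """
    if not references:
        raise InputError("no reference profiles supplied")
    if not query:
        return "unclassified", 0.0
    scores = {name: jaccard(query, ref) for name, ref in references.items()}
    best = max(scores.values())
    winners = [n for n, s in scores.items() if s == best]
    if best == 0.0 or len(winners) > 1:
        return "unclassified", best
    return winners[0], best


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def write_character_matrix(cm: IntronCharacterMatrix, path) -> None:
    cm.matrix.to_csv(path, sep="\t", index_label="gene_id")


def write_anchored_sites(anchored: Sequence[AnchoredSite], path) -> None:
    df = pd.DataFrame(
        [(a.gene_id, a.column, a.phase, a.intron_index) for a in anchored],
        columns=["gene_id", "column", "phase", "intron_index"],
    )
    df.to_csv(path, sep="\t", index=False)
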