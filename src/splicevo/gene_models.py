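"""Gene structures, transcripts and proteins: data model, I/O and sequence ops.

Coordinates are 0-based half-open everywhere inside the package.  GFF3 uses
1-based inclusive coordinates and the conversion happens only at the I/O
boundary; BED12 is already 0-based and is read natively.  All transcript-level
computation happens in mRNA (transcription-order) coordinates after strand
resolution, so minus-strand genes store their exons 5'->3' in transcription
order (descending genomic start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    ConfigurationError,
    InputError,
    NonStopWarning,
    RangeError,
    StructuralError,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named sequence, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StructuralError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise StructuralError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """Genomic exon/CDS structure of one gene in one species.

    ``exons`` are listed in transcription order (for minus-strand genes this
    is descending genomic coordinate).  ``cds_start``/``cds_end`` are genomic
    offsets delimiting the annotated coding region including the stop codon.
    """

    gene_id: str
    species: str
    locus: GenomicInterval
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    subfamily_label: str | None = None

    # -- derived helpers ----------------------------------------------------

    @property
    def strand(self) -> str:
        return self.locus.strand

    def exons_genomic_order(self) -> list[GenomicInterval]:
        return sorted(self.exons, key=lambda e: e.start)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Introns in transcription order (gaps between consecutive exons)."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                s, e = up.end, down.start
            else:
                s, e = down.end, up.start
            out.append(GenomicInterval(self.locus.chrom, s, e, self.strand))
        return out

    def cds_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.locus.chrom, self.cds_start, self.cds_end, self.strand
        )

    def validate(self) -> "GeneModel":
        exons = self.exons
        if not exons:
            raise StructuralError(f"{self.gene_id}: gene has no exons")
        for e in exons:
            if e.chrom != self.locus.chrom or e.strand != self.strand:
                raise StructuralError(f"{self.gene_id}: exon on wrong chrom/strand")
            if not self.locus.contains(e):
                raise StructuralError(f"{self.gene_id}: exon outside locus")
        genomic = self.exons_genomic_order()
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise StructuralError(f"{self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if exons != expected:
            raise StructuralError(
                f"{self.gene_id}: exons not in transcription order"
            )
        for i in self.introns:
            if i.length < 4:
                raise StructuralError(
                    f"{self.gene_id}: intron shorter than 4 nt at {i.start}"
                )
        if not (self.locus.start <= self.cds_start < self.cds_end <= self.locus.end):
            raise StructuralError(f"{self.gene_id}: CDS outside locus")
        # CDS must be covered by exons: every CDS position in some exon
        uncovered = self.cds_end - self.cds_start
        for e in genomic:
            lo = max(e.start, self.cds_start)
            hi = min(e.end, self.cds_end)
            if hi > lo:
                uncovered -= hi - lo
        introns_in_cds = [
            i for i in self.introns if self.cds_start < i.start and i.end <= self.cds_end
        ]
        if uncovered != sum(i.length for i in introns_in_cds):
            raise StructuralError(f"{self.gene_id}: CDS not contained in exons")
        return self


@dataclass
class Isoform:
    """A mature mRNA as an ordered chain of genomic blocks.

    ``blocks`` are in transcription order.  ``cds_offset`` is the mRNA
    coordinate of the start codon (``None`` when the start codon was removed
    by the generating splice event).
    """

    parent: str
    blocks: list[GenomicInterval]
    cds_offset: int | None
    polyA_truncated: bool = False
    isoform_id: str = ""

    @property
    def mrna_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def junctions(self) -> list[int]:
        return enumerate_junctions(self)

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    def validate(self) -> "Isoform":
        js = self.junctions
        if any(b <= a for a, b in zip(js, js[1:])):
            raise StructuralError("junctions not strictly increasing")
        if len(js) != len(self.blocks) - 1:
            raise StructuralError("junction count != block count - 1")
        if self.cds_offset is not None and self.cds_offset >= self.mrna_length - 2:
            raise StructuralError("cds_offset too close to mRNA end")
        return self

    # -- coordinate transforms ---------------------------------------------

    def genomic_to_mrna(self, pos: int) -> int | None:
        """Map a genomic position to its mRNA coordinate, or None if spliced out."""
        off = 0
        for b in self.blocks:
            if b.start <= pos < b.end:
                if self.strand == "+":
                    return off + (pos - b.start)
                return off + (b.end - 1 - pos)
            off += b.length
        return None

    def mrna_to_genomic(self, pos: int) -> int:
        if not 0 <= pos < self.mrna_length:
            raise RangeError(f"mRNA position {pos} out of range")
        off = 0
        for b in self.blocks:
            if pos < off + b.length:
                within = pos - off
                if self.strand == "+":
                    return b.start + within
                return b.end - 1 - within
            off += b.length
        raise AssertionError("unreachable")


@dataclass
class ProteinRecord:
    gene_id: str
    sequence: str
    trim_end: int | None = None

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise StructuralError(f"{self.gene_id}: internal stop in protein")
        if self.trim_end is not None and self.trim_end > len(self.sequence):
            raise ConfigurationError(
                f"{self.gene_id}: trim_end {self.trim_end} beyond protein length"
            )


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------


def spliced_sequence(genome: Mapping[str, str], isoform: Isoform) -> str:
    """Concatenate isoform blocks in transcription order (revcomp on minus)."""
    parts = []
    for b in isoform.blocks:
        try:
            chrom = genome[b.chrom]
        except KeyError as exc:
            raise RangeError(f"unknown sequence {b.chrom!r}") from exc
        if b.end > len(chrom):
            raise RangeError(
                f"block [{b.start},{b.end}) beyond end of {b.chrom} ({len(chrom)} nt)"
            )
        seg = chrom[b.start : b.end]
        parts.append(reverse_complement(seg) if b.strand == "-" else seg)
    return "".join(parts)


def translate(mrna: str, cds_offset: int = 0) -> str:
    """Translate with the standard genetic code, stopping at the first stop.

    The returned peptide excludes the stop symbol.  If no stop codon occurs
    before the end of the mRNA a :class:`NonStopWarning` is issued and the
    partial protein is returned.
    """
    if cds_offset + 3 > len(mrna):
        raise InputError("cds_offset leaves no room for a codon")
    coding_len = 3 * ((len(mrna) - cds_offset) // 3)
    coding = mrna[cds_offset : cds_offset + coding_len]
    aa = str(Seq(coding).translate())
    if "*" in aa:
        return aa[: aa.index("*")]
    warnings.warn("no stop codon before mRNA end", NonStopWarning, stacklevel=2)
    return aa


def first_stop_position(mrna: str, cds_offset: int) -> int | None:
    """mRNA coordinate of the first nt 3' of the first in-frame stop codon."""
    for i in range(cds_offset, len(mrna) - 2, 3):
        if mrna[i : i + 3] in ("TAA", "TAG", "TGA"):
            return i + 3
    return None


def enumerate_junctions(isoform: Isoform) -> list[int]:
    """mRNA coordinates where consecutive blocks meet (prefix sums)."""
    out, acc = [], 0
    for b in isoform.blocks[:-1]:
        acc += b.length
        out.append(acc)
    return out


def trim_proteins(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Truncate each protein at the supplied domain boundary (trim_end)."""
    out = []
    for rec in records:
        if rec.trim_end is None:
            raise ConfigurationError(f"{rec.gene_id}: trim_end not set")
        out.append(replace(rec, sequence=rec.sequence[: rec.trim_end]))
    return out


def productive_isoform(gene: GeneModel) -> Isoform:
    """The reference (all-exon) isoform of a gene model."""
    iso = Isoform(
        parent=gene.gene_id,
        blocks=list(gene.exons),
        cds_offset=None,
        isoform_id=f"{gene.gene_id}:productive",
    )
    cds_first = gene.cds_start if gene.strand == "+" else gene.cds_end - 1
    iso.cds_offset = iso.genomic_to_mrna(cds_first)
    return iso


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    Uses gffutils for parsing; converts 1-based inclusive coordinates to the
    package's 0-based half-open convention and returns minus-strand exon
    lists in transcription order.
    """
    import gffutils

    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##gff-version 3"):
        raise InputError(f"{path}: missing '##gff-version 3' directive")

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        strand = g.strand
        mrnas = list(db.children(g, featuretype="mRNA"))
        if len(mrnas) != 1:
            raise InputError(f"{g.id}: expected exactly one mRNA, got {len(mrnas)}")
        exons = [
            GenomicInterval(g.seqid, e.start - 1, e.end, strand)
            for e in db.children(mrnas[0], featuretype="exon", order_by="start")
        ]
        cds = [
            (c.start - 1, c.end)
            for c in db.children(mrnas[0], featuretype="CDS", order_by="start")
        ]
        if not cds:
            raise InputError(f"{g.id}: no CDS features")
        if strand == "-":
            exons = exons[::-1]
        model = GeneModel(
            gene_id=g.id,
            species=g.attributes.get("species", [""])[0],
            locus=GenomicInterval(g.seqid, g.start - 1, g.end, strand),
            exons=exons,
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
            subfamily_label=(g.attributes.get("subfamily", [None]) or [None])[0],
        )
        genes.append(model.validate())
    return genes


def write_gff(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3; round-trips losslessly through read_gff."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id};species={g.species}"
        if g.subfamily_label:
            attrs += f";subfamily={g.subfamily_label}"
        chrom, strand = g.locus.chrom, g.strand
        lines.append(
            "\t".join(
                [
                    chrom, "splicevo", "gene",
                    str(g.locus.start + 1), str(g.locus.end), ".", strand, ".",
                    attrs,
                ]
            )
        )
        mrna_id = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [
                    chrom, "splicevo", "mRNA",
                    str(g.locus.start + 1), str(g.locus.end), ".", strand, ".",
                    f"ID={mrna_id};Parent={g.gene_id}",
                ]
            )
        )
        for n, e in enumerate(g.exons_genomic_order(), 1):
            lines.append(
                "\t".join(
                    [
                        chrom, "splicevo", "exon",
                        str(e.start + 1), str(e.end), ".", strand, ".",
                        f"ID={mrna_id}.exon{n};Parent={mrna_id}",
                    ]
                )
            )
            lo = max(e.start, g.cds_start)
            hi = min(e.end, g.cds_end)
            if hi > lo:
                lines.append(
                    "\t".join(
                        [
                            chrom, "splicevo", "CDS",
                            str(lo + 1), str(hi), ".", strand, "0",
                            f"ID={mrna_id}.cds;Parent={mrna_id}",
                        ]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED12 (spliced EST alignments)
# ---------------------------------------------------------------------------


@dataclass
class Bed12Record:
    """One spliced alignment; blocks are genomic, ascending, half-open.

    A trailing ``;pA=1`` in the name marks a polyA-terminated read.
    """

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    blocks: list[tuple[int, int]] = field(default_factory=list)
    score: int = 0

    @property
    def polyA(self) -> bool:
        return ";pA=1" in self.name

    def to_line(self) -> str:
        sizes = ",".join(str(e - s) for s, e in self.blocks) + ","
        starts = ",".join(str(s - self.start) for s, _ in self.blocks) + ","
        return "\t".join(
            [
                self.chrom, str(self.start), str(self.end), self.name,
                str(self.score), self.strand, str(self.start), str(self.end),
                "0", str(len(self.blocks)), sizes, starts,
            ]
        )


def read_bed12(path) -> list[Bed12Record]:
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.split("\t")
            if len(f) < 12:
                raise InputError(f"{path}:{ln}: expected 12 BED fields")
            start = int(f[1])
            n = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n or len(offsets) != n:
                raise InputError(f"{path}:{ln}: block count mismatch")
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append(
                Bed12Record(
                    chrom=f[0], start=start, end=int(f[2]), name=f[3],
                    strand=f[5], blocks=blocks, score=int(f[4]),
                )
            )
    return out


def write_bed12(records: Iterable[Bed12Record], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_line() + "\n")
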