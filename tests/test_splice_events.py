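from __future__ import annotations

import pandas as pd
import pytest

from splicevo.errors import InputError
from splicevo.gene_models import (
    Bed12Record,
    GenomicInterval,
    Isoform,
    spliced_sequence,
)
from splicevo.splice_events import (
    ALT_POLYA,
    CASSETTE_EXON,
    INTRON_RETENTION,
    SpliceEvent,
    build_isoform,
    call_events,
    classify_nmd,
    stabilization_report,
    virtual_rt_pcr,
)
def _est(blocks, name="e", strand="+", chrom="chr1"):
    return Bed12Record(
        chrom=chrom, start=blocks[0][0], end=blocks[-1][1], name=name,
        strand=strand, blocks=list(blocks),
    )


class TestCallEvents:
    def test_cassette_exon_with_matching_flanks(self, three_exon_gene):
        est = _est([(50, 100), (130, 160), (200, 250)])
        events, skipped = call_events([est], three_exon_gene)
        assert skipped == 0
        (ev,) = events
        assert ev.kind == CASSETTE_EXON
        assert ev.host_intron == 0
        assert (ev.interval.start, ev.interval.end) == (130, 160)

    def test_cassette_requires_exact_flanking_junctions(self, three_exon_gene):
        # 5' flank lands 1 nt short of the donor edge: not a cassette call
        est = _est([(50, 99), (130, 160), (200, 250)])
        events, _ = call_events([est], three_exon_gene)
        assert events == []

    def test_intron_retention_with_overhang(self, three_exon_gene):
        est = _est([(50, 300)])
        events, _ = call_events([est], three_exon_gene, min_overhang=10)
        (ev,) = events
        assert ev.kind == INTRON_RETENTION and ev.host_intron == 0
        assert (ev.interval.start, ev.interval.end) == (100, 200)

    def test_retention_needs_min_overhang(self, three_exon_gene):
        est = _est([(95, 205)])
        events, _ = call_events([est], three_exon_gene, min_overhang=10)
        assert events == []
        events, _ = call_events([est], three_exon_gene, min_overhang=5)
        assert len(events) == 1

    def test_polya_terminus_inside_intron(self, three_exon_gene):
        est = _est([(50, 150)], name="e;pA=1")
        events, _ = call_events([est], three_exon_gene)
        (ev,) = events
        assert ev.kind == ALT_POLYA and ev.host_intron == 0
        assert (ev.interval.start, ev.interval.end) == (100, 150)

    def test_est_outside_locus_skipped_with_count(self, three_exon_gene):
        est = _est([(450, 600)])
        events, skipped = call_events([est], three_exon_gene)
        assert events == [] and skipped == 1

    def test_support_counts_deduplicate(self, three_exon_gene):
        ests = [_est([(50, 100), (130, 160), (200, 250)]) for _ in range(3)]
        (ev,), _ = call_events(ests, three_exon_gene)
        assert ev.support == 3


class TestBuildIsoform:
    def test_cassette_isoform_blocks_and_junctions(self, three_exon_gene):
        ev = SpliceEvent(CASSETTE_EXON, "G1", 0, GenomicInterval("chr1", 130, 160))
        iso = build_isoform(three_exon_gene, ev)
        assert [(b.start, b.end) for b in iso.blocks] == [
            (0, 100), (130, 160), (200, 300), (400, 500)
        ]
        assert iso.junctions == [100, 130, 230]

    def test_retention_fuses_flanking_exons(self, three_exon_gene):
        ev = SpliceEvent(INTRON_RETENTION, "G1", 0, GenomicInterval("chr1", 100, 200))
        iso = build_isoform(three_exon_gene, ev)
        assert [(b.start, b.end) for b in iso.blocks] == [(0, 300), (400, 500)]
        assert iso.junctions == [300]

    def test_polya_truncates_into_intron(self, three_exon_gene):
        ev = SpliceEvent(ALT_POLYA, "G1", 0, GenomicInterval("chr1", 100, 150))
        iso = build_isoform(three_exon_gene, ev)
        assert [(b.start, b.end) for b in iso.blocks] == [(0, 150)]
        assert iso.polyA_truncated and iso.junctions == []

    def test_event_gene_mismatch_rejected(self, three_exon_gene):
        ev = SpliceEvent(CASSETTE_EXON, "OTHER", 0, GenomicInterval("chr1", 130, 160))
        with pytest.raises(InputError):
            build_isoform(three_exon_gene, ev)

    def test_retention_sequence_is_productive_plus_intron(self, scenario_family):
        genome = scenario_family.genomes
        for isos in list(scenario_family.isoforms.values())[:4]:
            by_kind = {s.kind: s for s in isos}
            if INTRON_RETENTION not in by_kind:
                continue
            ri = by_kind[INTRON_RETENTION]
            prod = by_kind["productive"]
            gene = next(
                g for g in scenario_family.genes if g.gene_id == prod.gene_id
            )
            intron = gene.introns[ri.host_intron]
            intron_seq = genome[intron.chrom][intron.start : intron.end]
            if gene.strand == "-":
                from splicevo.gene_models import reverse_complement

                intron_seq = reverse_complement(intron_seq)
            prod_mrna = spliced_sequence(genome, prod.isoform)
            ri_mrna = spliced_sequence(genome, ri.isoform)
            j = prod.isoform.junctions[ri.host_intron]
            assert ri_mrna == prod_mrna[:j] + intron_seq + prod_mrna[j:]


class TestClassifyNmd:
    def test_rule_arithmetic_distance_above_threshold(self):
        # junctions [200, 450, 700]; stop ends at 600 -> distance 100
        mrna_parts = list("".join("CAA" for _ in range(334)))[:1000]
        mrna_parts[597:600] = list("TAA")
        genome = {"c": "".join(mrna_parts)}
        iso = Isoform(
            parent="g",
            blocks=[GenomicInterval("c", 0, 200), GenomicInterval("c", 200, 450),
                    GenomicInterval("c", 450, 700), GenomicInterval("c", 700, 1000)],
            cds_offset=0, isoform_id="g:x",
        )
        # blocks are adjacent here purely to control mRNA coordinates
        call = classify_nmd(iso, genome, threshold_nt=50)
        assert call.verdict == "NMD_TARGET"
        assert call.stop_mrna_pos == 600
        assert call.last_junction == 700
        assert call.distance == 100

    def test_rule_arithmetic_distance_below_threshold(self):
        mrna_parts = list("".join("CAA" for _ in range(334)))[:1000]
        mrna_parts[677:680] = list("TAA")
        genome = {"c": "".join(mrna_parts)}
        iso = Isoform(
            parent="g",
            blocks=[GenomicInterval("c", 0, 200), GenomicInterval("c", 200, 450),
                    GenomicInterval("c", 450, 700), GenomicInterval("c", 700, 1000)],
            cds_offset=2, isoform_id="g:x",
        )
        call = classify_nmd(iso, genome, threshold_nt=50)
        assert call.verdict == "PRODUCTIVE"
        assert call.stop_mrna_pos == 680 and call.distance == 20

    def test_polya_truncated_escape(self, scenario_family):
        genome = scenario_family.genomes
        gene_by_id = {g.gene_id: g for g in scenario_family.genes}
        seen = 0
        for isos in scenario_family.isoforms.values():
            for s in isos:
                if s.kind != ALT_POLYA:
                    continue
                call = classify_nmd(s.isoform, genome, gene=gene_by_id[s.gene_id])
                assert call.verdict == "ESCAPE_TRUNCATED"
                seen += 1
        assert seen > 0

    def test_no_start_when_event_removes_start_codon(self, three_exon_gene):
        ev = SpliceEvent(ALT_POLYA, "G1", 0, GenomicInterval("chr1", 100, 150))
        iso = build_isoform(three_exon_gene, ev)
        iso.cds_offset = None
        call = classify_nmd(iso, {"chr1": "A" * 500})
        assert call.verdict == "no_start"

    def test_monotonicity_in_threshold(self, scenario_family):
        """Raising the threshold never converts PRODUCTIVE to NMD_TARGET."""
        genome = scenario_family.genomes
        gene_by_id = {g.gene_id: g for g in scenario_family.genes}
        for isos in list(scenario_family.isoforms.values())[:6]:
            for s in isos:
                lo = classify_nmd(s.isoform, genome, gene=gene_by_id[s.gene_id],
                                  threshold_nt=25)
                hi = classify_nmd(s.isoform, genome, gene=gene_by_id[s.gene_id],
                                  threshold_nt=100)
                if lo.verdict == "PRODUCTIVE":
                    assert hi.verdict != "NMD_TARGET"


def test_stabilization_arithmetic_with_pseudocounts():
    df = pd.DataFrame(
        {
            "gene_id": ["g", "g"],
            "isoform_id": ["productive", "ptc"],
            "count_wt": [90, 10],
            "count_nmd_deficient": [50, 50],
        }
    )
    records = stabilization_report(df, min_fold=2.0)
    ptc = next(r for r in records if r.isoform_id == "ptc")
    assert ptc.fold_change == pytest.approx(4.81, abs=0.01)
    assert ptc.stabilized
    prod = next(r for r in records if r.isoform_id == "productive")
    assert not prod.stabilized


def test_stabilization_identical_fractions_not_stabilized():
    df = pd.DataFrame(
        {
            "gene_id": ["g", "g"],
            "isoform_id": ["a", "b"],
            "count_wt": [60, 40],
            "count_nmd_deficient": [60, 40],
        }
    )
    for r in stabilization_report(df):
        assert r.fold_change == pytest.approx(1.0)
        assert not r.stabilized


class TestVirtualRtPcr:
    def test_two_band_logic_on_fungal_like_locus(self, scenario_family):
        """Primers flanking the retained intron give two products differing by
        the intron length; a junction-spanning reverse primer loses the
        retained-intron band."""
        genome = scenario_family.genomes
        isos = scenario_family.isoforms["neurospora_g"]
        by_kind = {s.kind: s for s in isos}
        prod = by_kind["productive"].isoform
        ri = by_kind[INTRON_RETENTION]
        gene = next(g for g in scenario_family.genes if g.gene_id == "neurospora_g")
        intron_len = gene.introns[ri.host_intron].length

        mrna = spliced_sequence(genome, prod)
        junctions = prod.junctions
        h = ri.host_intron
        from splicevo.gene_models import reverse_complement

        fwd = mrna[junctions[1] + 5 : junctions[1] + 25]  # inside exon 3
        rev_flank = reverse_complement(mrna[junctions[h] + 10 : junctions[h] + 30])
        rev_span = reverse_complement(mrna[junctions[h] - 10 : junctions[h] + 10])

        products = virtual_rt_pcr([prod, ri.isoform], genome, fwd, rev_flank)
        assert products[prod.isoform_id] is not None
        assert products[ri.isoform_id] is not None
        assert products[ri.isoform_id] - products[prod.isoform_id] == intron_len

        spanning = virtual_rt_pcr([prod, ri.isoform], genome, fwd, rev_span)
        assert spanning[prod.isoform_id] is not None
        assert spanning[ri.isoform_id] is None

    def test_absent_primer_gives_no_product(self, scenario_family):
        genome = scenario_family.genomes
        prod = scenario_family.isoforms["neurospora_g"][0].isoform
        mrna = spliced_sequence(genome, prod)
        fwd = mrna[10:30]
        products = virtual_rt_pcr([prod], genome, fwd, "T" * 20)
        assert products[prod.isoform_id] is None

    def test_short_primer_rejected(self, scenario_family):
        prod = scenario_family.isoforms["neurospora_g"][0].isoform
        with pytest.raises(InputError):
            virtual_rt_pcr([prod], scenario_family.genomes, "ACGTACGTAC", "A" * 20)
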