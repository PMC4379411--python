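# splicevo

Comparative-genomics toolkit for studying the evolution of **unproductive
splicing** — alternative splicing that produces mRNAs destroyed by
nonsense-mediated decay (NMD) instead of protein — across a duplicating gene
family, exemplified by the SR splicing-factor subfamily SRSF4/SRSF5/SRSF6.
It is written for molecular evolutionists who want to ask: did the poison
cassette exons and NMD-inducing retained introns seen in today's paralogs
descend from one ancestral event, arise independently, or replace one
another as the family duplicated?

## What it does

- **Intron positions as phylogenetic characters.** Each intron is encoded by
  the codon it interrupts and its phase (`codon_index = cds_nt_upstream // 3`,
  `phase = cds_nt_upstream mod 3`), projected through a protein multiple
  alignment into binary presence/absence characters shared across the
  family. Genes are assigned to subfamilies by Jaccard similarity of their
  exon-boundary profiles.
- **Event calling from spliced EST alignments** (BED12) against reference
  gene models: cassette exons strictly inside a reference intron with exact
  flanking junctions, full intron retention with a minimum exonic overhang,
  and early polyadenylation inside an intron.
- **NMD classification by the 50-nt junction rule**: a transcript is an NMD
  target iff its stop codon lies ≥ `threshold_nt` (default 50) upstream of
  the last exon–exon junction; transcripts whose stop falls in the last
  exon, or that are polyA-truncated, escape. The threshold is configurable
  because NMD mechanics differ between clades.
- **Gain/loss histories under Dollo parsimony** (one gain, any number of
  losses) for each event homology group, and a family-level verdict:
  `SINGLE_ORIGIN`, `INDEPENDENT`, or `REPLACEMENT` (a new group gained on a
  branch where an ancestral group was lost). An unrestricted Fitch cost is
  reported alongside; groups where it beats the Dollo history are flagged
  ambiguous.
- **Ultraconservation scanning**: maximal runs of perfect identity
  (default ≥ 200 nt, gaps break runs), smoothed per-column identity
  profiles, and intron-length percentiles ("is the retained intron in the
  longest 1% for its genome?").
- **A gene-family simulator with ground truth**: an ancestral 8-exon gene
  evolved down a 12-species animal+fungus tree with two nested duplications,
  nucleotide substitution (rejecting premature stops in the productive
  frame), intron gain/loss, poison-exon birth/death/replacement, EST
  sampling, and NMD-dependent transcript abundances in wild-type versus
  NMD-deficient conditions. Every inference stage is scored against the
  emitted truth tables.
- **In-silico RT-PCR**: exact-match primers on isoform mRNAs, including
  junction-spanning primers that only amplify spliced isoforms.

## Worked example

The bundled scenario re-creates an SRSF-like history: an ancestral poison
exon in intron 5 conserved from fungi to vertebrates (fungi keep only the
exon-less retained intron), lost together with the whole ancestral intron
set when the chordate duplicate restructured, and replaced by a new poison
exon in the new second intron — plus a mammal-only third event in the first
intron of the SRSF4-like copy.

```bash
splicevo run --seed 7 --out demo/
```

```
origin model verdict: REPLACEMENT
report: demo/report.json
```

Inside `demo/report.json` (seed 7):

- `n_genes: 23`, `n_characters: 10` — 23 genes across 12 species carry ten
  distinct intron-position characters (seven ancestral, three
  post-duplication).
- `event_counts: {INTRON_RETENTION: 24, ALT_POLYA: 22, CASSETTE_EXON: 22}`
  and `nmd_verdict_counts: {NMD_TARGET: 46, ESCAPE_TRUNCATED: 22}` — every
  cassette-inclusion and retention isoform is an NMD target; the
  polyA-truncated isoforms escape.
- `origin.verdict: REPLACEMENT`, with the ancestral group (character
  `col150_p0`, the intron-5 position) linked to the new group (`col100_p0`,
  the new second intron) on the branch subtending all `*_g.2*` genes — the
  post-duplication branch.
- `conservation.perfect_runs`: 241-nt perfect-identity runs across 10
  sequences for both the ancestral and the replacement poison exon — the
  ultraconserved-element signature.
- the fungal host intron spans 120 nt with `top_fraction 0.143`: the single
  longest of that genome's seven introns.
- `metrics`: subfamily accuracy, intron-site precision/recall, event
  precision/recall, NMD accuracy and verdict correctness are all `1.0`
  against the simulator truth on this noise-free run.

The same stages run from files you supply (`inputs:` section in the YAML
config: genome FASTA, GFF3 gene models, aligned protein FASTA, BED12 ESTs,
abundance TSV, newick tree) — see `splicevo run --help` and
`src/splicevo/data/srsf_scenario.yaml` for the config shape.

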