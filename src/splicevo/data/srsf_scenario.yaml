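# SR-like family scenario: a deep SRSF5-like gene whose ancestral poison
# cassette exon (in intron 5, group P1) persists throughout animals, with
# exon-less alternative retention of the same intron in fungi.  The chordate
# duplication produces a paralog (lineage g.2) whose gene structure is
# rebuilt — all ancestral introns lost, three new introns gained — so the
# ancestral unproductive splicing necessarily dies on that branch, and a new
# poison exon (P2) is born in the new second intron: a replacement.  A third,
# mammal-only poison exon (P3) later appears in the first intron of the
# SRSF4-like copy (lineage g.2.2).
simulate:
  seed: 0
  regime: REPLACEMENT
  placed_events:
    - {node: fungi, lineage: g, kind: exon_loss, intron: I5}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I1}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I2}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I3}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I4}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I5}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I6}
    - {node: chordates, lineage: g.2, kind: intron_loss, intron: I7}
    - {node: chordates, lineage: g.2, kind: intron_gain, intron: J1, codon: 40}
    - {node: chordates, lineage: g.2, kind: intron_gain, intron: J2, codon: 100}
    - {node: chordates, lineage: g.2, kind: intron_gain, intron: J3, codon: 170}
    - {node: chordates, lineage: g.2, kind: poison_birth, intron: J2, group: P2}
    - {node: mammals, lineage: g.2.2, kind: poison_birth, intron: J1, group: P3}

params:
  nmd_threshold: 50
  min_len: 200

tree: truth
outgroup: neurospora_g
subfamily_references:
  SRSF5-like: neurospora_g
  SRSF46-like: human_g.2.1
score_truth: true
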