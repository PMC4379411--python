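# Methods

## The inference model

The package treats the position of an intron within a coding sequence as a
heritable character. An intron's position is `(codon_index, phase)` where
`cds_upstream` is the number of coding nucleotides 5' of the intron,
`codon_index = cds_upstream // 3` and `phase = cds_upstream mod 3`; phase-1
and phase-2 introns are assigned to the codon they interrupt, which makes
the simulator round trip exact. Positions are projected through each gene's
gap pattern onto protein-alignment columns and merged into binary characters
when they share a phase and sit within `window` columns of each other
(single linkage, default `window = 0`, i.e. exact column+phase identity —
the strictest reading of "conserved exon boundary"; a positive window is
available for noisy alignments). Characters on columns that are mostly gaps
(fraction > `max_gap_fraction`, default 0.5) are flagged low-confidence
rather than dropped, since a column with little residue support cannot
anchor a homology claim.

Unproductive-splicing events called from spliced alignments are grouped into
homology groups by the character of their **host intron**: a cassette exon
in one species and a retained intron in another, sitting in the same
ancestral intron position, belong to one group. This is what lets an
exon-less fungal retained intron and a metazoan poison cassette exon count
as the same ancestral event.

Each group's history is reconstructed under **Dollo parsimony** on a rooted
gene tree: the gain is placed on the branch above the most recent common
ancestor of all carriers, and the losses are the maximal carrier-free
subtrees inside that clade. This is the unique minimum-loss single-gain
history on a binary tree (placing the gain any higher forces at least one
extra loss in a sister subtree). An unrestricted Fitch cost is computed for
comparison; when `fitch_cost < 1 + losses`, independent gains would be
cheaper than the single-gain story and the group is flagged in
`ambiguous_groups` instead of silently asserting uniqueness.

The family verdict follows from pairwise linkage: `REPLACEMENT` when some
group's gain branch lies on or below a branch where another group was lost
(`linkage: strict`; `linkage: clade` relaxes to the enclosing clade for
trees with weakly resolved branches), `SINGLE_ORIGIN` for exactly one group,
otherwise `INDEPENDENT`.

## NMD rule

A transcript is classified from its own sequence: translation starts at the
reference start codon mapped into the isoform, the first in-frame stop is
located, and the distance from the first nucleotide 3' of the stop to the
last exon–exon junction decides the verdict. `NMD_TARGET` requires distance
≥ `nmd_threshold` (default 50 nt, the metazoan junction rule) *and* a
downstream junction; a stop in the last exon escapes (`ESCAPE_LAST_EXON`,
or `ESCAPE_TRUNCATED` for polyA-truncated transcripts); a stop at the
annotated reference position is always `PRODUCTIVE`. The threshold is a
config knob because the NMD machinery itself differs across the clades this
method spans; the rule is monotone in the threshold by construction.

## Event calling conventions

All calls require exact junction agreement with the reference model:
a cassette exon is an alignment block strictly inside a reference intron
whose neighbouring blocks end/begin exactly at the intron's donor and
acceptor edges; intron retention is a single block covering the whole intron
with ≥ `min_overhang` (default 10 nt) aligned on each flanking exon, which
guards against spurious 1-nt overlaps; early polyadenylation requires a
polyA-flagged read ending strictly inside an intron. Alternative 5'/3'
splice sites are out of scope. Events deduplicate to (kind, host intron,
interval) with support counts.

Stabilization analysis compares per-isoform fractions of per-gene totals
between wild-type and NMD-deficient conditions with a 0.5 pseudocount on
every count (avoiding division by zero for condition-absent isoforms); an
isoform is *stabilized* at fold ≥ `min_fold` (default 2). Under thinning
with efficiency *e*, the expected fold of a target whose class holds weight
*w* of the gene's transcripts is `(1 − e·w)/(1 − e)` — about 3.2 at the
default e = 0.8, comfortably above the threshold.

## Trees

External newick trees are first-class inputs (the tree program is not this
package's contribution). The built-in fallback is p-distance (mismatch
fraction over mutually ungapped columns) plus neighbor joining with a
deterministic tie-break (smallest row-index pair) and negative branch
lengths clamped to zero with a warning. Column-resampling bootstrap support
uses seed + r for replicate r, so replicates are reproducible independently
of execution order. Rooting is by a declared outgroup; unrooted trees
without an outgroup are an error for history inference.

## The simulator: what it emulates, and what it does not

The generator's defaults *are* the study conditions. A 240-residue ancestral
gene with eight exons (introns at codons 25–210 in varied phases) evolves
down a 12-species opisthokont-like tree — a two-species fungal outgroup and
ten animals — with a duplication at the chordate node and a second
duplication of the derived copy at the vertebrate node, yielding 23 genes.
Rates per unit branch length: substitutions 0.05/site (≈15% divergence
between the most distant genomes), intron gain and loss 0.02 each (order-of-
magnitude choices; no quantitative turnover rates exist to calibrate
against, and the values are documented as choices, not estimates). Intron
lengths are log-normal(μ = 4.0, σ = 0.6 in ln-nt, ≈55 nt median, floor
20 nt), matching compact fungal-like introns; the ancestral host intron is
built long (80 nt 5' part + 241 nt poison exon + 40 nt 3' part) so it lands
at the top of its genome's length distribution and exercises the percentile
report. Poison exons are 241 nt (3k+1) with an in-frame stop near their 5'
end and are mutation-protected by default (`poison_conserved`), emulating
the extreme constraint observed on such exons and giving the
perfect-identity scanner a true ≥200-nt target. Every intron carries an
embedded in-frame stop just after its donor so retention reliably produces
a premature stop. Isoform truth verdicts are computed analytically from the
assembled transcript at realization time, not by calling the classifier.

Expression: per gene, raw isoform weights are 1 (productive) plus, per
alternative intron, 0.3 inclusion / 0.15 retention / 0.05 polyA, normalized
to sum to one; wild-type samples thin NMD-target isoforms by
`nmd_efficiency` (default 0.8) and renormalize. ESTs (default 150 per gene,
800 nt) cover uniform windows of their isoform; reads from polyA-truncated
isoforms are anchored at the transcript 3' end, as oligo-dT priming
dictates, and carry a `;pA=1` flag. Genes alternate strands along each
species' chromosome so minus-strand code paths are always exercised.

Because evolution is substitution-only (no coding indels), all family
proteins stay equal length and the emitted "alignment" is the identity
stacking of sequences — so alignment error contributes nothing here, and
passing round-trip tests demonstrate coordinate bookkeeping, not robustness
to misalignment. Likewise the simulator does not model EST alignment noise,
sequencing error, paralog cross-mapping, or codon-level substitution
realism; results on real data will additionally depend on those factors.
The simulated gene tree is emitted and used for history inference by
default (`tree: truth`), standing in for the externally built
maximum-likelihood tree a real analysis would supply; `tree: nj` exercises
the built-in route.

Regime scenarios for origin-model validation place events explicitly rather
than waiting for rare rate-driven draws: `SINGLE_ORIGIN` keeps the ancestral
exon everywhere; `INDEPENDENT` drops it and places two births on random
disjoint clades *in different host introns* — two births at the same
homologous position are, by construction of the position-homology method,
indistinguishable from a single origin, which is precisely the method's
known blind spot; `REPLACEMENT` couples a death and a birth on one random
branch drawn from non-root-child branches, because a loss that prunes an
entire root-adjacent clade leaves no Dollo-visible trace (the gain simply
reconstructs lower). Both constraints are properties of the inference
problem, not conveniences.

## Numerical and I/O choices

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
converts only at the I/O boundary; BED12 reads natively. Minus-strand genes
keep exon lists in transcription order. The standard genetic code only.
Identity profiles count gaps (including gap–gap) as disagreement; smoothing
is a centered moving average truncated at the edges, window 25 columns,
purely presentational. Percentiles: `percentile` is the fraction strictly
shorter, `top_fraction` the fraction at least as long; "in the longest q"
iff `top_fraction ≤ q`. Primer matching in the in-silico RT-PCR is exact
(no mismatches): desk-scale determinism beats thermodynamic realism here.
All randomness flows from explicit seeds through `numpy` generators;
repeated runs are byte-identical, and the pipeline skips unchanged stages
via content hashes in `manifest.json` (timestamps exist only in the log).

## Problem sizes

The validation suite uses 1,000 random isoforms for the NMD oracle, 1,000
tree/character pairs (trees of 4–10 leaves) against exhaustive Dollo
enumeration, 500 random alignments for the conservation oracles, 50
replicates per generating regime for origin-model recovery, 500 ESTs per
gene for event-calling recovery, and 20 resampled abundance replicates for
stabilization — sizes at which every stochastic check is stable while the
whole suite stays interactive (~30 s).

## Known limitations

Intron sliding (coordinated small boundary shifts) is not modelled or
detected; `window > 0` merges nearby positions but cannot distinguish
sliding from coincidence. Gene-tree/species-tree reconciliation is out of
scope: the gene tree is an input. The replacement verdict depends on loss
visibility (see above); histories whose equal-cost alternatives involve
multiple independent gains are flagged, not resolved. Subfamily
classification needs user-named reference genes; it makes no attempt to
discover subfamilies de novo.
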