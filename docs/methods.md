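# Methods

`diphase` reconstructs both haplotypes of a diploid genome independently
from accurate short reads, rather than building a consensus and splitting
it afterwards.  This note records the model, the parameters that matter,
the numerical choices, and what the synthetic data do and do not probe.

## Assembly model

**Contig assembly.** Reads are decomposed into canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement).  Occurrences
below a coverage cutoff are discarded; the cutoff is half the leftmost
local minimum of the unsmoothed occurrence histogram, scanned from
occurrence 2 upward with ties resolved to the smaller occurrence.  A candidate
minimum must also lie at or below the occurrence-1 count: the rule exists
to separate an error peak (which towers at occurrence 1) from the
coverage peak, and with error-free reads — where no error peak exists — a
sampling-noise dip inside the signal would otherwise masquerade as the
valley and wipe out heterozygous k-mers.  Halving
the classical cutoff, and never removing bubbles, protects heterozygous
k-mers, which run at half the homozygous depth.  Maximal non-branching
k-mer paths become *straight nodes* (contigs) and branching k-mers become
*junction nodes*; adjacent nodes overlap by exactly k−1 bases.  The graph
is rebuilt at increasing k (default 32, step 20) so that repeats and close
het sites resolve progressively; at each raise the previous contigs'
k-mers are retained even below the cutoff, and the cutoff is rescaled by
the k-mer sampling ratio (L−k+1)/(L−k₀+1) for read length L — the
local-minimum scan is meaningful only on the initial histogram, where the
error peak lives.  The default final k is L/2: each k-mer position is then
still sampled by about half the reads, so heterozygous paths (at half
depth again) stay connected.  Pushing k toward L starves them and
fragments the graph.

**Anchor bubbles and c_hetero.** In the initial graph, a *simple bubble*
is two straight nodes between two junctions.  Most simple bubbles are
allele pairs, so the length-weighted mean coverage of their branches,
`c_hetero`, estimates the per-haplotype depth of unique sequence.  Bubbles
whose branches both stay below `r_upper_threshold × c_hetero` (default
1.75) are *anchor bubbles*: later stages use them to recognise homologous
scaffolds.  The factor 1.75 sits between the heterozygous (1×) and the
collapsed-repeat (≥2×) depth bands.

**Cross-structure untangling.** A collapsed homozygous segment between
heterozygous flanks appears as a *cross*: a centre node whose two sides
each fan out into two externals.  Candidate crosses must satisfy
`cov(centre) ≤ 2 r c_hetero` and `min(cov(externals)) ≤ r c_hetero`
(repeat guard).  The two pairings of externals (parallel vs cross) are
scored by (1) read-pair / single-read link counts, (2) summed long-read
match sites, and (3) reads shared per barcode between externals
(linked reads; skipped when the centre exceeds 200 kbp, beyond a linked
fragment's reach).  A pairing wins iff its score is at least
`max(1, 4 × alternative)` — the floor of 1 means zero evidence never
phases.  Winning crosses duplicate the centre (each copy inherits half its
coverage) into the two haplotype paths; the graph is recompressed and the
procedure iterates (≤5 rounds, stopping at a round with no untangle).
Methods that agree merge; methods that conflict leave the cross alone.
Seed mapping is exact and genome-wide unique at lengths 32/64/96
(shortest first, seeds tiling the read): because homologous branches share
their k−1 flanks, only het-covering seeds are unique, so placements on
branch nodes are intrinsically haplotype-specific — exactly the evidence
untangling needs.  Pair links whose mate sits further from the node end
than 1.5× the insert are geometrically impossible and dropped.

**Scaffolding.** Link evidence is bundled per oriented node end (gap =
median of per-link estimates from `insert − d₁ − d₂`; insert sizes are
re-estimated from same-node pairs).  Bundles need `min_link_threshold`
(default 2) links; a bundle whose target lies beyond a nearer neighbour,
within a slack of `min(500, len/2)` bp, is transitively reduced.  Ends
whose single surviving bundle is reciprocal are chained; negative gaps
attempt an exact overlap merge (probing ±60 bp around the estimate, which
also restores the k−2 overlap across dropped junction k-mers), otherwise
`max(gap, 1)` Ns keep the join visible.  Nodes shorter than the largest
library insert are excluded from the scaffold graph — they are mostly
unduplicated homozygous leftovers — *unless* they contain an anchor
bubble, which marks them as heterozygous and worth keeping.  Cross
structures in the scaffold graph (link-bundle edges instead of overlaps)
untangle under the same 4× rule.

**Haplotype synteny-based correction.** Each node is an ordered list of
contigs (N-free stretches) with lengths l_i; every anchor bubble found in
a node votes the scaffold-ID of its counterpart's node onto its contig
(b_i; majority per contig, ties to the smaller ID).  The dominant
counterpart B_max maximises the summed length of agreeing contigs (ties
to the smaller ID).  The retained range starts as the first/last contig
voting B_max and is tightened by a division score walked across the
range: carry on anchor-free contigs, −l on B_max contigs, +l on contigs
voting elsewhere, base 0 before the range.  A positive maximum relocates
the boundary to its argmax (ties to the smaller index; the far boundary
uses the mirrored walk over the already-tightened range).  The corrected
boundary contig is kept inclusively even when it is not itself a B_max
anchor.  Nodes are additionally divided at internal contigs whose
counterparts are edge contigs of other nodes (a mis-join signature), and
the whole correction iterates until a round divides nothing.

**Gap closing and output.** Reads map back onto the blocks by unique seed
hits only — sequence present in both haplotype blocks is ambiguous and
contributes nothing, so phase is preserved.  Pairs whose placement falls
within one insert of a gap are pooled; the N run is replaced iff a local
de Bruijn walk (k = final k/2, path bounded at 10× the gap estimate)
connects the two flank anchors through unique successors.  The
untangle–scaffold–correct–close loop runs twice by default.  Finally,
nodes with reciprocal dominant counterparts are paired into bubbles
("megabubble" output): the member with more non-N bases is the primary
(ties to the smaller scaffold-ID); everything else is non-bubble.
Optional consensus scaffolds concatenate primary bubbles and non-bubble
sequences through exact (k−1) end overlaps that are unique on both sides;
secondary bubbles are excluded.

## Evaluation statistics

* **NG50 / LG50** — largest length L such that sequences ≥ L sum to more
  than half the genome size, and their count; sequences under 500 bp are
  excluded first, and contig statistics re-run after splitting at N runs.
  An assembly that never passes half the genome reports NG50 = 0 with a
  flag.
* **Heterozygous 1k-mer pairs** — the unit of phasing evaluation: the
  trusted source set (haplotype chunks or synthetic long contigs,
  optionally quality-masked at Q ≤ 40) is aligned all-vs-all (minimap2,
  `-c -k19 -p0 -X --cs=long`); near-exact alignments (edit distance ≤ N
  bases in the aligned regions — self or same-haplotype hits) are
  discarded, the best remaining hit per sequence is filtered at identity
  ≥ 0.8 and length ≥ 500 and cut into blocks in which the shorter side
  carries 1000 bases.  Blocks with N or without a difference are dropped.
  The confirmation step requires `min_exact_matches` exact occurrences of
  both sides in the source set; the default 2 presumes a redundant contig
  set, so evaluations against exactly two truth haplotypes pass 1 (each
  locus occurs once per haplotype there).
* **Recall / precision / F** — fraction of truth fragments (fixed length,
  from position 0, N and trailing partials dropped) occurring verbatim in
  the blocks, and vice versa; matching is strand-symmetric everywhere.
* **Phased pair rate** — a pair is phased iff both sides occur exactly in
  the blocks, bubble-phased iff they land in the two members of one
  bubble pair; rates are also windowed on source coordinates.
* **Reference-absent bubbles** — 1-kbp fragments of each bubble pair are
  aligned to the reference (minimap2 `-c -k19 -p1`); fragments with best
  alignment < 500 bp or identity < 0.9 are reference-unaligned and count
  only when exactly present in the truth set (ruling out mis-assembly);
  bubbles ≥ 100 kbp with a confirmed-unaligned rate ≥ 0.25 are reported.
* **Switch errors** — this package's formalisation: consecutive block
  fragments are assigned a haplotype of origin by exact (or best
  semi-global) match; fragments matching both haplotypes are homozygous
  and uninformative.  Between adjacent assigned fragments, truth
  positions must advance collinearly by the fragment spacing (slack =
  one fragment length): a haplotype flip at collinear coordinates is a
  switch error, any collinearity violation (order, orientation, distance)
  is a mis-assembly.

## Synthetic data

The generator emulates the benchmark design: haplotype A is i.i.d.
uniform sequence (optionally with planted repeats), haplotype B derives
from it by Bernoulli per-base SNVs at the background rate (0.1–5%
supported), geometric indels (mean 3 bp), and highly divergent regions
with their own divergence and an optional inversion; every variant is
recorded, and the truth table reconstructs B from A exactly.  Libraries:
inward paired-end, outward mate-pair, barcoded linked reads (BX:Z: tags),
and long reads with i.i.d. substitution/insertion/deletion errors.
Fragments alternate between haplotypes; everything is deterministic under
a seed.

The standard scenario (`benchmark_scenario`) is a 200-kbp diploid at 1%
heterozygosity with one inverted 10-kbp HDR at 5% divergence, error-free
40× paired-end (250-bp reads, insert 400 ± 40) plus 40× mate-pair (100-bp
reads, insert 3000 ± 300).  250-bp reads are the deliberate choice for
the short library: with read length L and insert I, a read pair jointly
covers het-site spacings from 0 (single read) up to I only when 2L ≳ I;
shorter reads leave a spacing window that no evidence class covers and
that is an artefact of library design, not of the method.  Replicate
counts (5 seeds in the test suite, 3 in the acceptance script) and the
200-kbp genome keep a full run around a minute while leaving ~2000 het
sites and ~1400 anchor bubbles per run.

What the simulations do **not** emulate: sequencing errors in the short
libraries during acceptance runs (error rates are supported and exercised
in unit tests, but the benchmark is error-free), instrument-specific error
profiles, PCR/amplification bias, mate-pair chimeras (available behind a
flag, off by default), and genomes with realistic repeat landscapes.
Passing the benchmark therefore demonstrates the graph algorithms —
untangling, synteny correction, pairing — under clean evidence, not
robustness to raw-instrument noise.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; N is a hard break for all
  k-mer extraction.
* k-mer identity inside graph construction uses a 64-bit polynomial
  rolling hash; with < 2³¹ distinct k-mers the collision probability is
  negligible, and the unique-counting path compares full rows at group
  boundaries so distinct k-mers are never merged.
* Seed placement picks the leftmost matching seed; a read whose seeds are
  all absent (not merely duplicated) at one length can never match at a
  longer length and stops escalating.
* Untangling applies non-overlapping crosses per round (first by centre
  ID) and recompresses between rounds; evidence precedence follows the
  spec of the decision rule — agreement merges, conflict abstains.
* Division ties: Eq-style argmaxes resolve to the smaller ID / smaller
  index for deterministic output; scaffold chains keep the ID of their
  largest member.
* Gap rendering: `max(gap, 1)` Ns, so every link-based join is visible in
  FASTA; exact-overlap merges are attempted for negative gaps only.
* The local-assembly walk refuses to close a gap at the first branch —
  a conservative rule that leaves repeat-internal gaps open rather than
  risking a chimera.
* Library processing order is ascending insert size, then all libraries
  together, in every untangling phase (visible in the logs).

## Known limitations

* Polyploid (>2) phasing is out of scope; so are reference-guided
  scaffolding and optical maps.
* The scaffold-graph cross detector requires the exact 2+2 shape; nested
  tangles resolve only through iteration, if at all.
* Long reads contribute links and match-site scores but there is no
  long-read-only assembly path; the method is short-read-first by design.
* Switch-error counting is this package's own formalisation of a
  one-line description; its collinearity slack is configurable and its
  absolute counts should be compared only within this package.
* At heterozygosity ≪ 0.1% almost no anchor bubbles form and the
  pipeline degrades gracefully to an unphased assembler (synteny
  correction disables itself with a warning).
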