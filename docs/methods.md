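# Methods

This note documents the models, algorithms and parameter choices behind
mitostruct, what the synthetic-data generator does and does not emulate,
and the numerical conventions that make results reproducible.

## Recombination model

A plant mitogenome is modelled as a set of autonomous circular molecules.
Homologous recombination between two copies of a large repeat on the same
circle is treated as a single crossover:

* **Direct pair** (copies in the same orientation, starts *d* apart on a
  circle of length *L*): the circle resolves into two sub-genomic circles
  of lengths *d* and *L − d*. Each child carries exactly one full repeat
  copy, so the lengths sum to the parent length exactly — an invariant the
  test suite asserts over random placements.
* **Inverted pair**: a "flip-flop" event that reverse-complements the
  segment between the two crossover points, yielding one isoform of
  unchanged length. Applying the operation twice returns the parent (as a
  canonical circle), which is asserted as an involution property.

Only single-crossover products are enumerated. Recombination at large
repeats is recurrent and reversible, and observed sub-genomic circles are
single-event products; chained products of products would multiply the
hypothesis space without read evidence to constrain it. No master-circle
reconstruction is attempted. Repeat copies are treated as identical for
product construction even when a divergence knob planted differences; the
junction flanks always come from the product sequence itself, because read
support is measured on the product, not an idealised repeat.

Crossover breakpoints are placed at the repeat-copy midpoint: for
identical copies every crossover position inside the repeat yields the
same product sequence, so the midpoint is a canonical representative.

**Canonical circular form.** Circular sequences are deduplicated and
compared as the lexicographically minimal rotation of whichever of
(sequence, reverse complement) is smaller under rotation (Booth's
algorithm). This makes product sets independent of rotation, strand, and
which repeat copy is labelled A or B.

## Repeat detection

`find_repeats` is seed-and-extend self-comparison: exact 21-mer seeds on
the doubled sequence (so repeats spanning the origin are contiguous), both
strands (inverted matches are found against the reverse complement),
greedy merging of co-diagonal seeds with gaps up to `max_gap` (default
100 bp), exact tip extension, and deduplication of doubled-sequence images
modulo the length. Identity is computed as matching columns over the
gap-free run (substitution-only model; the repeat families of interest
recombine homologously and are near-identical, hence `min_identity`
defaults to 0.98 and `min_len` to 1,000 bp — the size class above which
plant mitochondrial repeats recombine frequently). Sub-pairs contained in
a longer reported pair are suppressed, matching how repeat families are
counted. The contract is behavioural, verified two ways: equality with a
quadratic brute-force diagonal search on instances ≤ 5 kb, and exact
recovery of planted pairs (length, orientation, identity) on
molecule-scale fixtures, invariant under rotation and whole-molecule
reverse complement.

Copy order on a circle is canonicalized by choosing a gap position outside
both copies and taking copyA as the copy reached first clockwise from it;
output is deterministic across runs and rotations.

`find_short_repeats` (for the 20–200 bp breakpoint-flank class) is the
exhaustive diagonal scan itself, restricted to a window — at these scales
the quadratic scan is cheap and has no seed-length blind spot.

## Reverse read mapping

Junction constructs are `left + right` flanks of width *w* around each
product breakpoint. A construct is *novel* iff it occurs on neither strand
of the doubled parent. The central caveat of repeat-mediated junctions is
that a breakpoint inside a repeat copy is only confirmable by reads whose
anchors clear the repeat ends; the pipeline therefore:

* sizes *w* as `max(flank_w, ceil(repeat/2) + min_anchor + flank_margin)`
  in the end-to-end path (and warns when `min_anchor` < repeat length);
* widens the spanning window by half the repeat length on each side in
  `count_support`, so a read that never leaves the repeat can never count.

The internal mapper is deliberately simple: an exact 15-mer prefilter,
then edlib infix alignment of whichever of read/construct is shorter into
the other. The alignment is trimmed to its best locally-matching window
(+1 per match, −3 per mismatch/indel column, maximum-scoring stretch) and
the window ends are snapped to the nearest run of 10 consecutive matches.
The snap makes trimmed coordinates exact on error-free reads (chance
10-mer agreement with unrelated sequence is ~10⁻⁶ per position), which in
turn makes the internal mapper agree with provenance-derived alignments —
asserted as a cross-check against a truth-built PAF. Real-data alignments
can be imported as PAF instead of using the internal mapper.

`flank_margin` (200 bp) exists because a sequencing error within the first
few bases of the true overlap trims the well-matching span slightly; the
margin keeps the anchor requirement strictly inside the construct so this
jitter cannot unseat an anchored read. Support defaults — `min_anchor`
500 bp, `min_reads` 3, `min_identity` 0.85 — are declared conventions (a
standard long-read SV support floor), configurable, not inferred from any
dataset.

## Molecule comparison

Synteny blocks are gap-free: anchors are 31-mers unique in both molecules
(near-unique at the 50–300 kb molecule scale), chained along diagonals and
extended while bases match exactly. Divergence appears as block
fragmentation rather than gapped alignment, because the comparisons asked
of these molecules are presence/arrangement questions. Circular molecules
use modular coordinates throughout; blocks may wrap the origin.

Overlaps between blocks arise exactly where a repeated segment (e.g. a
short breakpoint flank) is claimed by two neighbouring blocks. They are
resolved longest-block-first, trimming each block against the *original*
extents of all longer blocks on both molecules and keeping its longest
free stretch. This deterministic rule assigns shared flank copies to the
collinear neighbours, so a translocated block is reported at the length of
the moved content itself (774 bp in the bundled fixture), with the 40 bp
flanks excluded — which is also what makes the flanking-repeat search
around the reported breakpoints well-posed.

Classification: strand-flipped blocks are inversions; among forward
blocks, the maximum-weight chain collinear in both molecules (circular
order anchored on the longest block; weight = block length) is the
syntenic backbone and any off-chain block is a translocation; uncovered
regions ≥ 50 bp are insertions (extra in B) or deletions (absent from B) —
the 50 bp floor ignores the sub-flank-sized gaps that overlap trimming
necessarily leaves. Swapping the argument order maps insertions to
deletions and leaves other calls unchanged.

`breakpoint_flanks` scans `window` bp around each breakpoint plus a margin
inside the block (so a flank copy carried along with an inserted block is
still seen) for the longest exact direct pair with one copy at each
breakpoint, via a diagonal longest-common-substring scan.

The marker-region arrangement report (`report_intergenic`) returns the
shorter arc between two named annotation features — used for the
cob-fragment→rps10 distances (637/638 bp fixtures) rather than a bespoke
detector.

## In silico PCR and typing

Primer sites require ≤ `max_mismatches` (default 2) over the primer with
an exactly matching 3′-terminal base (polymerase extension realism; it
also suppresses spurious sites). Both strands are scanned with circular
wrap. Products are all convergent fwd/rev site combinations within
`max_product` (default 5 kb), lengths measured modulo the circle.
Type calls use ±15% tolerance around the 2,400 bp (α) and 1,600 bp (β)
classes — wide enough for "approximately"-reported sizes, narrow enough
that the classes stay disjoint; no product calls γ; products in two
different classes return `unknown` with all evidence attached. The marker
primer sequences themselves are user-supplied configuration: the package
ships the mechanism, and fixtures plant synthetic sites at the published
product distances.

## Gene inventory

ORFs are ATG-initiated and stop-terminated, scanned in six frames;
circular sequences are scanned on the doubled sequence and deduplicated
modulo the length, discarding spans longer than the molecule (a stop-free
frame on a circle has no closed ORF). Codon counts exclude the stop codon
and the threshold is exclusive ("larger than" 100 codons); both choices
are declared here and configurable (`min_codons`, extensible start-codon
set). The category lexicon covers the conserved potato mtDNA complement
(5 atp, 9 nad, 11 ribosomal proteins, 4 ccm, 3 cox, 2 sdh, cob, matR,
mttB, rRNAs, tRNAs), plastid-derived integrations (petA, petG, petL,
psbJ, psbL, rpl23 — the plastid assignment takes precedence over the
ribosomal-protein prefix), Ψ-prefixed pseudogene fragments (counted
separately), and orf* hypotheticals; ids outside the lexicon must be
categorized by user configuration rather than guessed. The 33-gene
phylogenetic marker list is carried as a constant for inventory checks
(the phylogeny itself is out of scope). The published "50–54 ORFs" is a
property of the real genomes' sequence content and is not reproducible on
random backgrounds; it is deliberately not asserted anywhere.

## Synthetic genomes and reads

The generator emulates the four observed architectures with their
published molecule lengths and repeat-family lengths (group A: four
circles, inverted R1 + direct R2 in molecule 1a, R2 in 1b, R4 in
molecule 2; group B: three circles, direct R1 + R3 in molecule 1, R4 in
molecule 2; 10908-06: R1 + R2 and R4; OKA15: expanded R1 13,435 bp,
reduced R2 7,076 bp, and no R4). Background sequence is i.i.d. random at
GC 0.45 (no published background model); planted copies are exact
duplicates unless a divergence rate is set. The R4 copy spacing in
molecule 2 defaults to 45,336 bp so the two sub-genomic circles are
45,336 and L − 45,336 bp, mirroring the reported ~45/~67 kb split; other
placements spread copies evenly, since real inter-repeat spacer layouts
are not published — placements are recorded in truth, not claimed to match
the clones. The `scale` parameter shrinks spacers only, never planted
features, so printed repeat lengths survive desk-scale runs.

**Distinct junction contexts.** After planting, the background base
adjacent to each planted copy (and each fixture block/flank boundary) is
resampled if it would extend the exact match. This is what makes "exact
recovery" well-defined: detected repeat lengths, translocation block
lengths and flank lengths equal the planted values exactly rather than
exactly-plus-a-coin-flip. It is a property of the fixtures, not of the
detectors.

The translocation fixture places three flank copies
(`A = U·F·b·F·V·F·W`, `B = U·F·V·F·b·F·W`) so both molecules have the
block bounded by the flank on both sides and lengths are conserved; the
insertion fixture (`A = P·F·Q`, `B = P·F·b·F·Q`) makes the carrier
molecule longer by block + one flank copy (814 bp at the default sizes).

Reads are drawn from a weighted mixture of circular templates: lognormal
lengths (default μ = 9.2, σ = 0.4 in log-bp ≈ 9.9 kb median, clipped to
[2, 40] kb — chosen for junction-spanning capability, not instrument
realism), uniform start (reads may wrap the origin), uniform strand,
substitution and indel errors applied after extraction, constant FASTQ
quality, and full per-read provenance in the truth object. Read count from
coverage uses the analytic lognormal mean. The simulator does **not**
model chimeric reads, quality-dependent errors, homopolymer artefacts or
linked-read structure — so passing validation tests demonstrates the logic
of junction confirmation under clean long-read geometry, not robustness to
every real-data pathology; the PAF import path exists for real alignments.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (NumPy `default_rng`)
and all generators are byte-deterministic under it. The test suite runs
the full-scale repeat fixtures (112,834 and 297,036 bp circles), the
49,239 bp translocation pair, and read-validation fixtures on a 24 kb
circle at ~20–25× per-isoform coverage plus one full-scale 112,834 bp
validation at 40×; the whole suite completes in about a minute on one
CPU. The acceptance script uses the same full-scale fixtures and runs in
seconds.

## Known limitations

* Gap-free blocks mean indel-containing homologies fragment; totals of
  shared sequence between diverged molecules are conservative.
* Repeat identity is substitution-based (no gapped repeat alignment);
  copies differing by indels report shortened lengths, bounded by
  `max_gap`.
* Junctions inside repeats longer than the longest reads cannot be
  confirmed by any anchor scheme; the tool surfaces this (warning +
  widened constructs) rather than silently counting repeat-internal reads.
* Inter-molecule recombination (e.g. fusion of molecules 1a/1b into a
  single linear form) is not modelled; products are enumerated per circle.
* Isoform stoichiometry is not estimated; support counts are evidence of
  presence, not abundance.
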