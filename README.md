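# mitostruct

Structural analysis of multipartite plant mitochondrial genomes, built
around the potato (*Solanum tuberosum* and relatives) case: mitogenomes
that exist as several autonomous circular molecules which recombine at
large repeats, producing sub-genomic circles and inversion isoforms, and
which differ between clones by translocations bounded by short repeats.

It is written for researchers assembling or comparing organelle genomes
from long reads who need the downstream structural analysis as reusable,
testable code rather than one-off scripts:

* **Repeat detection** (`mitostruct.repeats`) — seed-and-extend
  self-comparison of a circular molecule, both strands, reporting repeat
  pairs with orientation (direct/inverted), length and identity, and
  matching them to the named potato repeat families R1–R4 (≈11.9, 7.5,
  4.5 and 1.6 kb) by length class.
* **Recombination-product enumeration** (`mitostruct.recombination`) — a
  single crossover at a direct pair on a circle of length *L* with copies
  *d* apart yields two sub-genomic circles of lengths *d* and *L − d*
  (each keeping one repeat copy); an inverted pair yields one equal-length
  isoform with the inter-repeat segment reverse-complemented.
* **Reverse read mapping** (`mitostruct.validation`) — junction constructs
  (breakpoint ± *w* bp) are built for every predicted product; a junction
  is *supported* when ≥ `min_reads` long reads align across it with
  ≥ `min_anchor` bases on each side **clearing the repeat copy ends** — the
  central ambiguity of repeat-mediated junctions, handled explicitly.
* **Molecule comparison** (`mitostruct.compare`) — gap-free synteny blocks
  from unique 31-mer anchors; translocation/insertion/deletion/inversion
  calls from block arrangement; discovery of short repeats flanking the
  breakpoints (the 40 bp class that explains the ~774 bp *orf210*
  translocation in molecule 3).
* **In silico PCR typing** (`mitostruct.pcr`) — primer-site matching with a
  mismatch budget and 3′-exact rule on circular templates; mtDNA type
  calls (α ≈ 2.4 kb product, β ≈ 1.6 kb, γ = no product) and combined
  cytoplasm labels (T/β, S/β, W/α, W/γ).
* **Gene inventory** (`mitostruct.inventory`) — six-frame ORF discovery on
  circles (> 100 codons), internal-stop checks, category counts and
  presence/absence matrices across genomes.
* **Synthetic mitogenomes** (`mitostruct.simulate`) — first-class
  generators for the four observed architectures (group A, group B,
  clone 10908-06, OKA15) with planted repeats at the published lengths,
  translocation/insertion fixtures, and a seeded long-read simulator with
  per-read provenance truth.

## Worked example

Simulate a group-B-architecture mitogenome (three circles, desk-scaled to
25% spacer length so repeat lengths stay exact), detect its repeats, and
enumerate the recombination products:

```bash
$ mitostruct simulate --profile groupB --scale 0.25 --seed 7 --out demo
wrote demo.fasta (3 molecules)

$ mitostruct repeats --in demo.fasta --out repeats.tsv
3 repeat pairs -> repeats.tsv

$ cat repeats.tsv
molecule            family startA  lenA   strandA startB  lenB   strandB orientation identity
groupB_molecule_1   R1     12576   11916  +       54157   11916  +       direct      1.0
groupB_molecule_2   R4     9188    1589   +       21714   1589   +       direct      1.0
groupB_molecule_1   R3     37068   4513   +       78649   4513   +       direct      1.0

$ mitostruct recombine --in demo.fasta --out isoforms.fasta --junctions junctions.fasta
6 products -> isoforms.fasta
```

Molecule 1 carries direct R1 and R3 pairs and therefore yields **four**
sub-genomic circles; molecule 2 carries the R4 pair and yields **two** —
six products in total, each with a novel junction construct written for
read-based confirmation (`mitostruct validate --reads reads.fastq ...`).

Comparing two molecule-3 variants that differ by a translocation:

```bash
$ mitostruct compare --a m3A.fasta --b m3B.fasta --out events.tsv
shared=49199 uniqueA=40 uniqueB=40; 1 events -> events.tsv

$ cat events.tsv
type           startA  startB  block_length  flank_repeat_len
translocation  19378   33922   774           40
```

The moved block is reported at 774 bp with a 40 bp direct repeat found on
both sides of it — the configuration consistent with a recombination
origin of the translocation.

## Scope notes

The pipeline starts from assembled molecules: de novo assembly, barcode
processing, functional annotation and phylogenetics are out of scope.
Circular coordinates are 0-based and half-open everywhere internally;
GFF3 is converted at the boundary. Circularity is self-described by a
`circular=true` token in FASTA headers.
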