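# Methods

## The detection rule

A reference gene *g* (1-based inclusive interval, stranded) is *detected*
by a prediction *p* when both of the following hold:

1. **Frame**: same contig, same strand, and `(p.start − g.start) mod 3 = 0`.
   Frame is defined as coordinate congruence anchored at the annotated
   start; for features whose lengths are codon multiples this is equivalent
   to congruence anchored at the stop. It is the only strand-consistent
   formalization that needs no sequence access.
2. **Coverage**: `overlap(g, p) / length(g) ≥ t`, with *t* = 0.75 by
   default. Coverage is frame-agnostic; the two gates are independent, so a
   prediction can cover a gene completely and still miss it by being one
   nucleotide out of frame.

Coordinates are compared exactly as given in the input files; no trimming
or extension around stop codons is applied, so the evaluation is agnostic
to whether an annotation convention includes the stop codon — both sides of
the comparison are simply held to the same convention.

End deviations are signed in gene orientation: on the forward strand
`start_diff = g.start − p.start` and `stop_diff = p.end − g.end`; on the
reverse strand the roles of the genomic ends swap. Positive always means
elongation of the predicted protein.

## One-to-one assignment

Each prediction may detect at most one gene. The rationale: a long
predicted CDS that happens to span a second, smaller in-frame gene encodes
only one protein; crediting it with every gene it covers would reward
overprediction. Assignment is a deferred-acceptance procedure: genes (in
coordinate order) propose to their eligible predictions in order of
increasing deviation `|start_diff| + |stop_diff|`; a contested prediction
keeps the gene with the smaller deviation (ties: smaller `|start_diff|`,
then gene coordinate order) and the displaced gene falls back to its next
candidate or MISSED. Candidate ordering breaks remaining ties by leftmost
prediction start, then shorter prediction. The result is deterministic and
independent of input ordering; a configuration switch
(`classify_gene` per gene, without the assignment constraint) provides the
permissive many-to-one alternative for sensitivity analysis.

## Metrics

Definitions as in the README table. Choices where the definitions were
genuinely open:

* **M5 denominator** is the number of *detected* genes, not all genes, so
  M5 isolates start/stop accuracy from detection ability (a tool can have
  low M1 and high M5). `m5_denominator="all"` gives the other reading.
* **M6/M7** are medians of |deviation| in codons over matched genes with a
  *nonzero* deviation of that end; 0 when no end is mispredicted. Signed
  medians are available in the secondary block.
* **M8/M9** count matched *predictions* having the overlap/short property
  against *reference* genes having it; `property_side="gene"` evaluates the
  property on the detected genes instead. Overlap means sharing ≥ 1 nt with
  another feature of the same set, any strand, same contig; "short" is
  length < 300 nt strictly (both thresholds configurable).
* **TP/FP/FN** are whole-feature counts (a prediction is a TP iff it
  detects a gene), so M10 = M2 and M11 = M1 under one-to-one assignment;
  no nucleotide-level variant is computed.
* Undefined values (zero denominators) propagate as `None`/NA and rank
  worst in the cross-genome rank totalling; ranks use average-tie
  positions, higher-better for M1/M2/M5/M10/M11, closest-to-zero for
  M3/M4/M8/M9, lower-better for M6/M7/M12.

## GFF algebra

`gff_intersect(a, b)` keeps the a-side coordinates of features confirmed by
*b* under the same frame/coverage gates as detection (coverage measured on
the a-feature). The operation is deliberately asymmetric — one annotation is
the frame of reference — with a `symmetric` flag for the union of both
directions. `gff_add(existing, new)` admits a new CDS when its largest
single overlap with an existing CDS is ≤ 50 nt (any strand); a `footprint`
mode measures against the merged coverage of all existing features instead
(stricter for newcomers straddling two genes), and `stranded` restricts
the test to same-strand overlaps.

## Synthetic data generator

`generate_genome` draws i.i.d. bases at a target GC (realized GC within
~1 percentage point at ≥ 100 kb). `plant_annotation` packs genes left to
right with 50–150 nt intergenic gaps, giving the ~75–85% CDS density
typical of bacterial genomes when the genome is sized near the packing
requirement. Defaults emulate the composition ranges of well-studied model
organisms:

| parameter | default | emulates |
|---|---|---|
| start codon profile | ATG 0.80, GTG 0.15, TTG 0.05 | ~69–91% ATG usage in real annotations |
| `frac_short` | 0.10 | 4.8–13.6% of genes < 300 nt |
| `frac_overlapping` | 0.20 | ~a quarter of genes overlapping a neighbour |
| length distribution | lognormal, median 900 nt, clipped [300, 3000] | median bacterial CDS length |
| translation table | 11 (4 optional) | universal vs *Mycoplasma*-style stop usage |

Start-codon counts follow the profile by largest-remainder quota, so
requested proportions are realized exactly; short and overlapping counts
are exact by construction (the overlapping count is rounded down to an even
number, as overlaps are laid in pairs). Overlapping pairs are placed
tail-to-tail on opposite strands with 10–50 nt overlaps: opposite
strandedness guarantees the partners can never satisfy each other's frame
gate, which keeps planted truth unambiguous. Real start and stop codons
are written into the sequence (gene bodies avoid all three universal stop
codons; under table 4 roughly half the genes receive an internal in-frame
TGA, which a universal-code scanner reads as a premature stop). Start/stop
codon positions are protected once written; inside an overlap the partner
gene's *body* may therefore contain incidental in-frame stops — codon
tallies and coordinates stay exact, but overlapping-gene bodies are not
guaranteed to be clean ORFs.

`perturb` degrades a gold annotation per an error profile: each gene is
independently omitted (`p_miss`), frame-shifted by +1/+2 nt
(`p_frameshift`, yielding a surviving non-detector prediction), or copied
with 5'/3' shifts drawn in whole codons (`start_shift`/`stop_shift`
distributions, positive = elongation); spurious predictions are Poisson in
number (`p_spurious` expected per gene, 150–900 nt, uniform placement).
Two guards make the truth ledger exact rather than approximate: truncating
shifts are capped at 24% of gene length, so an intended PARTIAL keeps
≥ 76% coverage; and any shifted or spurious feature that would be an
eligible detector of a different gene is rejection-sampled away (after 50
failed draws the gene falls back to an exact copy, noted in the ledger).
Every gene's intended category then provably equals the comparator's
output, which the test suite asserts across randomized profiles.

What the generator does **not** emulate: realistic codon usage, promoter /
ribosome-binding-site signals, operon structure, assembly gaps or chimeric
contigs, and genes wrapping a circular origin. Passing tests therefore
demonstrate the correctness of the classification, metric and aggregation
machinery on annotations with realistic interval structure — not the
biological difficulty of gene finding on real sequence.

## Numerical and I/O conventions

* All coordinates are GFF3 1-based inclusive internally and externally; no
  half-open conversion exists anywhere.
* Feature identity (and dedup) is the tuple (contig, start, end, strand);
  features on different contigs are never compared.
* Percentages are computed at full precision and rounded to 2 decimals
  only at presentation.
* GC content excludes N from numerator and denominator; an all-N sequence
  is undefined, not zero.
* GFF3 parsing is strict and record-level: non-integer coordinates,
  start > end, or an unknown strand symbol raise an error naming the line.
  FASTA input is uppercased, U→T, and all other non-ACGT characters map
  to N.
* Reported problem sizes: the acceptance script uses a 235 kb genome with
  200 planted genes and three emulated tools; the ledger-recovery test
  runs 50 random error profiles against a 200-gene annotation.

## Known limitations

* Eukaryote-style multi-exon CDS grouping is out of scope; each GFF3 CDS
  row is an independent feature.
* The rank table totals ranks without significance testing; with few tools
  and genomes, small metric differences can swap adjacent ranks.
* The permissive (many-to-one) matching mode reports per-gene outcomes
  only; the confusion-matrix metrics assume the one-to-one rule.
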