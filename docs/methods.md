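# Methods

## The assay being modelled

TISseq (transposon insertion-site sequencing) recovers the genomic flank of a
DNA transposon insertion with an element-anchored amplicon: genomic DNA is
double-digested with EcoRI and HindIII (chosen because neither cuts the
mariner element), cohesive adapters are ligated to the cut ends, and PCR with
one primer in the element's subterminal region and one in the adapter
amplifies the flank on each element end.  Single-end reads of at most ~300 bp
then contain `adapter + genomic flank + element-derived primer region`.
Reads sharing a flank are collapsed into insertion-site sequences (ISS), and
the ISS count is scaled to a somatic insertion rate (SIR) per genome.

The pipeline implemented here covers the five computational stages: trimming
(`tisseq.trimming`), within-sample redundancy collapsing
(`tisseq.redundancy`), between-treatment comparison (`tisseq.comparison`),
accessibility modelling plus rate arithmetic (`tisseq.sir`), and long-read
somatic-mobilization calling (`tisseq.longread_sm`).  A first-class
synthetic-data generator (`tisseq.simdata`) emulates the molecular protocol
so every stage is testable with known truth.

## Accessibility model and rate arithmetic

An insertion is only sequenceable when a restriction site lies within read
reach of the insertion point.  Over a digestion fragment table the accessible
genome percentage is

    P = (b + c * L) * 100 / (b + d)

with *L* = 600 bp (both ends of a fragment that short are within a 300-bp
read), *b* the total bases of fragments in [50, 600] bp, *c* the count and
*d* the total bases of fragments longer than 600 bp; fragments under 50 bp
are excluded from both numerator and denominator.  *d* is the true base sum
of the long fragments: the equation only yields a fraction below 100% with
that denominator.  On a drosophilid genome this evaluates to roughly 30%
accessible (the test suite reproduces ~31% on a random genome with
drosophilid base composition and fragment statistics; real assemblies differ
slightly through repeat structure).

The per-genome rate is a two-step quotient: `detected = ISS / n_flies`
(default 30 pooled individuals per library) and
`estimated = detected * 100 / P`.  Reported values round half away from zero
to one decimal, each from the unrounded chain.  Note one published-table
quirk: 2494.6 / 30 = 83.1533 prints as 83.2 under this convention, while the
original table shows 83.1; the estimated column is unaffected.

For simulation-recovery work the 600/300 approximation is replaced by the
exact counterpart of the simulated library: `detectable_fraction()` counts
genome positions whose one-sided cut distance lies in `[min_flank,
max_flank]`, where `min_flank` is the trimming length filter (25 nt) and
`max_flank` the read budget after adapter and primer
(300 − 20 − 22 = 258 nt).  Using Eq.-style binning with the 600 cut-off on
simulated data would systematically under-recover by ~10–15%, because flanks
shorter than 25 nt are planted but never survive trimming.

## The synthetic-data generator

`simdata` is the study-conditions oracle, not a dial:

* **Genome** — i.i.d. bases at GC 0.42 (drosophilid-like).  This reproduces
  the EcoRI+HindIII fragment-length statistics of the real digest (mean
  ~1.6 kb) but carries no repeats, satellites or chromatin structure; tests
  passing on it say nothing about repeat-driven artefacts.
* **Element** — a 1286-bp AT-rich (GC 0.37) mariner-like sequence with 28-bp
  imperfect terminal inverted repeats (7 substitutions between the repeats,
  as in the natural element) and no EcoRI/HindIII site.  The imperfect TIRs
  matter computationally: they keep the two terminal 22-mers used as
  subterminal primers mutually distinguishable at the 2-mismatch tolerance.
* **Insertions** — uniform positions without replacement, random orientation;
  germline copies at cell fraction 1.0 (the study strain carries ~2 mariner
  copies), somatic fractions uniform on [0.05, 1] by default, standing in for
  insertions arising at different developmental times.
* **Library** — 10,000 single-end reads per sample (fixed count by default,
  Poisson in stochastic mode), upstream/downstream PCRs merged 1:1 (the
  molar ratio is configurable; it is not reported for the real assay).
  Element reads are allocated to accessible (site, end) pairs with
  probability proportional to cell fraction.  Artifact classes: 30%
  element-free contaminant amplicons and 10% adapter chimeras
  (`adapter + partial flank + adapter + unrelated flank + primer`), together
  matching the reported loss of roughly half the reads to short fragments,
  chimeras and element-free amplicons.  Substitution errors at 0.001/base
  (the constant-Q30 quality model); no indels, no PCR duplicates, no
  platform-specific error profiles.  Optional geometric length bias
  (`pcr_length_bias`) models preferential amplification of short fragments
  and is off by default for testability.
* **Long reads** — Gaussian lengths (default 8 kb ± 0.8 kb), uniform starts;
  each read draws a haplotype carrying every overlapped somatic insertion
  with probability equal to its cell fraction.  No nanopore error model is
  attempted; error rate is a plain substitution probability.

Every read is reconstructable from its truth-table row at error rate 0, and
the site table's accessibility flags are checked against a brute-force cut
scan in the tests.

## Alignment and clustering choices

* Primer/adapter matching is substitution-only (Hamming scan, both strands,
  default ≤2 mismatches for 20–22-mers).  Indels in a 22-mer at Illumina
  error rates are rare enough that the simpler scan is preferable; reads
  matching both primers are discarded as chimeric rather than split.
* Flank-to-flank comparison uses a containment alignment (edlib, bit-parallel
  edit distance, infix mode, both strands): the shorter sequence is aligned
  within the longer and identity is computed over alignment columns.  Flanks
  from one locus share the restriction cut and the insertion junction, so
  they are equal, nested or substitution variants — exactly the geometry
  containment alignment captures.  A small pure-Python Smith-Waterman serves
  as the independent oracle in the tests.
* Two flanks are the same ISS when the alignment covers ≥70% of either
  sequence (qCOV and/or sCOV) *and* identity is ≥90%.  The coverage rule is
  the assay's published criterion; the identity floor is this package's
  addition, preventing low-complexity sequences from chaining clusters.
* Clustering is order-free single-linkage (union-find) over those edges,
  followed by a final de-duplication pass over representatives in decreasing
  (read support, length) order.  The iterative filter cascade it replaces is
  order-dependent; union-find plus the final pass reaches the same stated
  postconditions (every flank in exactly one record; no qualifying pair among
  survivors) deterministically.  All-vs-all cost is controlled by collapsing
  byte-identical reads first and by aligning only pairs sharing a canonical
  12-mer; the k-mer prefilter can in principle miss a qualifying pair whose
  mismatches are spaced every <12 bases, which does not occur at the
  simulated error rates and is guarded by the brute-force oracle test.
* Clustering runs sample-wide rather than per element end, and a cluster
  inherits its representative's end tag.  This lets a chimera-trimmed
  fragment — which carries the *partner* read's primer and hence a wrong end
  tag — fold into its true site instead of founding a spurious ISS.
* Representative = longest member, ties to the smallest identifier (the rule
  is not specified by the assay; longest preserves the most flank sequence).
* "With coverage" means read support ≥2.  `poisson_rate_for_coverage_fraction`
  inverts P(X≥2 | X≥1) for per-site Poisson sampling; ~13% with-coverage
  corresponds to a mean of ~0.27 reads per detectable site.
* Between-treatment sharing is reciprocal best hit under the same edge rule,
  with best = (identity, alignment length, smallest id); reciprocal-best makes
  the matching one-to-one so Venn counts are disjoint.

## Long-read SM calling

Element copies are located by containment alignment on both strands with
iterative masking (multiple copies per read are each reported).  A copy
truncated by a read boundary aligns its overhang as terminal
insertion/mismatch columns; these are treated as soft clipping, reducing the
reported element coverage (span-based at boundaries) rather than the
identity, with an 80% coverage floor.  Flanks of 2 kb are extracted on the
element-forward orientation, grouped by single-linkage at ≥90% identity over
≥50% mutual coverage, and each group is tested for uniqueness in the
reference (exactly one qualifying genome alignment).  Because extracted
flanks are anchored at the insertion junction, same-locus flanks are nested
and containment alignment suffices; a group can split if no member spans
both full flanks, a known limitation at very low coverage.

A somatic-mobilization event is *supported* when a unique region is observed
in at least one read with the element adjacent (within 50 bp, absorbing
alignment clipping) and at least one read without it.  A without-element
call additionally requires the read to continue ≥50 bp beyond the insertion
junction: a read broken at the junction matches the flank query within the
identity budget yet is evidence for neither state, and treating it as
element-free produces false mosaicism calls (the same situation that
prevented a verdict at one locus in the original assay).  Multicopy regions
(e.g. tandem gene clusters) and unplaced regions are never supported,
regardless of read evidence.

## Problem sizes and numerical conventions

The acceptance computations use a 5-Mb single-scaffold genome, 200 somatic +
2 germline insertions, 10,000 reads per library and three replicate
libraries (averaged, as in the assay's replicate design), and a 300-kb
genome with 500 long reads for SM calling; these sizes keep every
distributional property measurable while the whole run stays desk-scale.
End-to-end recovery of the planted insertion count is accurate to well
within ±15% under these conditions; the residual noise is binomial placement
of insertions into the accessible genome fraction.  Ties are broken
lexicographically everywhere a total order is needed; all randomness flows
from explicit integer seeds; degenerate inputs (empty genomes, zero-length
scaffolds, out-of-range rates) raise `InputError`/`DesignError` rather than
propagating.

## Known limitations

* The synthetic genome has no repeat structure, so the multicopy-region
  pathway is exercised only through an explicitly planted tandem
  duplication.
* Upstream and downstream ISS of one insertion are not paired into loci
  (short flanks on opposite sides share no sequence; the original assay had
  the same limitation), so site counts are per element end.
* Two insertions falling in the same fragment on the same side of a shared
  cut yield nested flanks that merge into one ISS; at 200 sites on 5 Mb this
  affects ~1% of sites and is inherent to the assay, not the implementation.
* Read-breakage at insertion junctions is modelled only through truncated
  flank flags and the junction-margin rule; no breakpoint assembly is
  attempted.
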