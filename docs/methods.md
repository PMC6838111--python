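# Methods

## The splicing model

A gene is a list of exon intervals (0-based, half-open) on a
transcription-oriented DNA sequence; introns are the gaps between
consecutive exons and are never stored independently.  Minus-strand genes
are reverse-complemented at load time, so all motif logic (GT donor, AG
acceptor, branchpoint) is written once, in transcript orientation, with
RNA motifs transliterated to DNA (GU→GT, YURAY→YTRAY).  N bases are
allowed in sequences but fail any motif position they occupy.

Splicing events are defined **relative to the canonical fully spliced
form**: the event set for an isoform describes how its removals differ
from "remove every intron".  Intron retention deletes a removal;
alternative 3′ acceptor / 5′ donor move one boundary of a removal to a
genomic alternative site (which may lie inside the intron or inside the
flanking exon); exon skipping removes an internal exon and fuses the two
flanking removals.  Events are applied declaratively to the removal set,
so any ordering of a compatible event set yields the same segment list.
Incompatibilities: retention vs. an alt site on the same intron; skipping
a terminal exon; skipping exon *e* vs. retention of either flanking
intron, the 3′ alt site of intron *e−1*, or the 5′ alt site of intron
*e* (those splice sites no longer exist when the exon is gone).  Alt sites
are genomic positions rather than offsets so that one catalog entry
serves every composite isoform that reuses the site.  Isoforms are
deduplicated by exact sequence identity — the same criterion by which gel
sizing and clone sequencing distinguish them.

Re-splicing models the observation that an intron-retaining transcript is
itself a substrate: each canonical intron wholly contained in a variant's
segments may be excised either canonically or through any catalog
alternative site that fits inside the retained region, giving the set of
derivable products (for the intron-2-retaining isoform: the canonical and
the alt-acceptor product, hence three gel bands including the substrate).

## ORFs and protein consequences

The default ORF policy scans every ATG in all three forward frames and
returns the longest ORF in amino acids (ties: smallest start), ending at
the first in-frame stop or, absent one, at the transcript end.  Protein
lengths exclude the stop codon.  An `anchored` policy translating from a
fixed start is available because all isoforms of the modeled locus share
their 5′ UTR and initiation codon.  Stop codons are mapped back through
the variant's segments to genomic coordinates; the containing exon is
reported 1-based, or "intron" for stops inside retained intronic
sequence, and a stop is premature when its genomic position differs from
the canonical form's stop.  Shared termini are plain longest common
prefix/suffix over a named protein set.

## U2-type intron rules

Five per-intron checks, aggregated into a single `u2_type` conjunction:

1. **Donor**: the intron must begin with GT; the 8-position consensus
   AG|GTAAGT (2 exonic + 6 intronic) is scored and reported but only GT is
   obligatory.
2. **Acceptor**: the intron must end with AG; the 7-position consensus
   TGYAG|GT is scored analogously.
3. **U/A richness**: fraction of A+T over the whole intron ≥ 0.60 by
   default.  The threshold is configurable; 0.60 reflects the canonical
   ~60% AU content of plant introns.
4. **Branchpoint**: every YTRAY match whose *first* base lies 30–70 nt
   (inclusive) upstream of the intron's final base.  Whether the window
   anchors the motif's first or last base is a recorded convention;
   both are supported (`anchor="first"` default, `"last"` switchable).
   Introns shorter than 35 nt cannot satisfy the window and report no
   branchpoint.
5. **Poly-U tract**: in the region strictly between the branchpoint motif
   (the most 3′ one when several exist) and the terminal AG, a run
   containing ≥ 5 T with at most one single-base interruption; the
   longest such tract is reported.  Both parameters are configurable.

Rule 5 is anchored on rule 4's motif by definition, so destroying the
branchpoint necessarily also unsets the poly-U flag; the other rules are
mutually independent and each is falsifiable by a single targeted
substitution (the test suite exercises exactly that).

## Statistics

**Quality filter.** 3′ bases with quality < 30 are trimmed, then a read
is kept when ≥ 70% of its remaining bases have quality ≥ 30.  Q = 30 is
treated as passing in both steps, and the fraction is computed after
trimming; both are recorded conventions where the underlying description
is ambiguous at the boundary.

**Counting.** Reads carry genomic footprints (lists of intervals, since a
spliced read maps discontiguously).  In the default intersection-strict
mode a read counts toward the gene's exon-union feature only if its whole
footprint lies in the exon union, toward intron *i* only if wholly inside
that intron, and is otherwise ambiguous (counted in the library size but
in no feature).  An `overlap` mode assigns a non-exonic read to the single
intron it overlaps; it exists because an intron shorter than the read
length (the modeled locus retains a 35-nt intron; reads are 50 nt) can
never strictly contain a read, so retention evidence requires overlap
counting — the behavior of interval-overlap intron counters.

**FPKM** is computed directly: count / (length/1000) / (library/10⁶).
**qPCR** relative expression is (target / 18S reference) × 1000.

**Differential expression** replaces negative-binomial machinery with a
pooled two-sided exact binomial test: replicate counts are summed per
condition, and count_A is tested against Binomial(count_A + count_B,
lib_A/(lib_A+lib_B)), two-sided by summing the probabilities of all
outcomes no more likely than the one observed.  Benjamini–Hochberg
adjustment follows, and a feature is called DE when its normalized fold
change (pseudocount 0.5 on zeros, avoiding infinite ratios) exceeds 2 in
either direction *and* the adjusted p ≤ 0.05.  A gene is
intron-differential when at least one of its intron-region features is
flagged under the same rule.  This design is deliberately simple and
exactly testable (brute-force enumeration reproduces every p-value);
the trade-off is that the test is calibrated under its own (Poisson-like)
sampling model.  Under biological overdispersion it is anticonservative —
it has no tagwise dispersion — so calibration checks run in the
vanishing-dispersion regime, and DE counts on overdispersed data should
be read as liberal.

**Clone quantification.** Inserts are assigned to the nearest reference
length within a tolerance (fractional by default, 0.8%); ties and
non-matches are ambiguous and excluded from the proportion denominator,
with the count reported.  Reference pairs closer than the sum of their
tolerances are rejected as indistinguishable-by-size rather than silently
merged.  Proportions get Wilson score intervals (stable at n ≈ 100, unlike
Wald).  The shift test is chi-square homogeneity on the condition ×
variant table, pooling variants with expected count < 1 into "other", and
Fisher's exact test for 2×2 tables.  Replicate clone platings are pooled
by default before testing.

## The synthetic generator

All inputs derive from one seed, fanned out to named substreams
(CRC32-keyed `SeedSequence` spawn keys), so every stage is independently
reproducible.

`make_gene` emits a random 4-exon gene whose introns are U2-compliant by
construction: planted GTAAGT / TGCAG termini, a CTGAC branchpoint at a
random in-window distance (unique by rejection sampling, so mutation
tests are well-defined), an A/T-skewed filler meeting the U/A target, and
a planted poly-T tract of exactly 5 T (4 planted plus the acceptor's
leading T) so that one substitution abolishes rule 5.  Exon 2's length is
forced off a multiple of 3 so skipping it shifts frame.

`build_cwp_like_gene` is the deterministic reference locus (a synthetic
reconstruction; no genomic accession underlies it).  Its arithmetic is
fixed by the published isoform quantities: exons of 261/240/290/63 nt,
introns of 98/35/101 nt, a 26-nt 5′ UTR and 15-nt 3′ UTR, an alternative
5′ donor at position 245 (inside exon 1, at a codon boundary 219 nt into
the CDS) and an alternative 3′ acceptor at 822 (188 nt into exon 3).
Exon 2 opens with a stop codon that is in frame only for transcripts
using the alternative donor, which pins the truncated isoforms at 73 aa
with the stop's first base in exon 2; the retained 35-nt intron 2 and the
188-nt acceptor shift both break frame in exon 3 (planted stops at 187
and 185 aa); and the donor + skip + acceptor combination shifts by a net
multiple of 3, restoring the reference frame so the exon-skip isoform
shares VAR1's C-terminus (49 aa).  Every isoform carries exactly one ATG,
making the longest-ATG policy unambiguous.  A constraint worth noting:
with the alternative donor upstream of the canonical one, a 73-aa protein
whose stop begins in exon 2 is only possible when the cut falls exactly
at a codon boundary — an intron-internal donor site cannot satisfy both
facts simultaneously.

`make_reads` draws multinomial isoform counts at the configured depth,
uniform fragment starts, and constant Q38 qualities except for a
configurable fraction of reads with interspersed Q20 bases that fail the
70% filter; each read carries its generating isoform and genomic
footprint, so the pipeline tests counting and statistics rather than
alignment (alignment is out of scope by design).  `make_counts` draws
negative-binomial gene and intron-region counts (lognormal baseline
means, dispersion 0.1, two conditions × two replicates) with planted
fold-changes and a truth table.  `make_clones` draws multinomial tallies
of 100 clones × 3 replications per condition from the configured isoform
proportions — (VAR1 38%, VAR3 29%) at high temperature shifting to
(51%, 10%) at low, minor isoforms nearly unchanged — and insert lengths
with Gaussian gel noise (sd = 1% of length).  `make_qpcr` plants a
tenfold induction with ~15% lognormal measurement noise.

What the generator does **not** emulate: sequencing substitution errors,
positional coverage bias, PCR duplication, rRNA contamination, partial
(co-transcriptional) splicing intermediates, and biological replicate
structure beyond NB dispersion.  Passing tests therefore demonstrate the
correctness and calibration of the implemented computations under known
truth, not performance on real libraries.

## Numerical and scale choices

Simulation sizes are chosen to make the statistical checks sharp but
quick: 2000 genes for null calibration, 400 for power, 20 000 binomial
replicates for Wilson coverage (the exact coverage at n=100 sits between
93.6% and 96.6% at the studied proportions, so large replicate counts are
needed to separate it cleanly from the 93–97% band), and 100–150
replicate clone experiments for shift detection.  The shift test's power
at a single 100-clone draw per condition is ~77% on the full
seven-isoform table; the study design of three pooled 100-clone
replications per condition brings it to ~99.8%, and the pipeline tests
that design.  Degenerate inputs are defined explicitly: zero totals give
p = 1, empty event sets give the canonical transcript, single-exon genes
have no introns, transcripts shorter than the read length are skipped
with a warning, and zero assigned clones is an error rather than a NaN.

## Known limitations

- The exact test is anticonservative under overdispersion (see above);
  whole-transcriptome DE counts from the original study are not
  reproducible here in any case, since the raw libraries were never
  deposited.
- The reference locus is a synthetic reconstruction: sequence-level
  features beyond the engineered constraints (codon usage, real splice
  site strengths) are arbitrary.
- One reported ORF length in the source material (811 bp for the 270-aa
  frame) is internally inconsistent (270 aa + stop = 813 nt); the package
  reports the computed 813 and makes no attempt to match 811.
- Size classification treats gel measurement noise as Gaussian and
  independent; co-migration of near-length isoforms is handled by the
  declared-merge rule, not modeled physically.
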