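# Methods

This note documents the models and procedures implemented in `mirmzt`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Read mapping and counting

The mapper is an exhaustive scan (string search for the 0-mismatch case, a
vectorised sliding-window comparison otherwise) over both strands of an
in-memory genome, reporting **all hits in the best mismatch stratum**: if
any perfect hit exists, only perfect hits are returned; otherwise all hits
at the lowest observed mismatch count up to the allowance. This reproduces
the report-all-best-stratum policy of classic short-read aligners run as
`-v <mm> -a --best --strata -m <cap>`. There is no indel model and no
quality model; reads shorter than 16 nt are rejected. N never matches
anything, on either side. Hit results are memoised per genome because
collapsed libraries and iterative trimming re-query the same strings
heavily.

Counting applies three rules:

* **multi-mapper cap** — reads with more than `max_loci` (default 5)
  best-stratum hits are discarded entirely;
* **fractional split** — a retained read with *n* hits contributes
  count/*n* to each mature microRNA overlapped by each hit. The split is
  over all genomic hits, not only hits that touch an annotated mature:
  this is the simplest defensible reading of "correcting for mapping to
  multiple locations", and it means column sums never exceed the library
  total;
* **5′-anchor assignment** — a hit is assigned to a mature when it is on
  the mature's strand, contained in the hairpin, and its 5′ start lies
  within ±3 nt of the annotated mature 5′ end. MicroRNA 5′ ends are
  processed precisely (they define the seed), so the 5′ anchor is the
  robust key; the 3′ end is left free because of tailing and trimming
  heterogeneity. Whether counts should be pooled per hairpin instead when
  arms overlap ambiguously is unknowable from annotation alone; the ±3 nt
  anchor is this package's choice.

RPM normalisation divides by the per-library genome-mapped total (after
the multi-mapper cap) times 10⁻⁶. A zero total is an error naming the
library, never a silent NaN.

An optional exclusion-interval list stands in for upstream filtering of
reads from abundant non-microRNA loci (tRNA genes in real pipelines); no
tRNA predictor is included.

## Tail calling

`call_tail` implements detection of nontemplated 3′ additions by iterative
trimming: if the full read maps with 0 mismatches it is *untailed*;
otherwise one base is removed from the 3′ end and the prefix remapped,
until either a perfect hit appears (the read is *tailed*, with the longest
perfectly mapping prefix and the remaining suffix as the tail) or the
prefix would fall below `min_prefix` (default 16 nt, the same floor as the
global read-length cutoff; the read is *unmapped*). Maximality of the
prefix guarantees, at every reported hit, that the first tail base differs
from the genomic base immediately 3′ of the prefix — otherwise a longer
prefix would have mapped.

Two consequences shape all downstream statistics:

* **conservativeness** — an appended base identical to the genomic
  continuation is absorbed into the prefix. A tail is *recoverable* iff
  the full read is not a verbatim genomic substring; the recovered
  modified proportion therefore estimates the recoverable rate, a lower
  bound on the planted modification rate. The synthetic truth record
  tracks both per read (`first_base_detectable` for the first-base
  criterion, `recoverable` via an independent substring scan), and the
  test suite asserts exact equality of recovered and recoverable counts.
* **suffix tails** — a tail whose first bases are templated is recovered
  as its nontemplated suffix, shortening the observed length distribution
  and depleting the observed composition of whatever base the genome
  continues with (adenosine-rich tails lose adenosines at A-continuation
  loci).

Summaries are count-weighted over collapsed reads: overall and per-mature
modified proportions (fractional 1/n assignment when a prefix hits several
matures, consistent with counting), the tail length histogram, and a 5 × 4
positional composition matrix. Tails longer than 5 nt keep their full
length in the histogram but contribute only positions 1–5 to the matrix;
rows with no observations are NaN, not zero.

## Absolute quantification

With reference reads *r*, reference amount *a* (fmol) and total microRNA
reads *T* in the same library, the content per egg is (*T*/*r*) · *a* /
*n*<sub>eggs</sub>. All microRNA reads are treated as equimolar per read —
read count is the only abundance proxy available. Several spike-ins give
independent estimates; they are combined by the mean and the per-spike
table is always reported alongside, so the spread is never hidden. The
endogenous route uses an abundant microRNA whose amount was measured
independently (in the synthetic study, the truth record plays the role of
that measurement). Zero reference reads is an error ("below detection"),
not a zero estimate. Conversion to molecules multiplies by 10⁻¹⁵ ×
Avogadro's constant.

Both 1- and 2-mismatch mapping variants are computed by the pipeline: the
mapped total under 1 mismatch loses reads with ≥2-nt deviant tails, so the
1-mismatch estimate is biased low and the 2-mismatch estimate recovers
most of that mass. The package reports both rather than choosing.

Stage-to-stage comparison uses Spearman rank correlation (average ranks on
ties, the standard definition) for every library pair; a constant library
yields NaN entries and is listed in `attrs["constant_libraries"]` — an
undefined correlation is flagged, never silently zero.

## Catalog

Clustering chains loci on the same chromosome whenever the gap between
nearest hairpin boundaries (end of one to start of the next) is at most
`max_gap` (default 10 000 bases), ignoring strand. Boundary-to-boundary is
a choice — midpoint or start-to-start conventions would shift edge cases
by under a hairpin length — and single-linkage chaining means a cluster
can span far more than 10 kb. The result is a partition, invariant to
input order.

Seeds are mature positions 2..k+1 (k ∈ {6, 7, 8}); families are exact-seed
partitions with deterministic (lexicographic) member order. Partitions at
larger k refine, never merge, partitions at smaller k. Hairpin-homology
families are out of scope: the `family` field on a locus may be supplied
from annotation but is never computed.

## Target prediction

Site classes follow the canonical hierarchy. With seed s = positions 2–7
and m8 = position 8 (U ≡ T), the UTR match strings are: 6mer = rc(s);
7mer-m8 = rc(2–8); 7mer-A1 = rc(s)+"A"; 8mer = rc(2–8)+"A". The scanner
finds every seed-core occurrence and classifies it once, at its highest
class, by inspecting the two flanking bases; an occurrence at the UTR edge
simply lacks the corresponding context. Equivalence with a per-window
brute-force enumeration is asserted on a megabase of random sequence.

`min_class` defaults to 7mer-A1 — 7mers and 8mers count, lone 6mers do
not, matching the conventional "canonical" core — with a 6mer mode
available; the choice is recorded in output headers because the evidence
for any specific threshold is weak.

Genes with several transcripts are represented by one merged UTR:
duplicate sequences removed, distinct sequences joined with an 8-N spacer
so no site can span a junction. Genome coordinates of UTRs are not
modelled, which is why a spacer is used instead of interval union. An
optional second pair set from any external predictor can be overlapped for
bookkeeping; no thermodynamic or conservation scoring is implemented.

## Enrichment statistics

Gene classification: down iff log₂FC ≤ −log₂(fold) and adjusted p < α
(defaults fold = 2, α = 0.05); up symmetric; none otherwise, including
genes with large fold changes that miss significance. Genes lacking an
adjusted p are excluded and counted. The analysis universe is the
intersection of genes with a UTR record and genes present in the DE table
— enrichment must condition on testable genes.

The hypergeometric p is the upper tail P(X ≥ k) for k overlap between a
microRNA's targets (intersected with the universe) and a gene set of size
n drawn from a universe of N containing K targets. The permutation test
draws `n_perm` (default 1000) size-matched sets without replacement and
reports (1 + #{overlap ≥ k}) / (n_perm + 1); the pseudocount avoids zero
p-values. The permutation null *is* the hypergeometric law, which the test
suite exploits as a cross-check (agreement within Monte-Carlo error on 50
random instances). Correction is Bonferroni by default over all tested
(microRNA × gene set) combinations; the family size is recorded in the
output metadata because different figure layouts imply different families.
Benjamini–Hochberg is available behind the same interface.

Clearance flagging: a microRNA is flagged when its corrected p in the
down-set is below 10⁻³ *and* its corrected p in the up-set is not
significant (≥ 0.05; only the down-set threshold is canonical, the up-set
quietness cut is this package's parameter) *and* it has at least one
target in the universe. The report emits (expression, −log₁₀ p) pairs for
the expression-versus-enrichment scatter.

Word enrichment is a set-based hypergeometric over all 4ᵏ words (default
k = 6): for each word, genes whose UTR contains it versus the gene set,
Bonferroni over 4ᵏ. This deliberately simplifies ranked-landscape word
enrichment (Sylamer-style) by conditioning on a fixed gene set instead of
a ranked list; outputs are labelled "sylamer-like".

## The synthetic study

The generator emulates the *structure* of an early-development small-RNA
experiment, with defaults fixed once as the study conditions:

* genome: 3 chromosomes × 150 kb of i.i.d. uniform sequence; 24 hairpin
  loci (90 nt, mature arms of 22 nt at fixed offsets, plus strand), placed
  with ≥11 kb separation except for two planted clusters (4 loci spaced
  2 kb; 2 loci spaced 3 kb) on chr3;
* families: the clustered loci carry shared 3p seeds (AGUACG × 4,
  CACUGG × 2, written into the genome together with a shared position-8
  base so all seed-dependent site classes coincide within a family). All
  other seeds are drawn to be unique *and* non-nested: no mature's seed
  core may be a substring of another mature's possible site strings,
  otherwise planted sites would systematically alias between microRNAs
  and exact truth comparison would be impossible;
* expression (exact planted counts per library): four stages — oocyte,
  8–16 h, 16–24 h, 24–48 h. Clearance matures: 20 / 2000 / 800 / 400
  (near-silent maternally, surging at zygotic genome activation);
  an abundant constitutive endogenous reference at 5000; background
  matures at 300 (3p) and 30 (5p);
* tailing: per-molecule modification probability 0.2 (oocyte estimates of
  at least ~20% motivate the default), tail lengths 1–5 with law
  {0.50, 0.30, 0.12, 0.05, 0.03} (mass on 1–3 nt), positional composition
  A = 0.98 at position 1 and 0.95 at positions 2–5. The composition is
  deliberately stronger than the observable target because suffix
  recovery depletes adenosines (see Tail calling): with these planted
  values the *recovered* composition is ≥90% adenosine at position 1,
  i.e. near-exclusive oligoadenylation as observed;
* spike-ins: three sequences absent from the genome at 0.01 / 0.005 /
  0.002 fmol, counts coherent with a planted total microRNA content of
  0.2 fmol per egg in the spiked (oocyte) library;
* genes: 300 UTRs of 1 kb. Random UTRs are first scrubbed of every chance
  seed-core occurrence for any simulated mature (a 1-kb random sequence
  contains ~0.24 such cores per mature), then sites are planted by
  substitution at spaced offsets, with the two flanking bases repaired so
  the realized class equals the requested class. A post-hoc scan verifies
  that no unintended site exists; rare junction artifacts trigger a
  redraw. Truth pairs are exact by construction;
* targeting: the AGUACG family targets 30 and the CACUGG family 25 of the
  40 always-down genes (2 sites each, classes 8mer/7mer-m8 and
  7mer-A1/8mer); every background 3p mature targets 8 uniformly chosen
  genes (1 site each) so non-clearance microRNAs have targets but no
  enrichment;
* DE tables: three comparisons versus oocyte. Down genes: log₂FC ~
  U(−4, −1.2), adjusted p = 10^U(−6, −2); up symmetric; unregulated genes
  |log₂FC| < 0.9 with p ≥ 0.06. Each comparison adds 5 stage-specific
  down and up genes, so the three-way intersections equal the planted
  always-down/always-up sets exactly.

Counts are emitted exactly (only the modified/unmodified split, tail
sequences, and DE values are stochastic), reads are pre-collapsed
(sequence + count, the post-trimming representation), and everything is
deterministic given `rng_seed` — byte-identical artifacts.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: sequencing error, adapter artifacts, piRNA and
degradation backgrounds, non-uniform genomic composition (repeats, low
complexity), chance target sites and decoy seed matches in UTRs,
expression noise (planted counts are exact), templated 3′/5′-end
heterogeneity beyond an optional ±1 nt 3′ offset (default off, and the
real distribution of such heterogeneity is unknown), and minus-strand loci
(the mapper and assignment handle them; the generator plants plus-strand
loci only). Exact recovery results on synthetic data are correctness
checks of the algorithms, not performance claims for noisy libraries.

## Problem sizes and numerical choices

The default study is sized for interactive use: ~11 000–23 000 reads per
library over a 450-kb genome; a full pipeline run completes in about a
minute on one CPU, and the test suite (including an end-to-end run, a
tail-contract sweep over ~33 000 simulated reads across a modification
grid, megabase site-scanner equivalence, and 50 × 1000-permutation
concordance checks) in about two minutes. Tolerances in statistical tests
are 3 standard errors of the relevant binomial or Monte-Carlo quantity;
deterministic recoveries are asserted exactly. Ties in Spearman use
average ranks; ties in word ranking break alphabetically; permutation
p-values carry the +1 pseudocount; Bonferroni caps at 1.

## Known limitations

* The mapper is exhaustive and in-memory — correct and fast at megabase
  scale, not a tool for real genomes.
* Mature assignment (±3 nt 5′ anchor) and the fractional split are
  reasonable conventions, not ground truth; pipelines differing in these
  rules will differ in per-mature counts for multi-mapping families.
* Equimolarity of reads ignores ligation and composition biases, which in
  real libraries distort absolute estimates by factors the spike-ins only
  partially absorb.
* The word-enrichment test conditions on a hard gene set; a ranked
  landscape analysis is strictly more informative and is not implemented.
* No novel-microRNA discovery, no DE engine, no thermodynamic target
  scoring: annotations, DE tables and (optionally) external pair sets are
  consumed, not produced.
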