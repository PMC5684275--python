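# Methods

## The problem

In Lepidoptera (moths and butterflies) females are the heterogametic sex:
WZ or Z0 females against ZZ males. Sequencing depth therefore carries
chromosome identity. Relative to autosomes, Z-linked sequence has half
coverage in females and full coverage in males, and W-derived sequence has
roughly half coverage in females and none in males. `zlink` turns
per-scaffold depth tables from male and female libraries into (i) Z /
autosome scaffold classifications, (ii) chromosome-level homology tests
against a reference karyotype, including detection of neo-Z fusions,
(iii) branch-resolved estimates of gene movement onto and off the Z across
a four-species phylogeny, (iv) candidate W-derived scaffolds, and (v) sex
calls for unlabelled libraries. Every stage is exercisable end to end on
synthetic genomes with planted truth.

## Coverage ratios and scaffold prefiltering

Depths are summed per scaffold within each sex, and the classification
signal is `Log2(F/M)` of the grouped female over grouped male depth. No
pseudocount is added: a pseudocount drags the Z mode toward zero on
low-coverage data, so zero-depth rows are instead flagged non-finite and
left out of histograms (they end up unclassified).

Before classification, scaffolds must be strictly longer than 1500 bp with
grouped male depth strictly above 5× and strictly below the 99.5th
percentile of grouped male depth. The floor removes scaffolds with too
little signal to place; the percentile cap removes collapsed repeats, which
have inflated depth in both sexes and would otherwise be confidently—and
wrongly—called autosomal. The cap is computed once, on the pre-filter
population, and carried with the table, so the filter is idempotent. For
degenerate depth distributions (noise-free simulations put every autosomal
scaffold at exactly the same depth, so any strict cap empties the table)
the cap can be disabled with `male_pct_cap=None`.

## Lenient classification

The `Log2(F/M)` distribution of a female-heterogametic genome is bimodal:
a dominant autosomal peak (`A_mode`, near 0) and a Z peak near
`A_mode − 1`. `A_mode` is the centre of the most populated bin of an
equal-width histogram over the finite ratios (default 200 bins; 120 suits
sparser tables); a tie between bins goes to the bin nearer 0, since the
autosomal peak is by assumption the dominant one at equal dose. Scaffolds
with ratio strictly below `A_mode − 0.6` are Z, strictly above
`A_mode − 0.4` autosomal, and everything in between — including the exact
boundary values, and all non-finite ratios — is unclassified. The 0.6/0.4
offsets split the valley between modes asymmetrically because depth noise
is larger on the (lower-coverage) Z side.

## Stringent classification

When scaffolds can be tied to a reference karyotype through orthologs, the
Z cutoff can be calibrated instead of assumed. Sweeping the cutoff from
`A_mode − 0.6` downward, the fraction of Z-called scaffolds that map to the
reference Z chromosome rises and then plateaus once essentially only true
Z scaffolds remain. The calibration returns the most lenient cutoff at
which the fraction's rise over the next 0.1 log2 units drops below one
percentage point (sweep step 0.02, at least 10 Z calls per evaluated
cutoff). The plateau in the source analyses was judged visually; these
defaults make the judgement reproducible, and a manually chosen cutoff can
always be supplied instead (`StringentConfig.z_cutoff`). If the curve is
still rising at the strict end, a warning is issued and the strictest swept
value returned.

Stringent Z calls additionally require grouped female depth strictly below
the median grouped female depth (a single-copy chromosome cannot be
female-coverage-rich); stringent autosomal calls require the ratio above
the 10th percentile of ratios among scaffolds assigned to reference
autosomes. A scaffold meeting the Z conditions is Z even if it also clears
the autosomal floor (the conditions can only overlap when the calibrated
cutoff is lenient, and the Z evidence is the specific one). Everything else
is unclassified; stringent therefore trades classified fraction for purity,
and on noisy data its unclassified fraction rises relative to lenient.

## Chromosome assignment and homology tests

Tabular ortholog hits (reference gene, scaffold, interval, alignment score)
are filtered to a minimum score of 50 and one best location per gene, with
deterministic tie-breaking (lexicographically smallest scaffold, then
leftmost interval). Within a scaffold, genes overlapping a higher-scoring
gene by strictly more than 20 bp are dropped; resolution is a greedy
score-descending sweep, which on small cases provably equals the fixpoint
of the pairwise rule (verified against exhaustive subset search in the
tests). Each scaffold is assigned to the chromosome contributing the most
surviving genes; count ties go to the larger summed score, and double ties
leave the scaffold unassigned.

Per chromosome, a one-tailed Wilcoxon rank-sum test checks that
reference-Z-assigned scaffolds have lower `Log2(F/M)` than scaffolds of
each autosome. A chromosome is flagged as neo-Z when its ratios are
indistinguishable from the reference Z's *and* significantly lower than
every non-candidate autosome's. The similarity screen is two-sided and
Bonferroni-corrected across the tested chromosomes: with ~30 chromosomes
and ~100 scaffolds per group, an uncorrected non-significance rule would
reject a true neo-Z at the type-I rate of the similarity test. Raw P
values are reported alongside a Bonferroni column; groups under 10
scaffolds are skipped. Sliding profiles along a reference chromosome are
10-scaffold moving averages of the ratio, with scaffolds ordered by their
best hit's reference position.

## Gene movement on the four-species tree

Per-species classifications are combined into a gene × species linkage
matrix over the fixed rooted topology
`(((bmori, cohridella), ndegeerella), tsylvina)` — two ditrysian species,
an adelid, and the deepest lineage as outgroup. The topology is hard-coded:
it is the known backbone, not a quantity to re-estimate here. Genes inherit
their scaffold's label; only genes classified Z or A in all four species
enter the inference.

The polarisation is deliberately rule-based (parsimony-style), not a
likelihood reconstruction:

* **ancestral Z** — Z in the outgroup and in at least one other lineage;
* **Z at the Ditrysia+Adelidae node** — the ancestral set plus genes Z in
  the adelid and both Ditrysia (but not the outgroup); those extra genes
  are gains on the internal branch, which cannot be polarised further;
* **gain at the Ditrysia root** — Z in the two Ditrysia only;
* **terminal gains** — Z in exactly one non-outgroup species;
* **losses** — the mirror rules with A substituted for Z, applied to
  ancestral-Z genes; loss in both Ditrysia is a single root loss;
* **unpolarised** — Z in the outgroup only (no further outgroup exists to
  place the change), reported separately and assigned to no branch.

Two patterns the verbal rules leave open (Z in two non-sister, non-Ditrysia
lineages; A in two non-sister lineages of an ancestral gene) are attributed
to the two implicated terminal branches — the minimal attribution that is
consistent with the stated rules and leaves the ancestral-node counts at
their rule-defined values. The complete 16-pattern table ships as
`movement.PATTERN_RULES`; an independent per-gene oracle re-derives it in
the tests, and a property test checks equality on random matrices.

Because only a fraction of the reference Z's annotated genes survive into
the classified sample, branch counts are rescaled by the sampling fraction
(sampled / annotated reference Z genes) to chromosome-wide estimates,
reported raw and rounded to the nearest integer. Branch rates are compared
with a chi-square contingency test of moved vs not-moved per branch group
(no continuity correction; a warning suggests an exact test when an
expected cell drops below 1).

## W-candidate scan

W-derived scaffolds should have essentially no male coverage and roughly
half-autosomal female coverage. Candidates must exceed a length floor,
show per-male-library depth below a ceiling, and per-female-library depth
strictly between ¼× and 1× that library's median depth. Two presets:
lenient (1000 bp, male < 1.1×, tolerating stray mismapped reads) and
stringent (2000 bp, male depth exactly 0) for shortlisting in fragmented,
low-coverage assemblies. Female medians are computed per library over all
scaffolds of at least 200 bp — the assembly's own length floor, *not* the
classification prefilter, whose male-coverage floor would discard every W
scaffold before the scan. All inequalities are strict. A grouped-female
median variant is available (`grouped_female_median=True`) for designs
where single-library medians are unstable.

## Sexing unlabelled samples

Given a classification built from other individuals, a library is sexed by
a one-tailed rank-sum test of its Z-scaffold depths against its autosomal
depths: significantly lower (default α = 0.05) means one Z copy → female;
otherwise male. Fewer than 30 depth-bearing scaffolds in either class
yields an indeterminate call. Depths enter raw (the test is rank-based);
an optional median normalisation exists for cross-library comparisons. The
call is dosage-only: Z0 and ZW females are indistinguishable here.

## The synthetic-data generator

The generator emulates the study conditions this pipeline targets, with
full planted truth:

* **karyotype** — 31 chromosomes, Z = chr1, optional W and neo-Z; ~3.7% of
  genes Z-linked (the reference Z's share), W gene-free;
* **assembly** — log-normal scaffold lengths (default ln-mean 8.3, ln-sd
  1.0, median ≈ 4 kb) floored at 200 bp, mimicking a short-read assembly;
  scaffolds apportioned to chromosomes by largest remainder, so realised
  fractions track configured ones;
* **coverage** — expected depth per library: autosomes 1×, Z/neo-Z ½× in
  females, W ½× in females and 0 in males (default 40× autosomal per
  library, one library per sex). Noise is negative-binomial on read
  counts with per-125-bp-window overdispersion α (default 0.15); windows
  average out, so a scaffold of length L has effective dispersion
  α·125/L — long scaffolds are tight, short ones noisy, matching real
  depth data. α = 0 is the exact noise-free limit. A small fraction
  (0.5%) of scaffolds are collapsed-repeat outliers with 25× depth in both
  sexes, exercising the percentile cap;
* **ortholog hits** — each gene's best hit lands length-weighted on a
  scaffold of its own chromosome with score 80–200; 10% of genes get an
  extra lower-scoring spurious hit, exercising best-hit filtering;
* **linkage matrices** — genes start ancestrally Z (3.7%) or A, then
  planted `MovementEvent`s flip states on the implicated species; an
  optional missing-data fraction masks states to U. In the noise-free
  setting inference recovers the planted counts exactly, and the tests
  assert it.

The observed per-scaffold depth variance of the source data was never
published, so the dispersion default is a calibration choice, set to
produce the visible spread of real coverage-ratio plots (a few tenths of a
log2 unit for kb-scale scaffolds).

What the generator does **not** emulate: read-level artifacts (mapping
bias, GC bias, PCR duplicates), sequence content, repeat architecture
beyond flat depth outliers, mis-assembly chimeras, and cross-chromosome
ortholog contamination. Passing tests therefore demonstrate correctness of
the decision rules under dosage logic with realistic noise, not robustness
to every artifact of real short-read data.

## Numerical and scale choices

All decision inequalities are strict, as specified by the rules they
implement; boundary values fall into the unclassified gap. Histogram range
is `[min, max]` of the finite ratios with equal-width bins. Rank-sum tests
use `scipy.stats.mannwhitneyu` (tie-corrected normal approximation at
these group sizes); chi-square uses `scipy.stats.chi2_contingency` without
continuity correction. Deterministic tie-breaks are documented at each
operation (best hits: scaffold id then position; chromosome votes: summed
score then unassigned). All randomness flows from a single integer seed
per simulation; reruns are byte-identical.

The analysis drivers and test suite run on genomes of 1.5–5k scaffolds and
libraries of a few hundred genes; these sizes give every statistic ample
resolution (group sizes of 100+ scaffolds per chromosome test, binomial
errors well under the asserted tolerances) while keeping each script to
seconds.

## Known limitations

* The neo-Z compound decision reconstructs an informally stated rule;
  chromosomes genuinely intermediate between Z and autosomal dose (partial
  fusions, large inversions) may be flagged inconsistently.
* Gene-level classification is inherited from scaffolds; chimeric
  scaffolds would propagate their mis-assignment.
* Losses on double-loss patterns are attributed minimally; a likelihood
  model could weigh alternatives but is deliberately out of scope.
* The sex caller assumes the classification was built without the tested
  library; re-using the same library biases Z-scaffold depths and weakens
  the call.
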