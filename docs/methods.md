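# Methods

## Design under analysis

The pipeline targets a factorial drying experiment: G genotypes (default
four, labelled Ba12, Ba99, Bf11, p194) × two tissues (leaf, root) × four
growing-medium water-content (EWC) sampling points (35, 15, 5, 1 %) × four
replicates.  Two contrast schemes are defined over the EWC points:
against-reference (AR) compares the 35 % baseline with each later point
(35/15, 35/5, 35/1), time-course (TC) compares consecutive points (35/15,
15/5, 5/1).  The first comparison is shared between schemes; all
downstream bookkeeping deduplicates accordingly.

## Consensus DEG calling

A gene is called differentially expressed for a comparison only when
*every* configured caller reports |log₂ FC| > 1.2 and BH FDR ≤ 0.01 with
sign-concordant fold changes.  The threshold is read as two-sided
(|log₂ FC|, not a one-sided excess): up- and down-regulated genes are
roughly balanced in this kind of data, which a one-sided reading could not
produce.  Sign concordance is required in addition to the two thresholds
because a "DEG" whose callers disagree on direction cannot be assigned the
single direction every later stage needs.  FDR is controlled per
caller × genotype × tissue × scheme × comparison stratum, mirroring
separate per-program, per-contrast runs.  Raising either threshold, or
adding a caller, can only shrink the DEG set (tested invariant).

Two desk-scale callers are provided; the consensus rule, not the callers,
is the contribution, and K is configurable:

- **nb_wald** — per-gene negative binomial with variance μ + αμ².  The
  method-of-moments dispersion (pooled across both groups) is shrunk
  toward a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ, weighting the
  gene-wise estimate by its residual df against a prior weight of 3.  The
  Wald statistic uses the delta-method standard error of
  log₂(mean_test/mean_ref) under the NB variance.
- **lm_moderated** — two-sample t on log₂(normalized count + 0.5) with
  the residual variance moderated toward a binned-median mean–variance
  trend.  The moderation prior df is *estimated* from the spread of
  log(s²/trend) by moment matching on the scaled-F model of gene-wise
  variances (the trigamma identity): excess spread beyond what χ²_df
  sampling noise explains identifies a finite prior df; no excess gives an
  effectively infinite prior (variance fully pooled to the trend).  A
  fixed prior df (the conventional desk value is 3) can be forced via
  `prior_df`.  The estimate was chosen over a hard-coded 3 because with
  n = 4 per side a weak prior leaves the moderated t underpowered at the
  stringent 1 % FDR, which needlessly caps the sensitivity of the whole
  consensus (the intersection is only as strong as its weakest caller).

Normalization is DESeq-style median-of-ratios by default (total-count
optionally).  Genes whose normalized mean count over the compared samples
is below 1 are excluded from testing and from the enrichment background;
this low-count filter stabilises dispersion estimation.  Degenerate strata (zero variance, both group
means zero) report p = 1.  LFC uses the raw (unshrunken) group-mean ratio
with a half-pseudocount for stability at zero means.

## Trajectory classification

Per gene × genotype × scheme the three consensus directions collapse to a
3-letter code (ns→n, up→u, down→d).  A genotype-level class follows:
u-DEG (contains u, no d), d-DEG (mirror), i-DEG (both), non-DEG (`nnn`).
These four classes partition all 27 codes (checked exhaustively).

Per tissue, a genotype's **trend** set pools AR and TC evidence (DEG under
at least one scheme); the **core** set is the intersection of all trend
sets.  A core gene is labelled u when every genotype is net-up, d when
every genotype is net-down, and m (mixed) otherwise — i.e. when directions
differ across genotypes or any genotype is itself inconsistent.  Treating
a within-genotype i-DEG as forcing m is the conservative composition of
the within- and across-genotype notions, which are defined independently.

Summary bookkeeping reports per-genotype d/u/i counts and totals, the
cross-genotype arithmetic mean rounded half away from zero (the convention
that reproduces the published averages, e.g. 3040.25 → 3040 and
2716.5 → 2717), and the deduplicated across-scheme union per genotype.
Expression-category proportions pair mirrored codes (`nnd/nnu`,
`dnn/unn`, `ddd/uuu`, …); i-coded genes keep their own mirrored pairs and
are included in the denominators.  Strata with fewer DEGs than a
configurable floor (default 21) are flagged and excluded from the
cross-genotype mean ± SE, mirroring the exclusion of a 20-DEG stratum in
the motivating dataset.

## GO enrichment and sharing

Over-representation is the upper hypergeometric tail P(X ≥ a) for the
2×2 table of study × term membership — the one-sided Fisher exact test —
with BH control per scope × direction × namespace family and significance
at FDR ≤ 0.05.  Study sets are the direction partitions: d/u/i of each
genotype's trend set, d/u/m of the core set; a term may enrich several
partitions.  The background is the set of annotated genes that passed the
expression filter in that tissue — the least biased desk-scale universe,
and overridable.  Annotations count only directly assigned terms unless an
OBO file is supplied, in which case they are propagated to is_a/part_of
ancestors first.  The functional-group roll-up counts significant terms
per user-supplied group and the *union* (not sum) of their contributing
genes.

Pairwise sharing between genotype gene sets A, B is
100·|A∩B| / mean(|A|,|B|) — the average-reference convention, selectable
against `union` and `min_size` since the defining text of such figures is
usually ambiguous; the 4-way value is 100·|∩ all| / |∪ all| and can never
exceed any pairwise value.  Both are computed per direction (U, D), for
complete trend sets and, when an annotation is given, restricted to the
genes contributing to significant GO terms.

## Comparative statistics

Class-proportion tables (groups = genotypes + core, columns = u/d/i-or-m)
are tested with the uncorrected Pearson χ²; when the omnibus p < 0.05 all
pairwise 2×C sub-tables are tested and BH-adjusted at 5 % FDR.  Compact
letter displays assign letters to maximal cliques of the
non-significance graph (exact enumeration; group counts are ≤ 5), so a
significant pair shares no letter.  One-way ANOVA uses the classical F;
all-pairs comparisons use Tukey–Kramer (studentized range with unequal-n
correction).  All tests run on untransformed counts/measurements.  The
relative-water-content utility implements RWC = 100·(FW−DW)/(TW−DW) with
TW ≥ FW ≥ DW > 0 enforced.

## Synthetic data

Counts are NB(μ, α) with variance μ + αμ², dispersion α = 0.1 by default
(a typical bulk RNA-seq regime), baseline log₂ means uniform on (3, 9),
and per-sample target library sizes log-uniform on (0.5 M, 1.5 M); gene
means are rescaled per sample so the expected column sum equals the target,
which exercises normalization.  A planted fraction (default 0.1) of genes
receives a 3-letter trajectory archetype in AR semantics (letter → signed
log₂ shift of ±2.0 at EWC 15/5/1), drawn from weights favouring late
single-step responses (`nnd/nnu`), then early and sustained shapes, as in
drying time courses.  Each planted gene is assigned 1–4 carrier genotypes
(weights 0.35/0.2/0.15/0.3) and, with probability 0.25 when it has ≥ 2
carriers, a strict subset of carriers has all shifts sign-flipped —
generating the mixed (m) class.  The same trajectory is planted in both
tissues; tissue-specific responses are not simulated, so cross-tissue
contrasts of the kind a real dataset supports are outside what passing
tests demonstrate.  TC ground truth derives from differences of
consecutive AR shifts; note this makes a transient `dnn` gene genuinely
up-regulated at the TC 15/5 step, so pooled-evidence ground truth classes
are computed from both codes when scoring recovery.  The ledger records
codes, shifts, carriers and the concordant/mixed flag; identical config +
seed reproduces counts bit-exactly.

Not emulated: GC/length bias, batch effects, outlier samples,
genotype-specific effect-size distributions (a single |log₂ FC| knob), or
read-level artefacts.  Recovery results on this generator therefore bound
what the pipeline does under its own model assumptions, not under real
library-preparation noise.

## Numerical choices and problem sizes

BH is the exact step-up with stable sorting; ties share the adjusted
value.  Fisher p-values come from the hypergeometric survival function
(validated against direct enumeration for every table with N ≤ 60).
Letter displays break ties by first group index.  Recovery checks run ten
seeds of 2000 genes × 4 genotypes × 4 replicates in a single tissue —
large enough for stable rates (≈ 400 planted u/d gene-genotype pairs per
seed) while keeping the whole suite fast on one CPU; the generator's
default remains the full two-tissue design.

## Known limitations

- The in-repo callers are deliberately desk-scale; they reproduce the
  consensus-intersection semantics, not the numerical output of any
  external DE program.
- The m-class composition rule (any i-DEG genotype ⇒ m) and the sharing
  denominator are documented conventions where the field's usage is
  ambiguous; both are configurable rather than asserted.
- GO enrichment without an ontology file tests only directly annotated
  terms; hierarchical double counting between ancestor terms is the
  user's responsibility when propagation is enabled.
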