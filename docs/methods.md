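# Methods

This note documents the models, conventions and numerical choices behind
`varbench`, and what its synthetic-data tests do and do not demonstrate
about real annotation data.

## Problem setting

A pathogenicity predictor maps a variant to a real-valued score; a decision
threshold turns scores into pathogenic/benign calls. Benchmarking such
tools on a disease-specific cohort faces four complications that shape the
design here:

1. **Missingness.** Most tools score only a subset of variants (absent
   transcripts, off-panel genes, conservation tracks with gaps). A metric
   computed only on scored variants silently rewards selective tools.
2. **Threshold provenance.** Published thresholds were tuned on
   heterogeneous, disease-agnostic data and may be far from optimal for a
   specific phenotype.
3. **Circularity.** Variants used to train a tool inflate its measured
   performance when they reappear in the evaluation set (type-I
   circularity).
4. **Unlabeled variants.** The clinically interesting output is a triage
   of VUS, which by definition have no truth labels.

## Metrics

Confusion counts are computed over scored variants; unscored variants
enter only through coverage `c = n_scored / n_total`. The ranking
statistic for fixed-threshold evaluation is the coverage-weighted
normalized MCC, `c · (MCC + 1) / 2`, which is 1 only for a perfect tool
with full coverage and 0.5·c for a chance-level tool. MCC uses the
standard square-rooted denominator and is defined as 0 (chance level) when
any confusion-matrix marginal is zero, so the weighted statistic stays
defined for degenerate tools. Ratio metrics with a zero denominator
(precision with no positive calls, etc.) carry an explicit undefined
marker — NaN in memory, `.` in TSV reports — never 0; ranking places
undefined below every defined value.

The multi-threshold view rank-transforms each tool's scores to [0, 1]
(mean rank for ties, sign inversion first for lower-is-pathogenic scales)
and computes the ROC curve over scored variants with tie-grouped cutpoints
and trapezoidal area. This area equals the Mann–Whitney concordance
probability with ties half-counted, which the test suite verifies against
a brute-force pairwise oracle; it is invariant under any strictly monotone
rescaling of scores, so the rank transform changes nothing about auROC and
serves only to put tools on a common scale. ROC construction is delegated
to scikit-learn's curve routine; the pairwise oracle in the tests is
independent of it. Tools whose numeric scores are artificial recodings of
categorical output are excluded from every multi-threshold analysis and
participate only at their fixed decision boundary.

Strict comparators everywhere: pathogenic iff `score > t`
(higher-is-pathogenic) or `score < t` (lower-is-pathogenic); a score equal
to the threshold is benign. Negating a tool's scores while flipping its
direction and threshold sign leaves every downstream quantity unchanged
(property-tested).

## Threshold calibration

Candidate thresholds form a uniform grid of 100 points spanning the
observed score range of the cohort (endpoints included); constant scores
are a degenerate-range error. Each candidate is scored by Fβ computed
directly from counts, `(1+β²)·TP / ((1+β²)·TP + β²·FN + FP)`, which
handles empty-call corners without special cases (defined as 0 when no
true positives are attainable). Among maximizers the most stringent
threshold wins — fewest variants called pathogenic, residual ties broken
toward the stringent end of the grid — a deterministic, clinically
conservative default.

Bootstrap: each of the replicates (default 1,000) draws exactly
n_pathogenic and n_benign scored variants with replacement within class,
so the class ratio is preserved literally; the grid is re-laid over each
replicate's own observed range and the best threshold re-derived. The
reported interval is the 0.025/0.975 empirical quantile pair, and a
reference threshold outside the closed interval is flagged. Note that the
stringent tie rule places each replicate's threshold just below that
replicate's smallest pathogenic score, so replicate thresholds are
guaranteed to separate their own replicate, not to stay between the
original sample's class extremes.

Calibration uses scored variants only; coverage deliberately does not
enter (it re-enters when calibrated thresholds feed the ranking).

## Cohort construction

Filter chains are explicit, ordered, and audited: every step records
(name, n_in, n_kept), telescoping so each output count is the next input
count. The ClinVar-style chain keeps records matching at least one
configured disease-ontology identifier, meeting a review-star floor
(default 1 star for benchmark cohorts; 2 is the conventional floor for
descriptive summaries), not carrying an excluded significance (uncertain
or conflicting interpretations by default), and labels survivors by P/LP
vs B/LB. The population-database benign chain applies a strict allele
frequency floor (default AF > 0.001), a gene-panel restriction, missense
selection (substring match on the picked consequence, so compound terms
like `missense_variant&splice_region_variant` are kept), single-gene
over-representation exclusions, and overlap exclusion against other
cohorts, then splits survivors into seeded disjoint subsets; leftover
survivors are retained and logged as unassigned. All sub-filters are
conjunctive and idempotent, so their order affects only the audit trail,
not the result (property-tested).

Circularity control removes any variant whose key appears in the union of
per-tool training-set key lists; recency filtering keeps variants first
reported strictly after a user-supplied cutoff date, dropping undated
records (they cannot prove recency; the count is logged). Merging cohorts
is a key-level union where the first-listed cohort's record wins
collisions (its curated metadata is assumed richest); conflicting labels
are an error unless deduplication is explicitly requested.

Variants are keyed by `(chrom, pos, ref, alt)` after multi-allelic
decomposition; no left-alignment or other normalization is applied because
all inputs are assumed to come from one annotation pipeline on one genome
build (a config property, metadata only — no liftover). When a tool
reports several scores for one variant, the picked transcript's value is
used; residual multi-value annotations collapse to the most deleterious
value under the tool's direction (worst-case clinical convention, logged).
Transcript picking follows the order: has CCDS id → canonical flag →
protein-coding biotype → rank.

## Ranking and VUS triage

Fixed-threshold tables rank by coverage-weighted normalized MCC with ties
broken by higher coverage then tool name; ROC tables rank by auROC and
exclude tools scoring fewer than half the variants (they are listed with
reasons, not silently dropped). Cross-dataset selection averages each
tool's rank over the tables, optionally weighted by labeled-cohort size;
a tool missing from a table receives that table's worst rank + 1 —
penalized but not disqualified. VUS triage classifies each variant with
every selected tool that scored it and reports the agreement fraction with
the *scored-tool* denominator (a flagged per-row count makes the
alternative fixed-panel denominator computable); tiers are unanimous
pathogenic, majority pathogenic (fraction strictly above 0.5), majority
benign, and unscored (excluded from percentage summaries).

## Synthetic data

The generator emulates exactly what the pipeline consumes: annotated VCFs
whose CSQ block carries per-tool scores, with class-conditional parametric
score distributions (normal, beta, or two-component mixtures — enough to
model separability, heavy overlap, direction inversion and missingness),
per-class missing-score probabilities, and a weighted gene pool whose
default is dominated by a single disease gene (mirroring the skew of real
pathogenic cohorts, against more uniformly spread benign variants).
Variants live on a fictional contig `chrS` with sequential positions and
random ref≠alt bases, so nothing resembles a real locus. VUS rows carry
scores drawn from an equal mixture of the two class distributions. With a
fixed seed, output files are byte-identical across runs.

`analytic_optimum` returns the score where the prevalence-weighted class
densities cross (dense sign-scan plus Brent root refinement between the
class means); for equal-variance normals at equal prevalence this is the
midpoint of the means. It is the recovery target for F1 grid calibration:
at 1,000 variants per class the calibrated threshold lands within about
two grid steps of the crossing for well-separated profiles. Two caveats
temper this: the population F1 maximizer is close to, but not identical
with, the density crossing (F1 weighs false positives and false negatives
through precision and recall, not through total error — for the
equal-variance normal pair two units apart it sits near 0.84 rather than
1.0, under two grid steps away), and the empirical F1 curve is flat near
its maximum, so the argmax of any single draw carries sampling noise of
about a grid step. Individual seeds can therefore land slightly outside
the two-step band, and the bootstrap interval around the F1 optimum does
not always cover the density crossing.

What passing synthetic tests do **not** show: real annotation files have
correlated tools (meta-predictors ingest their competitors), per-transcript
score multiplicity, structured rather than independent missingness, and
label noise; none of these are modeled. The synthetic results validate the
machinery — metric arithmetic, chain audits, calibration, determinism —
not any claim about which real tool is best.

## Problem sizes and defaults

Defaults follow the method's own conventions: grid of 100 thresholds,
β ∈ {0.5, 1, 1.5}, 1,000 bootstrap replicates, 0.025/0.975 quantiles,
ROC coverage floor 0.5, AF floor 0.001, review-star floor 1. The test
suite and the acceptance script use smaller cohorts (tens to hundreds of
variants per class) and 15–200 bootstrap replicates, sizes chosen so the
whole verification runs in seconds while leaving the statistical checks
(binomial bounds on missingness, two-grid-step recovery, bootstrap
coverage) comfortably discriminative.

## Known limitations

- No VCF left-alignment or allele normalization; inputs from mixed
  annotation pipelines may mis-key.
- Categorical tools are handled through a fixed label→number map and
  excluded from calibration/ROC; there is no ordinal-model alternative.
- The bootstrap quantifies resampling stability only; it does not model
  cohort-selection bias.
- Meta-predictor construction from combined scores is out of scope, as is
  running any predictor or retrieving external databases.
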