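# Methods

This note documents the statistical procedures implemented in `losirf`, the
choices made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## The model and its assumptions

The pipeline targets *threshold epistasis*: a trait contribution that appears
only when two (or more) loci simultaneously satisfy a carrier condition, a
switch-like form common in biomolecular interactions and exactly the class of
structure a decision tree represents. The underlying assumptions are:

* genotypes are complete additive dosages in {0, 1, 2} (inputs are post-QC;
  any residual missingness is mean-imputed at load time);
* the trait is continuous, with covariate and sex effects that are nuisance
  structure, not signal;
* single-variant importances are unstable under LD, so interpretation happens
  at the level of *loci* — non-overlapping groups of variants defined by an
  externally supplied variant→locus map — while tree fitting happens at the
  variant level;
* signal is weak: the forest is expected to achieve only modestly-better-than-
  chance classification, which is why every interpretation step is gated and
  stability-filtered rather than read off a single fit.

## Pipeline stages and defaults

| Stage | Parameter | Default | Note |
|---|---|---|---|
| screen | top-k per ranking table | 1000 | union over tables, no clumping |
| screen | INT offset | Blom (3/8) | average ranks for ties |
| binarize | tail fractions | 0.15, 0.20, 0.25 | per sex; ⌊x·n_sex⌋ per tail |
| forest | trees / iterations | 500 / 3 | iteration t weights ∝ iteration t−1 MDI importance |
| forest | mtry | ⌈√p⌉ | weighted sampling without replacement (Gumbel top-k) |
| forest | min node size | 1 | library default; pipelines may raise it (see below) |
| RIT | depth / trees / children / min size | 3 / 500 / 5 / 1 | paths sampled ∝ class-1 leaf count |
| stability | bootstrap replicates | 50 | filter: stability > 0.5, smip > 0, sfsd > 0 |
| test | permutations | 10,000 | difference in means, two-sided, add-one rule |
| rank | shortlist / p cutoff | top 25 signed loci / 0.1 | stable = p < 0.1 in **every** run |

Splits mirror a 15,000/5,000/9,661 train/validation/test design with the
training set sub-split 2:1 into a fit part and a set-aside part; the
set-aside part ranks loci by mean LSI, the validation part feeds the
prediction gate and the permutation tests. Neither is ever seen by the
forest fit.

## Operationalized definitions

**Signed paths.** A root-to-leaf path is the set of its signed splits,
deduplicated per (variant, sign). A variant split at 0.5 and again at 1.5 on
one path legitimately contributes both signs. Dosage data admits only the
thresholds 0.5 and 1.5, which makes sign semantics exact: SNV⁺ from the 0.5
split means "carrier", from the 1.5 split "homozygous alternate".

**Random intersection trees.** Roots and children are drawn with probability
proportional to the leaf's target-class training count; sets surviving at any
node are candidates. When the children parameter reaches the number of
distinct paths, each node's children become the full deduplicated path set
and the per-root search is a breadth-first closure — this "saturating" mode
is exhaustive over intersections and is what the equivalence tests exercise.
Candidate prevalence is never taken from the randomized search: it is always
recomputed exactly as the weighted fraction of target-class paths containing
the set, and anti-monotonicity (a superset can never be more prevalent than a
subset) is asserted on every run.

**Stability metrics.** "Mean increase in precision" and "independence of
feature selection" are named rather than fully specified in the iterative
random forest literature; the implementable contract here is: per bootstrap
replicate, smip = precision(S) − mean over order-(K−1) sub-interactions of
their precision, where precision is the fraction of target-class samples
among samples in *all* leaves (both classes) whose paths contain the set;
sfsd = joint prevalence − product of the components' marginal prevalences.
The reported stabilities are the fractions of replicates where these are
positive. Computing precision over leaves of both classes matters: restricted
to target-class leaves the quantity degenerates toward 1 for every set and
its sign becomes noise.

**Local stability importance.** LSI(G, i) = D(G, i)/|T| with D counting
trees whose decision path for individual i (1) contains i in its terminal
node and (2) uses at least one signed variant from every signed locus of G.
Order-2 LSI is therefore bounded above by each component's order-1 LSI, a
property asserted in the tests.

**Permutation test.** Two-sided, difference in mean LSI between high and low
classes, labels shuffled among scored individuals only, empirical p with the
add-one rule p = (1 + #{|t*| ≥ |t|})/(B + 1) so p is never zero. One set of
label permutations is shared by all candidates at a threshold (seeded).

**Cross-threshold report.** A candidate missing from any binarization run is
unstable by definition (not imputed p = 1). Stable candidates are ranked by
mean p; candidates tied at the p floor are ordered by mean |observed LSI
difference| — an effect-size tie-break needed because strong synthetic
signals saturate the empirical p — then by label. Sign collapse reports a
locus or interaction at the smaller of its signed versions' mean p, which can
only decrease the reported p. Benjamini–Hochberg q-values are annotated for
transparency but play no role in ranking, as stability across thresholds is
the multiplicity control.

**Fisher enrichment table.** The annotation-enrichment test uses the standard
2×2 partition (locus vs rest of panel) × (annotation vs other annotations).
An alternative fourth cell sometimes seen in enrichment write-ups — total
minus locus total minus the locus's annotation count — does not partition
the panel; it is available behind `printed_table=True` for comparability
with tables that use it, but is not the default.

## The synthetic-data generator

LD is modeled by a latent-Gaussian copula: per block and haplotype, a shared
standard-normal factor (weight √ρ) plus independent noise is thresholded at
each variant's MAF quantile; two independent haplotypes sum to the dosage.
This yields Hardy–Weinberg dosages with exchangeable within-block correlation
and independent blocks — enough structure to stress locus aggregation and the
instability of variant-level importances. It does **not** emulate
recombination-map LD decay, population stratification, imputation
uncertainty, or rare variants; passing tests therefore demonstrate the
machinery's correctness and its behavior under block-wise LD, not performance
on cohort-scale human data. Epistasis is a product of carrier indicators
(dosage ≥ 1), matching the tree-representable interaction class; additive
effects are linear in dosage; sexes are assigned 50/50 exactly.

The reference recovery study (`planted_pair_study`) uses 4,000 individuals,
600 variants in 60 blocks of 10 (ρ = 0.5), one 0.6-SD carrier-pair
interaction, three 0.1-SD additive variants, a 0.5-SD sex offset, one 0.2-SD
covariate, unit noise, and common causal variants (MAF 0.25–0.45, reflecting
that an association screen upstream of any real input favors common
variants). Desk-scale runs use k = 100, 100 trees, forest min node size 5,
10 bootstraps, and a 2400/1000/600 split; these sizes keep a full
10-seed recovery experiment tractable on one CPU while leaving the planted
pair's recovery unambiguous.

## Numerical choices and degenerate inputs

* Mean-imputation of missing dosages rounds half up (0.667 → 1).
* Monomorphic variants in the scan receive p = 1 with infinite SE rather
  than an error; a fully degenerate (constant) trait is an error.
* Binarization resolves trait ties at a cutoff by stable (trait, id) order;
  a tie straddling the cutoff is logged.
* Top-k selection and locus ranking break ties lexicographically and log it.
* The forest requires both classes and at least one positive feature weight;
  bootstrap replicates that draw a single class are redrawn.
* All randomness flows from one master seed through `numpy` seed sequences:
  per-tree, per-replicate and per-test streams are independent and logged in
  the objects that used them.

## Known limitations

* The feature-weighted forest is this package's own implementation (no
  established Python library grows trees with per-node weighted feature
  sampling); it is validated against brute-force oracles and separable
  fixtures rather than bit-for-bit against the R reference.
* smip/sfsd follow the contract above, not necessarily the exact reference
  formulas, which the source literature does not print.
* The permutation test's empirical p is discrete (floor 1/(B+1)); ranking
  among floored candidates relies on the effect-size tie-break.
* Locus maps are taken as given; building them (positional annotation) and
  LD-aware expansion of prioritized variants are out of scope, as are the
  external enrichment services whose exports the downstream statistics
  consume.
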