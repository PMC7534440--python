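# Methods

## Model

`icamod` treats a gene-expression compendium as a linear mixture of latent
transcriptional programs.  The features x samples matrix **X** (log-scale
expression or fold changes) is decomposed as

    X = S · A

where the k columns of **S** are statistically independent source signals —
gene modules, giving the relative inclusion of each gene in each module —
and **A** holds the weight of each module in each sample.  Sources are
estimated by fixed-point negentropy-maximizing ICA (FastICA, log-cosh
contrast, tolerance 1e-4, iteration cap 200, the reference defaults).  The
central assumption is that gene-regulatory source signals are
super-Gaussian (positive excess kurtosis): ICA can then identify them,
unlike PCA, and modules may share genes, unlike hard clustering.

Before decomposition the compendium is standardized sample-wise (each
column mean 0, sd 1) and, by default, feature-wise (`row_standardize`,
mirroring the `row.norm` convention): row standardization balances total
variance between genes with subtle and with large expression changes.
Standardization uses the population sd (divide by n) throughout.  A
decomposition is deterministic given its seed; non-convergence within the
iteration cap is flagged but the result is still returned, and repeated
seeded runs can be ranked by annotation content (`select_run`: per
criterion annotation set, runs are ranked by the number of
Simes-significant annotations, and the run with the smallest summed rank
wins, earliest run on ties).

## Hemi-modules

Each component is oriented so its skewness is non-negative (flipping the
mixing row with it, so X-reconstruction is unchanged), then partitioned
into three gene sets: the positive "a" hemi-module (the more skewed side),
the negative "b" hemi-module, and excluded genes (0 in the trivalued S_p
matrix).  k components always give 2k hemi-module sets.  Thresholds are in
within-component sd units; since the literature states both "weight >= 3"
and "3 standard deviations from the mean", we standardize each component
column so the two readings coincide.

Two partitioners are provided:

* **fixed** — symmetric cutoff, default ±3 sd;
* **adaptive** — a small feed-forward network (2 inputs → 8 tanh units →
  2 outputs, lbfgs, seeded) that predicts per-component asymmetric
  thresholds (t_pos, t_neg) from the component's skewness and excess
  kurtosis.  Training examples are simulated components with known planted
  members; each is labelled with the thresholds maximizing the F1 of
  recovered vs planted members (independent sweeps of each side on a 0.1 sd
  grid, 0.5–6.0).  Training components emulate the loading vectors ICA
  recovers from a row-standardized compendium: member loadings are
  noise-attenuated correlations |w|/sqrt(w²+σ²) saturating near 1,
  background loadings are correlation sampling noise ~N(0, 1/m).  Member
  fraction (2–25%), noise level σ (log-uniform 0.05–0.8), side asymmetry
  (50–90% positive) and m (60–300) vary across examples so the predictor
  sees a realistic range of shapes.  Shapes outside the training hull are
  clamped to its boundary; a non-finite prediction falls back to ±3 with a
  warning.  On our synthetic compendia the fixed ±3 rule captures only the
  strongest members (typical member loadings sit between 1 and 3.5 sd) and
  the adaptive thresholds (≈0.8–1.2 sd for these shapes) recover planted
  members with F1 ≥ 0.93; the adaptive partitioner also finds at least as
  many significant annotations in the large majority of seeded trials.

## Annotation enrichment

Boolean annotations (GO terms, tissues, pathways, promoter/3'-UTR
oligonucleotide words — all treated identically) form a features x
annotations incidence matrix **B**.  For every hemi-module/annotation pair
we compute one-sided hypergeometric p-values with the standard
parametrization: universe = features present in the loaded expression
matrix, successes = annotated features, draws = hemi-module size;
p_over = P(overlap ≥ observed), p_under = P(overlap ≤ observed).  The
enrichment matrix **E** (rows = hemi-modules in block order m1a..mka,
m1b..mkb; columns = annotations) stores −log p_over for over-represented
pairs and +log p_under for under-represented ones (natural log; p floored
at 1e-300 to keep entries finite).  Two one-sided tests with the smaller
retained — rather than a single two-sided test — keep the sign
interpretation exact.

An annotation is *significant for a module set* when the Simes global test
over its 2k over-representation p-values rejects:
min_i { n · p_(i) / i } ≤ α, default α = 0.05.  The count of significant
annotations is the module-quality metric; depletion contributes to E but
not to the count, and the count deliberately uses annotations rather than
modules-with-at-least-one-annotation (which rewards splitting one signal
across several weak components).  BH step-up q-values and Holm step-down
adjustments are used where noted below.

## Module-weighted annotations

H = [S, −S] doubles the columns of S so each column carries per-gene
weights for one hemi-module, in the same order as E's rows.  R = H · E
then scores every gene against every annotation: annotations enriched in
the modules a gene loads on are boosted, foreign ones diminished.  R is
normalized separately for each annotation (mean 0, sd 1 across genes); the
un-normalized variant is retained for ranking annotations by the weight of
their most strongly associated gene.  Note the normalization axis: the
stated product shapes make annotations the *columns* of R, so
"per-annotation" means per-column.  Annotation-name word bias
(`word_position_bias`) tokenizes names (lowercase, split on
non-alphanumerics, drop tokens under 3 characters and a small stopword
list) and tests each word's ranks with a two-sided Mann-Whitney rank-sum;
the signed bias is the rank-biserial correlation (positive = top-biased).
The rank-sum choice is ours; any calibrated two-sample rank test would do.

## Projection

A contrast x (per-gene log fold changes, any platform) is projected onto
unit-normalized module columns: a = x · Ŝ.  Variance explained per module
is VE_i = a_i² / Σ_j a_j², and SVE_i = sign(a_i) · VE_i, so Σ|SVE| = 1
identically.  Features in the modules but missing from the contrast are
imputed as 0 (with a warning); foreign features are dropped; an all-zero
contrast is rejected.  Projection onto R (a = x · R) scores annotations
directly; significance comes from permuting x over features (uniform
permutation, seeded), default 1000 permutations, z = (score − null mean) /
null sd, with degenerate nulls flagged and reported as z = 0.

Contrast similarity is the Pearson correlation of SVE profiles over all
unordered contrast pairs (same-group pairs excludable), Holm-adjusted.
Gene-set/hemi-module enrichment reuses the hypergeometric machinery with
BH q-values across the 2k hemi-modules.

## Choosing the number of components

`evaluate_point` scores a candidate k by the Simes-significant annotation
count, averaged over seeded ICA repeats (default 5), on both the real
partitioned matrix and a feature-shuffled copy (the randomized-ID
control, which destroys the gene/annotation correspondence while keeping
module-size structure).  `select_k` smooths real and control curves over
the k grid with local linear regression (lowess, span 0.5, no robustifying
iterations — those would reject the sharp rise at the true module count as
outliers) and takes the smallest k within one annotation count (the
metric's granularity) of the maximal smoothed real-minus-control
difference; with several annotation sets the per-set optima are averaged
and rounded.  The plateau-onset tie rule matters on clean synthetic data,
where the count saturates once every planted module is resolved: extra
components past the onset buy no annotation signal.  `evaluate_point`
defaults to the fixed ±3 partitioner for this sweep: merged components at
too-small k dilute member loadings below a fixed cutoff, which makes the
curve informative, whereas adaptive thresholds keep even merged modules
fully enriched and flatten the sweep.

## Synthetic data

The generator plants k modules (default 5) of 40–60 members among 500
features; 5% of features belong to two modules.  Member weights are
Laplace (scale 1), non-members 0.  Activations are generalized-normal rows
calibrated to a target excess kurtosis (default 3 = Laplace), rejection-
sampled until the sample excess kurtosis is within ±30% of target, then
unit-standardized.  X = S·A plus Gaussian noise (default sd 0.1, small
against unit-variance module activations — a deliberately clean regime in
which recovery should succeed).  Annotations pair one per module: members
annotated with probability `annotation_fidelity` (default 0.8) plus a 1%
background; decoy annotations are membership-independent.  Contrasts are
x = S_true · w + noise.  All generators are bit-reproducible under a seed.

What the generator does **not** emulate: batch and platform effects,
probe-level artifacts, correlated noise, nested/hierarchical module
structure, realistic annotation ontology structure (term overlap and
granularity), or compendia whose module count approaches the sample count.
Passing tests therefore demonstrate correctness of the machinery and the
claimed qualitative behaviors (recovery at the true k, null behavior of
shuffled controls, noise robustness and specificity of the projection
test), not performance on real compendia.

## Test and verification scale

The suite runs the full pipeline at 500×120 with 5 modules (the default
study conditions); the hemi-module count identity uses a 2000×250
compendium at k = 209 (209 components, 418 hemi-modules); the k sweep uses
grid 2–20 with 5 repeats; noise robustness uses 10 seeds at 5× noise with
100 permutations; specificity uses 100 near-orthogonal contrast pairs; the
recapitulation check uses 20 seeds × 5 modules.  These sizes were chosen
as the smallest at which the qualitative claims are stable across seeds.

## Numerical and policy choices

* Population sd everywhere (standardization, R normalization).
* Zero-variance vectors: configurable `{drop, fail}`, default drop with a
  warning; missing values are rejected at load time.
* Zero-skewness components are left unflipped (logged).
* Simes on an empty p-value list is an error; p-values outside [0,1] are
  rejected.
* The shuffled-control study in the test-suite runs at α = 0.01: at any
  Simes level the expected null count is ≈ α × number of annotations, so
  "essentially zero significant annotations" is a statement about a strict
  level; at the analysis default α = 0.05 the null count sits at the
  α-level as expected (asserted separately).
* KS/t permutation z-scores exploit the equivalence between permuting the
  contrast over genes and permuting incidence rows, so one sort serves all
  permutations; the vectorized statistics are unit-tested against the
  scipy reference implementations.

## Known limitations

* The adaptive threshold model is trained on simulated component shapes;
  components from data with very different loading distributions (e.g.
  heavy multimodality) fall outside the training hull and are clamped.
* `select_k` assumes the annotation-count curve is rise-then-plateau (or
  rise-then-fall); adversarial non-monotone curves can mislead the
  plateau-onset rule.
* The optimizer sweeps k and standardization flags only; upstream
  preprocessing of raw arrays is out of scope, as are GO-graph-aware
  enrichment, iterated-ICA consensus clustering, and posterior membership
  probabilities.
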