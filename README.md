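# icamod

Extraction, partitioning and interpretation of transcriptional gene
modules from expression compendia by independent component analysis.

Genes that respond together across many conditions form co-expression
modules, and a large heterogeneous compendium samples enough conditions to
expose an organism's transcriptional wiring.  `icamod` is for
computational biologists who want to (1) extract such modules from a
features × samples expression matrix, (2) turn each continuous component
into discrete, annotation-testable gene sets, and (3) interpret new
experiments — a vector of per-gene log fold changes from any profiling
platform — in module space rather than gene-by-gene, which recovers
coordinated signals that per-gene significance tests miss.

## The model

The compendium **X** (features × samples) is decomposed as

    X = S · A

with **S** (features × k) the module definition matrix — statistically
independent, super-Gaussian source signals — and **A** (k × samples) the
module weights per sample (FastICA, log-cosh contrast).  Each component is
oriented to non-negative skewness and split at per-component thresholds
into an "a" (positive) and "b" (negative) hemi-module, giving a trivalued
matrix **S_p** with 2k gene sets.  Hypergeometric enrichment of Boolean
annotations **B** in every hemi-module fills the signed log-p matrix **E**
(−log p for over-, +log p for under-representation), aggregated per
annotation with the Simes test.  Module-weighted annotations are

    H = [S, −S],    R = H · E

so each gene gets a continuous relevance score for every annotation.  A
contrast **x** projects onto unit-normalized module columns,

    a = x · Ŝ,    VE_i = a_i² / Σ_j a_j²,    SVE_i = sign(a_i) · VE_i

(signed variance explained; Σ|SVE| = 1), or onto R (a = x · R) with
permutation z-scores per annotation.  An optimizer sweeps k and picks the
value maximizing the Simes-significant annotation count against
feature-shuffled controls.  A synthetic-data generator with planted
modules makes the whole pipeline testable end to end; see
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Simulate a compendium (500 genes × 120 arrays, 5 planted modules), extract
and partition modules, build module-weighted annotations, and project a
contrast that loads planted module 2:

```
icamod simulate --out-dir sim --seed 4
icamod extract --matrix sim/compendium.tsv --k 5 --runs 5 --seed 1 \
       --criteria-gmt sim/annotations.gmt --out-dir modules
icamod partition --s-matrix modules/S.tsv --adaptive --out-dir part
icamod enrich --s-p part/S_p.tsv --gmt sim/annotations.gmt --out-dir enr
icamod weight --s-matrix modules/S.tsv --e-matrix enr/E.tsv --out R.tsv
icamod project --contrast fc.tsv --modules modules/S.tsv --out sve.tsv
icamod project-weighted --contrast fc.tsv --weights R.tsv --n-perm 1000 \
       --seed 2 --out pw.tsv
```

The log reports `selected run 0 of 5 by combined annotation rank`, `10
hemi-modules` and `7/50 annotations significant` (the 5 module-paired
annotations plus two α-level false positives at α = 0.05).  `sve.tsv`
shows the contrast's activity concentrated in one module — component `m3`
is the extracted copy of planted module 2 (component order is arbitrary):

```
module  a             VE             SVE
m3      7.78401571051 0.99824719924  0.99824719924
m4      0.31760657779 0.00166191829  0.00166191829
m1      0.06239946164 6.41493674e-05 6.41493674e-05
```

SVE is the signed fraction of the contrast's projected variance explained
by each module; absolute values sum to 1.  `pw.tsv` ranks annotations by
permutation z-score:

```
annotation  score    z        degenerate
mod2_ann    167.463  15.2387  False
decoy16     -155.645 -14.2006 False
```

The module-paired annotation tops the list.  Decoys can score when they
are by chance (anti-)enriched in an active module's hemi-modules: R
transfers module structure onto annotations, which is exactly how weakly
annotated genes inherit signal — and why decoy calibration is part of the
test-suite.

The same analyses are available as library functions (`icamod.decompose`,
`model_partition`, `build_E`, `build_R`, `project`, `project_weighted`,
`evaluate_point` / `select_k`, ...), which the CLI wraps thinly.

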