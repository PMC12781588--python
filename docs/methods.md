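# Methods

## Overview

episignkit implements the two analytic arms of a rare-disorder methylation
study: (1) discovery, validation and classification of a blood DNA-methylation
*episignature* — a reproducible probe-level methylation pattern associated
with a genetic disorder — and (2) carrier-level burden testing of ultrarare
protein-coding variants across protein domains. Because real discovery
cohorts (patient EPIC arrays and a proprietary reference database) cannot be
redistributed, the package ships a synthetic-data generator whose outputs
carry the statistical structure the analysis assumes, with planted ground
truth, so every stage is quantitatively testable.

## Differential methylation model

Per probe, the beta value (fraction methylated signal, in [0, 1]) is
regressed by ordinary least squares on an intercept, a case indicator, and
estimated blood-cell fractions (all but one type, since fractions sum to 1):

    beta_ps = b0_p + b1_p * case_s + sum_t g_pt * f_st + e_ps

The group coefficient `b1` is the adjusted effect; the reported `delta_beta`
is the raw case-minus-control mean difference (the quantity the downstream
5% effect filter is defined on). Residual variances are moderated by an
empirical-Bayes scaled-F prior: the prior `(d0, s0^2)` is fitted by matching
the mean and variance of `log(sigma^2)` to the theoretical moments of log
scaled-F variates through digamma/trigamma relations, with the trigamma
inverse solved by Newton iteration. When the empirical spread of log
variances does not exceed the sampling floor `trigamma(dof/2)`, the prior is
degenerate (`d0 = +inf`) and `s0^2` is the bias-corrected geometric mean.
Moderated t-statistics use the posterior variance
`(d0*s0^2 + dof*sigma^2)/(d0 + dof)` on `d0 + dof` degrees of freedom
(standard normal when `d0` is infinite). Multiple testing uses
Benjamini–Hochberg step-up adjustment; the implementation accepts a battery
size `m` larger than the number of supplied p-values, which the variant arm
needs for its fixed 17-test battery.

Beta values are modelled directly (no M-value transform) because the effect
filter and reported differences are on the beta scale; an analyst wanting
M-value statistics can transform upstream.

## Probe-selection funnel

1. **Effect floor** — probes with `|delta_beta| < 0.05` are excluded; the
   boundary is inclusive (0.05 is retained, 0.049 is not).
2. **Composite ranking** — remaining probes are ordered by
   `|delta_beta| * (-log10 p_adj)` (adjusted p floored at 1e-300), ties
   broken by larger `|delta_beta|`, then lexicographic probe id, making the
   funnel invariant to input order. The top 1000 (configurable 800–1000) are
   kept.
3. **ROC refinement** — per-probe AUC is the Mann–Whitney U statistic over
   case/control pairs (ties 0.5), folded to `max(AUC, 1-AUC)` so hypo- and
   hypermethylated probes are treated alike; probes below 0.85 (default) are
   dropped. The threshold is a package default — only "high AUC" is
   prescribed by the source methodology.
4. **Correlation pruning** — a greedy scan in rank order keeps a probe iff
   its absolute Pearson correlation with every already-kept probe is ≤ 0.85
   (default), computed on training samples only; zero-variance probes
   correlate as 0 with a warning.

A final count outside 160–500 warns but does not error. The ROC step follows
the top-N cut (the order the source text implies); both thresholds are
exposed in `SelectionParams`.

## MVP classification

The methylation-variant-pathogenicity (MVP) score is the calibrated
probability that a sample matches the episignature. The reference database
(samples from other episignature-positive disorders plus unaffected
individuals) is partitioned into four seeded folds. Fold k's model is a
linear-kernel SVM (cost 1.0, class weights inversely proportional to class
size) trained on cases + matched controls + the other three folds, cases
labelled 1 against everything else, with Platt-style logistic calibration of
the training margins. Database samples are scored only by their held-out
fold's model (each serves as a test sample exactly once); external or query
samples receive the mean probability over all four folds — the "average
SVM". Call thresholds default to positive ≥ 0.5 and negative ≤ 0.1 and are
configurable; published positive scores cluster near 0.985 and negatives
below 0.46, so the defaults sit inside the empirical gap.

Matched training cases/controls stay fixed across folds; only the database
rotates. Missing signature probes at scoring time are imputed from the
training reference means (warning), erroring above 5% missing.

Leave-one-out cross-validation repeats the *entire* procedure — differential
analysis, funnel, training — without each case and scores it on the
resulting model. A fold whose funnel selects nothing has no signature to
match, so its held-out case is recorded as 0.0 with `fold_failed=True`;
this keeps LOOCV defined on signal-free cohorts.

Diagnostics: classical (Torgerson) MDS — double-centred squared-distance
matrix, top-two eigenvectors, sign fixed so the first sample is non-negative
on each axis — and Ward/Euclidean hierarchical clustering with samples
pre-sorted by id so equal-height merges resolve deterministically.

## Cross-cohort comparison and probe context

Signature overlap between cohorts A and B is
`100 * |top500(A) ∩ top500(B)| / |top500(A)|` — the denominator is the row
cohort, so the matrix is asymmetric when DMP counts differ. Cohort trees use
average-linkage clustering of signed delta-beta vectors over the union of
top DMPs (absent probes contribute 0), Euclidean distance, serialized to
Newick. Probes are classified against CpG islands as island / shore (≤ 2 kb
from an island edge) / shelf (2–4 kb) / inter-CGI, nearest island governing
with ties to the smaller coordinate, and against gene-model parts with
priority promoter > 5'UTR > CDS > 3'UTR > intron > intergenic (promoters are
2 kb upstream of the TSS, strand-aware).

## Variant burden testing

Variants are prefiltered to ultrarare (minor allele count ≤ 2 in every
reference panel), collapsed into PTV (stop-gain, frameshift, canonical
splice), PAV (missense, in-frame indel) and SYN classes, and flagged
splice-altering at SpliceAI ≥ 0.5. In-silico pathogenicity (PP3) tiers come
from per-tool threshold ladders (REVEL/CADD/MPC, editable configuration
following published calibration conventions); the combined tier is the modal
tier across available tools, ties resolved toward the weaker tier. Domain
annotation uses 1-based inclusive protein coordinates: disulfide disruption
(reference cysteine at an annotated bonded position), novel cysteine
creation, feature-interval membership, and ligand-site vicinity (core
residues 420–421, 448–452, 469 expanded ± 5).

Each of 17 scenarios defines carriers (≥ 1 qualifying variant, counted once
per sample); the 2×2 carrier table is tested with a two-sided Fisher exact
test (summing tables at fixed margins with probability ≤ observed). The
headline odds ratio is the sample cross-product ratio `ad/bc` (infinite when
`bc = 0`), matching the published table convention; the conditional-MLE OR
and its exact conditional 95% CI are also computed (the conditional MLE is
what an R `fisher.test` prints in-text). BH adjustment runs with m fixed at
the battery size of 17.

The bundled protein feature table is a synthetic emulation of a
single-pass-receptor annotation (EGF-like repeats, LNR, HD, RAM, ankyrin,
TAD, PEST, PSEN-interaction, explicit disulfide pairs, ligand-contact
residues, length 2555); it supports the domain logic and tests but is not a
curated database export.

## Synthetic data generator

Beta values are logit-normal: probe baselines are bimodal (mixtures near 0
and 1, as on real arrays), and a planted probe's case shift is computed on
the beta scale so the expected case-minus-control difference equals the
configured `delta` (default 0.15), signs split 50/50 hypo/hyper
(configurable skew). Nuisance structure: per-batch probe shifts (logit SD
0.05), blood-cell composition drawn from a granulocyte-dominated Dirichlet
with per-probe loadings on a 20% probe subset (so omitting cell covariates
on a composition-confounded configuration measurably inflates false
positives), and logit-scale Gaussian noise (SD 0.3). Database samples follow
the control model plus their own disjoint planted signatures per synthetic
"disorder". Detection-p failures cluster in a small set of unreliable probes
(2% of probes failing 10% of the time, 0.2% of entries overall) rather than
spreading uniformly, mirroring how failures arise on arrays. Control sex and
batch mirror the case list cyclically so the matched-control pool always
covers each case at the default 4:1 ratio — the matched design the analysis
assumes.

What the generator does *not* emulate: raw intensity chemistry (probe type
I/II, dye bias), spatial batch artefacts, age/sex methylation trends,
genotype-driven outlier probes, and correlated probe blocks within CpG
islands. Passing recovery tests therefore demonstrates that the pipeline
finds planted mean-shift signals under composition and batch confounding at
realistic noise — not that it is robust to every artefact of real arrays.

## Default study conditions and problem sizes

Simulated discovery cohorts default to 16 cases vs 64 matched controls —
the scale of a small rare-disorder discovery group — with a 300-probe
signature on a 50,000-probe array (a scaled-down array; the analysis is
per-probe, so probe count affects only multiplicity). The acceptance script
measures planted-probe recovery at the full 50k over five seeds, MVP ranking
on 100 held-out case/control pairs at 20k probes, and null behaviour at 20k
(selection) and 5k (LOOCV) probes; these sizes are the package's own
trade-off between resolution and turnaround, and results are stable across
seeds.

## Numerical choices and degenerate inputs

- `p_adj = 0` is floored at 1e-300 before `log10`.
- Trigamma inversion: Newton from `x = 0.5 + 1/y`, 50 iterations max,
  relative tolerance 1e-10.
- Zero-variance probes: `sigma2` clipped at 0; moderated t defined as 0 when
  the posterior standard error is 0; pruning treats their correlation as 0.
- All-zero contingency margins: p = 1, odds ratio flagged undefined.
- Ages are matched greedily (nearest absolute difference, pool order on
  ties) after exact sex/batch agreement; greedy (not optimal) matching is
  deliberate — it is deterministic, order-stable, and mirrors the
  nearest-neighbour default of the standard matching tools.

## Known limitations

- The funnel is a single pass; no iterative re-selection.
- Reference-based cell-composition estimation is not implemented; cell
  fractions must be supplied (or the model runs unadjusted, with a warning).
- The BH-adjusted scenario p-values follow the stated step-up procedure; a
  published table computed as raw p × m will differ for ranks ≥ 2.
- Real-world episignature classifiers are trained against databases of many
  disorders; the synthetic database here is a small stand-in and MVP scores
  on it should be read as qualitative behaviour, not calibrated
  probabilities for any real disorder.
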