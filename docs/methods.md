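# Methods

This note documents the models and procedures behind `cpdr`, the choices
made where the design was genuinely open, and what the synthetic test
scenarios do and do not demonstrate.

## Problem setting

Given one patient's bulk tumor RNA-seq profile and a reference cohort of
the same cancer type, the pipeline recommends drugs whose transcriptional
perturbation signatures *reverse* the patient's disease signature. An
individual profile alone cannot support differential expression, so the
patient is represented by a *subgroup* of cohort samples with similar
transcriptomes — pseudo-replicates — and the disease signature is the
subgroup-vs-normal differential expression result. The connectivity-map
machinery then scores each drug treatment for signature reversal, and
reversal predictions are sanity-checked in silico against cell-line
drug-sensitivity data.

## Subtyping and subgroup selection

Cancer subtypes are found by consensus non-negative matrix factorization
(NMF) on the cohort's 1,500 most variant genes (sample variance on
log2(x+1) values; ties break lexicographically by gene symbol so the panel
is deterministic).

For each candidate rank k (default 2–6), 30 NMF factorizations
(multiplicative updates, Frobenius objective, random non-negative
initialization, max 500 iterations, relative tolerance 1e-5; all run seeds
derive from one user seed) each assign every sample to its argmax metagene.
The fraction of runs in which two samples co-cluster is the consensus
matrix; final labels per k come from average-linkage hierarchical
clustering of 1 − consensus. The chosen k maximizes the cophenetic
correlation of that hierarchy, with average silhouette width (on the
consensus distance) as the tie-breaker and the smaller k as the final
deterministic tie-break. Published NMF-consensus practice "considers" both
metrics without a rule; this ordering makes the choice reproducible.

The patient is assigned to the subtype with the largest *median* Spearman
correlation (over the variant-gene panel) between the patient and the
subtype's samples; the subgroup is the top-N most correlated samples of
that subtype. N defaults to 5, the middle of the supported replicate sizes
{3, 5, 10}. Because Spearman correlation is rank-based, the patient profile
may be supplied as counts or log2 values.

Controls are the N normal samples maximizing the median Spearman
correlation to the subgroup over the same gene panel. This is a deliberate
proxy for embedding-based control matching: it needs no trained encoder,
is deterministic, and selects normals whose global expression ranking best
tracks the subgroup.

## Infiltration scoring and purification

Stromal/immune infiltration is scored per sample by single-sample gene set
enrichment (ssGSEA): genes are ordered by descending expression; walking
down the list the running sum gains `rank^0.25` (normalized over in-set
genes; the rank statistic gives the highest-expressed gene rank n, so
strongly expressed in-set genes weigh more) and loses `1/(n−t)` at
out-of-set genes. The reported score is the *integrated* running sum, not
the maximum deviation — the integrated form is smoother for small sets and
is noted here because both variants exist in the field. Scores depend only
on within-sample ranks (asserted by tests).

A subgroup is flagged "high infiltration" when its mean stromal+immune
score exceeds the cohort's 75th percentile (configurable quantile q;
no absolute threshold exists for these unitless scores).

Purification deconvolves each flagged tumor profile on the linear scale
(2^x − 1): y ≈ N·w + c with w ≥ 0 over the normal profiles, scalar c ≥ 0,
and contamination fraction α = Σw capped at 0.99. The fit is non-negative
least squares, switching to an SLSQP quadratic program (on the scaled
normal equations) only when the cap binds. The purified cancer profile is
log2(1 + max(0, y − N·w)/(1 − α)); clipping guarantees non-negative linear
expression, and the cap keeps the rescaling finite when a tumor is
indistinguishable from normal. This is a deliberately desk-scale,
convex-combination simplification of full Bayesian deconvolution; it
carries no priors, so α is only identifiable when the cancer component is
not collinear with the normal profiles (see the generator notes below).

## Disease signature

Counts are normalized to log2(CPM+1); each gene gets a Welch t-test
(case vs control) and Benjamini–Hochberg FDR. All-zero count rows are
dropped (logged). Zero-variance genes receive p = 1 when the group means
agree and p = 0 otherwise, so degenerate constant genes cannot crash a run.
The signature keeps genes with FDR < 0.05 and |log2FC| ≥ 1, split by sign,
each side truncated to the 100 largest |log2FC| (ties by symbol). The cap
prevents KS degeneracy on very large tag lists; all three thresholds are
configurable because no canonical values exist. The DE step is a plain
callable interface, so moderated-variance methods can be plugged in; the
built-in Welch test is the reference implementation.

## Reversal scoring

For a tag list with sorted universe ranks V(1) < … < V(t) in a ranking of
n genes (rank 1 = most up-regulated by the drug):

    a = max_j ( j/t − V(j)/n )        b = max_j ( V(j)/n − (j−1)/t )

es = +a if a > b, −b if b > a, and +a on an exact tie (the tie is a measure-
zero event; the sign choice is arbitrary but fixed). Tag genes absent from
the perturbation universe are dropped first; fewer than 5 remaining genes
reject the tag list for that record (configurable `min_overlap`).

RGES = es_up − es_down when the two enrichments disagree in sign, else 0
(the classic connectivity convention: a drug that moves both halves of the
signature the same way is a non-match). Negative RGES means reversal.
RGES is bounded in [−2, 2].

Treatments are standardized to the reference condition (10 µM, 24 h) by a
*reward model*: dose is classed low/high at 10 µM and time short/long at
24 h, and each non-reference class gets an additive offset estimated as the
mean, over drugs measured in both the reference and that class, of
(mean reference RGES − mean class RGES). Classes with no paired drug keep
offset 0, so an all-reference library degrades to plain means. The offsets
are estimated from the library itself rather than hard-coded, because the
published reward constants were calibrated to one specific perturbation
collection. sRGES is the unweighted mean of standardized RGES over a
drug's treatments (no cell-line weighting; one summary per drug; lower =
stronger reversal).

## In-silico validation

* The patient-relevant cell line is the panel line with the highest
  Spearman correlation to the patient over the panel's 1,500 most variant
  genes (ties to the smallest identifier).
* On that line, drugs with AUC ≤ mean − 0.5·SD (sample SD, inclusive
  threshold) are "effective"; if every AUC is equal the threshold equals
  the mean and all drugs are (vacuously) effective — a logged degenerate
  case rather than an error.
* Validation reports (a) Pearson r between sRGES and AUC over the shared
  drugs (at least 3 required), (b) a Welch t-test of sRGES between
  effective and ineffective drugs (reported as not-applicable when one
  class is empty), and (c) a permutation null: random same-size subgroups
  are drawn, pushed through the full subgroup→signature→sRGES pipeline,
  and correlated with the AUCs; the one-sample t-test of the null sample
  against the observed r gives the significance. Replicates whose random
  subgroup yields no signature, or constant score vectors, contribute
  r = 0 with a warning — a convention that keeps degenerate draws from
  aborting a run. Null subgroups may be drawn from the assigned subtype or
  from the whole cohort; the end-to-end scenario uses the cohort-wide
  draw, which matches the intent of permuting the patient–subgroup
  relationship.
* Responder analysis: Welch t-test of per-patient sRGES between
  responders and non-responders, and ROC AUC via the Mann–Whitney
  identity with lower sRGES ranked as more responder-like (ties count
  half; equals the trapezoidal ROC integral, cross-checked against an
  independent implementation in the tests).

Constant vectors in any correlation return 0 (Spearman and Pearson alike)
with a warning, never NaN.

## Synthetic study conditions

The generator (`cpdr.simulate`) produces every input with the structure
the pipeline assumes; its defaults are the standard scenario used by the
recovery tests and `scripts/acceptance.py`:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes, log-normal baseline (log2 mean 6 ≈ 64 counts, SD 1) |
| k / samples_per_subtype | 3 / 30 | planted subtypes |
| subtype_shift | 2.0 | log2 separation between subtype blocks (400 genes each, mean-centered across subtypes; normals sit at the common baseline) |
| noise_sd | 0.3 | per-gene per-sample biological log2 noise |
| signature_size / effect | 100 / 2.0 | 100 up + 100 down genes at 4-fold |
| carrier_fraction | 1/6 | fraction of the focal subtype carrying the signature |
| n_drugs / n_reversers | 20 / 5 | perturbation library composition |
| reverser_strength | 3.0 | z-shift of signature genes in reverser rankings |
| dose_time_grid | (10,24),(1,24),(10,6),(1,6) | per-drug conditions; low dose and short time each halve reversal strength |
| auc link | 0.7 + 0.25·score + N(0,0.05) | AUC vs reversal score (−1 reversers, 0 others) |
| response_noise_sd | 1.0 | label noise; gives responder ROC AUC ≈ 0.83 on average |

Counts are Poisson around the linear-scale mean. Several defaults are
coupled, deliberately:

* **Subtype blocks are mean-centered across subtypes.** Between-subtype
  separation is exactly `subtype_shift`, while each subtype deviates from
  normals by at most shift·(k−1)/k ≈ 1.33 — below the signature's |log2FC|
  of 2 — so subtype-identity genes compete with, but do not drown, the
  planted signature in the tumor-vs-normal contrast.
* **The signature is carried by a subset of the focal subtype.** The
  simulated patient is a carrier, so similarity-ranked subgroup selection
  finds carriers and recovers the signature, while a random subgroup
  rarely contains the ≥3 carriers needed to reach the fold-change
  threshold — which is what makes the permutation null concentrate near
  r = 0 and the observed correlation separable from it. If every tumor
  carried the signature, permuting the patient–subgroup relationship
  could not destroy the association and the null would be meaningless.
* **`distinct_cancer_baseline`** (purification scenario only) draws the
  cancer-cell baseline as a seeded permutation of the normal baseline,
  making it uncorrelated with the normals across genes. Without it the
  convex-combination purity model is unidentifiable — an intrinsic limit
  of prior-free least-squares deconvolution, not of the generator.

What the synthetic scenarios do **not** emulate: negative-binomial
overdispersion, gene–gene correlation beyond block structure, library-size
variation, batch effects between cohort and normals, dose–response curve
shapes, or the marginal distributions of any real compendium. Passing the
recovery tests therefore shows the pipeline is correct and well-calibrated
under its own assumptions, not that it reproduces results on real cohorts.

## Problem sizes

The recovery scenarios run at desk scale by design: 90-sample cohorts over
2,000 genes, 1,500-gene NMF panels (k = 2–6, 30 runs), 80-record
perturbation libraries over a 1,000-gene universe, 100-replicate
permutation nulls, and 20-mixture purification sets. These sizes keep the
full suite and the acceptance script fast on a single CPU while leaving
every statistic comfortably away from small-sample degeneracy.

## Known limitations

* The purification model is prior-free; on real tumors (where cancer and
  normal expression are highly correlated) its α estimates will be
  optimistic upper fits, and the infiltration flag should gate its use.
* Welch-on-logCPM has less power than moderated-variance DE methods at
  n = 3–5; the DE interface accepts replacements.
* The reward model assumes additive, drug-independent dose/time offsets.
* Gene identifiers are matched as case-sensitive symbols; no alias
  resolution is attempted.
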