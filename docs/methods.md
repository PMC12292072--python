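# Methods

## Classes and labels

The supervised problem is defined by the TRIM family registry. A pair
(TRIM, target) is labelled TRUE when the TRIM belongs to the CIV
subfamily and FALSE when it belongs to any other subfamily; both classes
are *curated, real* interactions, so the FALSE set is not a hypothesised
non-interaction set. Uncategorised (UC) members that nonetheless carry a
PRY-SPRY domain are excluded from both classes: their subfamily
assignment is unresolved and either label would blur the decision
boundary. The registry is authoritative for subfamily membership;
`classify_subfamily` recomputes the call from domain architecture (CIV =
C-terminal-most domain PRY-SPRY plus the RING/B-box + coiled-coil core)
only as a validator or fallback, because curated registries, not
structural recomputation, are how family rosters are maintained in
practice. The domain vocabulary is closed and case-insensitive; unknown
tokens raise rather than being skipped, since silently dropped domains
would corrupt labels.

## Expression preprocessing and differential expression

Proteomics (MS) matrices are log2-transformed (offset 0; a zero intensity
is treated as an error because zeros in intensity data denote
missingness — a configurable +1 offset serves count-derived inputs),
genes missing in strictly more than 50% of samples are removed (a gene
missing exactly half is kept), and remaining holes are filled by
gene-wise k-nearest-neighbour imputation (k = 10, inverse-distance
weights, distances over mutually observed columns rescaled by overlap —
the standard Troyanskaya-style configuration).

Count (RNAseq) matrices are filtered with a CPM rule — a gene must exceed
the CPM equivalent of 10 reads in the median-depth library in at least as
many samples as the smaller group — normalised by trimmed mean of
M-values (30% two-sided trim on M, 5% on A, inverse-asymptotic-variance
weights, reference = library whose upper-quartile CPM is closest to the
mean, factors rescaled to geometric mean 1), converted to log2 CPM with a
0.5 prior count, and duplicate gene symbols are averaged (first-occurrence
order). The TMM implementation reproduces the standard R implementation
to ~1e-11 on random matrices; the only known divergence is a
measure-zero tie artifact — integer count ratios that are exactly equal
in one language's `log2` but one ulp apart in another's can flip a rank
at the trim boundary, perturbing factors by ~1e-4. TMM assumes most
genes are unchanged between groups; when a majority of the transcriptome
is differentially expressed with a net direction, a residual depth shift
of a few tenths of a log2 unit remains. That is a property of the
estimator, and the synthetic cohorts used for estimator-recovery checks
keep planted DEGs a minority.

Differential expression uses an empirical-Bayes moderated t. Per gene,
the two-group pooled variance s² on d = n₁+n₂−2 degrees of freedom is
shrunk toward a prior (d₀, s₀²) estimated by moment-matching the scaled-F
model s² ~ s₀²·F(d, d₀) on the log scale (digamma/trigamma matching, with
a Newton inverse-trigamma); the statistic is t = logFC / sqrt(s²_post
(1/n₁+1/n₂)) on d+d₀ df, where s²_post = (d₀s₀² + d s²)/(d₀+d). Two
closed-form limits pin the semantics and are asserted in tests: prior df
= 0 reproduces the ordinary pooled two-sample t exactly, and prior df =
∞ with an explicit prior variance tests every gene against that common
variance. p-values are Benjamini–Hochberg adjusted; a DEG requires
p_adj < 0.01 and |logFC| above the layer cutoff — 0.5 for MS, 1.0 for
RNAseq — with logFC oriented tumour minus normal. Both layers use the
same moderated test; the prior-df limit property guards the alternative
reading in which the proteomics branch uses a plain t-test.

## Correlation screen

Every (TRIM, DEG) combination in a cancer is scored by Spearman
correlation with the t-approximation p-value
(t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df; p = 0 at |ρ| = 1) and flagged
significant at p < 0.01. Correlations are computed over **tumour samples
only** by default — the disease-context signal the screen is meant to
capture — with an `all`-samples mode available, since either reading is
defensible. The vectorised screen (rank once, one rank-Pearson matrix
product) is tied to the pairwise implementation at 1e-12 in tests.

## Feature space and classifier

A training record exists for a pair in a cancer only when the target is a
DEG there, the TRIM-target correlation is significant, and a docking
score exists; join losses are counted by cause (no DE row, not a DEG, no
correlation row, not significant, no docking). Numeric features (logFC,
R, zrank_score) are z-scored with statistics fit on training data only —
inside cross-validation, on each training split separately, which the
tests verify by fold-wise recomputation — and the cancer type is one-hot
encoded. One-hot encoding is used even though a scalar disease term would
also define a squared distance: over one-hot columns the squared distance
is 0 for same-disease and 2 for different-disease pairs, which is the
semantics a categorical covariate should have in an RBF kernel.

The classifier is a soft-margin SVM with RBF kernel (scikit-learn/libsvm
backend), classes TRUE→1 / FALSE→0. Hyperparameters default to a grid
search over C ∈ {0.1, 1, 10, 100} and γ ∈ {0.01, 0.1, 1, 10} — brackets
around the (C=1, γ=1) operating point used throughout the simulation
studies — scored by mean held-out AUC under stratified shuffled five-fold
CV (AUC rather than accuracy, because the downstream use is ranking;
configurable). Ties break toward smaller C, then smaller γ; the final
model is refit on all records. No resampling is applied for class
imbalance; an optional class-weight switch exists but defaults off.
Trained models serialise to a JSON bundle (support vectors, dual
coefficients, bias, kernel width, standardisation statistics, disease
vocabulary, schema tag); loading a newer schema fails loudly, and a
round-trip reproduces decision scores to 1e-10. Prediction on an unseen
disease code raises rather than emitting an all-zero one-hot row.

## Evaluation

Six confusion metrics (precision, specificity, accuracy, recall, F1,
Matthews correlation) are computed with TRUE as the positive class;
zero-denominator cells report 0 together with a degenerate flag instead
of raising, keeping fold aggregation total while surfacing the
condition. The cross-validated ROC averages TP/FP/TN/FN counts across
folds at each threshold (the union of observed scores; a fixed-size grid
is available for large inputs) and derives sensitivity/specificity from
the averaged counts, with trapezoid area; per-fold AUCs are reported
alongside for mean ± sd summaries. The two AUC estimators differ
slightly and both are surfaced. AUPR is the step-wise (non-interpolated)
average-precision sweep. All of these match independent implementations
(explicit arithmetic, scikit-learn curves) to 1e-10 on randomised
instances.

## ZRscore ranking

Within a normalisation cohort — by default the candidates sharing a TRIM
and cancer, matching a per-query presentation; globally as an option —
docking scores are min-max scaled **inverted**, so the most negative
(strongest-binding) score maps to 1. Without the inversion a higher
ZRscore would reward *weaker* binding, contradicting the score's intent.
A degenerate cohort (one candidate, or all-equal scores) falls back to
the global scale rather than erroring. The projection
ZRscore = (2·zrank_norm + R)/√5 uses √5, the norm of the projection
direction (2, 1) implied by the reference line R = 2·zrank_norm; a plain
/5 rescales all scores by one positive constant and cannot change any
ranking. The numerator order (2·zrank_norm + R, not zrank_norm + 2·R)
follows the printed formula; no switch is provided for the alternative
to avoid silent divergence. Candidates are sorted by descending ZRscore,
ties broken by stronger raw docking score, then target symbol; the sort
is stable.

## Synthetic cohorts

The generator produces the study conditions the pipeline assumes, not a
facsimile of any real dataset. Defaults (class `SimConfig`): 12 CIV and
12 non-CIV TRIMs, 150 targets assigned round-robin so classes stay
balanced, 2 cancer types, 100 tumour / 50 normal samples each, 200
background null genes, 60 non-interacting decoy pairs, and a 2% docking
failure rate mirroring the few-percent loss real docking pipelines see.

* **Differential expression.** 70% of targets are planted DEGs at
  |log2FC| = 2. CIV-partner targets are upregulated; non-CIV partners
  take a random sign — emulating the observed tendency of CIV members to
  track upregulated genes while other subfamilies are less consistent.
* **Co-expression.** Interacting pairs are planted with a Spearman
  correlation in tumour samples via a Gaussian copula (Pearson latent
  correlation 2·sin(πρ/6), quantile-mapped to the marginal): CIV pairs at
  ρ = 0.8, non-CIV pairs at ρ = 0.45, with per-pair heterogeneity sd 0.25
  (clipped to ±0.95) reflecting that correlation strength varies across
  pairs and cancers. Decoys carry no planted correlation.
* **Counts layer.** Negative-binomial with a dispersion trend
  0.05 + 10/mean (dispersion shrinks with abundance) and per-sample depth
  factors U(0.7, 1.4), so TMM has real work to do. **Proteomics layer.**
  Gaussian log2 intensities (per-gene sd U(0.6, 1.2)) exponentiated to
  raw positive intensities, with missing-completely-at-random dropout at
  rate 0.1 — MCAR is the weakest assumption and keeps the imputation
  check interpretable; real proteomics missingness is partly
  intensity-dependent, which the generator deliberately does not model.
* **Docking.** CIV-pair scores draw from a truncated normal, mean −45,
  sd 10, on support [−90, 0] — concentrating essentially all mass in the
  −20..−80 band with mode near −45 — while non-CIV pairs draw uniformly
  over the support; lower = stronger binding. The sd of 10 was chosen at
  design time so the docking feature carries a material, non-dominant
  share of the class signal: with a much wider CIV spread its
  single-feature discrimination against a uniform background falls
  toward chance and ablating it becomes undetectable, while a much
  narrower spread would make docking alone sufficient. Because both
  class distributions are symmetric about −45 by construction, they
  differ in shape, not location; distribution-difference checks
  therefore use the Kolmogorov–Smirnov test (a rank-sum test is blind to
  this alternative by symmetry). Setting `dock_separated=False` draws
  every pair from the uniform, ablating the subfamily signal while
  preserving marginals.

All three generators are deterministic given the config seed (independent
SeedSequence child streams per generator, cancer and layer), and the
file-based pipeline reproduces byte-identical TSVs under a fixed seed.

What passing on this cohort does **not** show: robustness to batch
effects and study-specific biases, intensity-dependent missingness,
isoform-level ambiguity, real docking-score error structure, or the
research-bias-driven unevenness of curated pair databases. The planted
geometry is calibrated so the pipeline's statistical machinery is
genuinely exercised, not so the numbers transfer to real cohorts.

## Problem sizes and numerical choices

Simulation studies in the tests and the acceptance script use the
default cohort (~370 genes × 150 samples per cancer and layer, ~350
feature records per layer) averaged over 5–10 seeds, with 20 seeds for
null controls — sizes at which every check runs in seconds while the
monitored averages are stable to well within the asserted margins.
Estimator-recovery runs use 50/50 samples per group and a DE-minority
transcriptome; the correlation-power condition uses 200 tumour samples.
Other numerics: BH adjustment enforces monotonicity and caps at 1; TMM
returns factor 1.0 for degenerate pairs (max |M| < 1e-6, empty trim
window); the screen skips constant-expression genes with a logged count;
grid-search and fold shuffling are fully seeded and recorded in the
model bundle.

## Known limitations

* Only synthetic mode is wired into `run-all`; real datasets enter by
  staging TSVs in the documented schemas into a run directory and
  running the stages individually.
* The moderated-t prior estimation uses the classic moment-matching fit
  without robustification against variance outliers.
* The low-count filter emulates the cited package's default behaviour
  (CPM threshold in ≥ min-group-size samples) rather than porting it
  bit-for-bit.
* Cross-validated metrics at the default threshold 0 can be optimistic
  on imbalanced feature tables (recall saturates before specificity);
  the AUC/AUPR columns are the primary comparison quantities.
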