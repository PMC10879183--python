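# Methods

## Survival primitives

Kaplan–Meier estimation uses the product-limit estimator over distinct event
times, with censored observations tied to an event time counted as still at
risk. The two-group log-rank statistic is `(Σ(O₁ⱼ−E₁ⱼ))²/ΣVⱼ` with the
hypergeometric variance at each distinct event time, referred to χ²₁.

Univariate Cox regression maximizes the Breslow partial likelihood by
Newton–Raphson (max 50 iterations, tolerance 1e-9 on β, step-halving on any
likelihood decrease). The reported p-value is always the **score test at
β = 0** (`U(0)²/I(0)`), for three reasons: it is defined even when the MLE
diverges (monotone likelihood, e.g. perfectly separating covariates inside a
bootstrap resample); for a binary covariate it coincides exactly with the
log-rank χ²; and it admits a vectorized closed form across a whole gene
matrix via risk-set suffix sums, which makes the bootstrap loop fast. The
phrase "p-values based on the log-rank test" for a Cox fit on continuous
expression is therefore read as this score test — the log-rank test's
generalization to continuous covariates. Ties are handled by the Breslow
approximation throughout; at the tie rates of continuous expression data the
difference from Efron is negligible, and tests cross-check both the log-rank
χ² (to 1e-8) and the Cox β/SE against lifelines.

The optimal-cutpoint scan considers every distinct marker value inside the
[10th, 90th) percentile band, splits as (marker > t) vs (≤ t), and returns
the threshold with the smallest log-rank p plus the full scan for audit. The
minimum over many thresholds is anti-conservative; a test verifies the
inflation (type-I error well above nominal under a null marker) rather than
pretending the p is calibrated.

## Bootstrap gene scoring

`B` resamples of patients (time, event, expression drawn jointly — the only
resampling unit consistent with "bootstrapped sample sets of the dataset")
are drawn with replacement; default `B = 5000`, trimmed by
`floor(B·0.05)` p-values from **each** tail (the per-tail reading of
"top and bottom 5%"), scored as the mean of `1/max(p, 1e-16)` over the rest.
The floor keeps the inverse finite if a retained p underflows; trimming
already removes the most extreme values. Degenerate resamples (no events, or
zero covariate variance) contribute p = 1 — counted, never dropped — so each
gene aggregates exactly B values.

One shared sequence of bootstrap index sets is reused across genes (common
random numbers): this makes scores comparable gene-to-gene and reduces cost
by a factor of the gene count; independent per-gene resampling is available
by flag. Samples are put in canonical (sorted-ID) order before index sets
are drawn, so scores are invariant to the storage order of the cohort —
an invariance finite-B resampling cannot otherwise provide. Ties in score
are broken lexicographically by gene ID so ranks are total and reproducible.

## Risk classifier

k-means (k = 2, 20 seeded restarts) runs on per-gene z-scored expression so
high-variance genes do not dominate the Euclidean metric. The high-risk
label is anchored to survival, not cluster index: the cluster with the
smaller restricted mean survival time (area under its KM curve up to the
cohort's last observed time) is "high". RMST is used instead of median
survival because the median is undefined under heavy censoring.

The NSC classifier follows the shrunken-centroid construction:
`d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀))` with `m_k = √(1/n_k − 1/n)` (the
standard error of the class-vs-overall mean difference), `s₀ = median(s_i)`,
soft-thresholding `d'_ik = sign(d_ik)·max(|d_ik|−Δ, 0)`, and classification
by the standardized squared distance minus `2·log π_k` with empirical class
priors. Δ is chosen by stratified 10-fold cross-validation over 30 evenly
spaced values from 0 to the maximum |d_ik| on the full data; the smallest Δ
achieving the minimum CV error wins and the model is refit on all data.
Folds shrink automatically (with a warning) when the smaller class cannot
fill them.

Forward selection evaluates each prefix g = 1..G_max of the candidate list
and combines the two quality metrics as
`combined_rank(g) = rank(logrank_p) + rank(cv_error)` (average ranks), with
ties going to the smaller g. Sum-of-ranks was chosen because the two metrics
live on incomparable scales and the procedure must honor "smallest list that
minimizes both"; degenerate prefixes (no split) are recorded and skipped.
The selected split's own log-rank p is selection-biased (a test documents
that it is not uniform under the null), so classifier quality is judged only
against held-out synthetic truth, never by its in-sample p.

## Differential expression and consensus

The two-group moderated t shrinks per-gene pooled variances (d_g = n − 2)
toward a prior: `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, t referred to
d₀ + d_g df. Hyperparameters are estimated by moment matching on log s²_g:
with `e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`,
`Var(e) − ψ'(d_g/2)` estimates `ψ'(d₀/2)` (solved by root-finding on the
trigamma), and the mean of e gives s₀². When the empirical variance of
log s² is at or below its sampling floor, d₀ = ∞ and all genes share s₀².
An unmoderated pooled-t mode (`moderated=False`, the d₀ = 0 limit) exists
for sensitivity analysis and as a test oracle. Family-wise error control is
step-down Holm at α = 0.05.

Consensus: a gene qualifies with ≥ `min_support` (default 2) cohorts calling
it significant in the same direction. A gene significant in opposite
directions across cohorts counts toward neither side unless one direction
alone reaches support (exact ties excluded) — the conservative reading of a
direction-consistent filter.

The empirical null redraws, per iteration and per cohort, a uniform random
gene subset of the cohort's observed list size from the shared universe
(taken as the **intersection** of cohort gene lists), reassigns the cohort's
observed up/down counts to the drawn names at random, and recomputes the
consensus size; `p = (1 + #{size ≥ observed})/(1 + n_iter)` (never exactly
zero). Direction labels are preserved in the resampling because the observed
statistic is direction-aware; a direction-blind null would overstate
significance. Default 100,000 iterations. On a two-cohort instance with all
calls in one direction the null size is exactly hypergeometric, which the
tests exploit as a closed-form oracle; under self-generated null lists the
empirical p is approximately Uniform(0,1).

## Synthetic cohorts

Expression: `x_gi = μ_g + b_gc + δ_g·1[i high]·1[g planted] + ε`, with
`μ_g ~ N(7,1)` on the log2 scale (typical microarray intensity range),
cohort batch shifts `b_gc ~ N(0, 0.3²)` by default, noise σ = 1, and half
the planted genes shifted up / half down to exercise the signed consensus.
Survival: exponential event times with hazard
`h₀·exp(Σ β_g z_gi)` over within-cohort standardized planted expression —
the simplest proportional-hazards-consistent generator; standardization
makes the effect size scale-free since Cox on raw log2 values would be
scale-sensitive. Censoring is independent exponential with its rate solved
by Brent root-finding on the analytic marginal censoring probability
`E[λ_c/(λ_c+h_i)] = target`, giving a controllable censored fraction
(default 30%, typical of progression-free follow-up). The gene universe,
planted set, directions, and gene means derive from the seed alone and are
shared across cohorts; all cohort-specific draws come from per-cohort child
seeds, so cohorts are independent given the truth and the whole simulation
is reproducible bit-for-bit.

What the generator does **not** emulate: platform-specific noise
(probe effects, background correction), missing values, competing risks,
non-proportional hazards, correlated background genes, or cohort-specific
follow-up distributions. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own model assumptions — not
that it is robust to every failure mode of real microarray/RNA-seq cohorts.

## Study conditions used in tests and the acceptance script

Scaled-down problem sizes keep the default runs fast while preserving the
regimes of interest: 200 genes / 10 planted / 150 patients per cohort;
B = 200 for ranking recovery (B = 100 inside the classifier and end-to-end
runs), G_max = 30, 5,000–20,000 null iterations. Two planted-effect regimes
appear:

- **Single-gene regime** (ranking recovery): β = 1.0 per planted gene,
  δ = 1.5 — each gene individually prognostic.
- **Multi-gene regime** (classifier and end-to-end checks): δ = 1.2 with the
  per-gene log-hazard chosen as `ln(4)/(10·δ_std)` so the *combined* latent
  hazard ratio is ≈ 4 while no small subset of genes separates the groups on
  its own. The choice comes from the two-component mixture accuracy
  `Φ(√g·δ_std/2)` with `δ_std = δ/√(1 + f(1−f)δ²)`: at δ = 1.2, ten genes
  give ~95% achievable agreement but five give only ~88%, so a genuinely
  multi-gene list is required — the situation the forward-selection step
  exists for.

## Numerical choices and degenerate inputs

- p-values are clipped away from exact 0; the bootstrap inverse uses a
  1e-16 floor.
- Zero-variance genes score at the minimum (1.0) with a warning; cohorts
  with zero events refuse to rank.
- Cox fits on constant covariates return a degenerate flag with p = 1.
- k-means on samples identical over the selected genes raises (no split);
  forward selection skips such prefixes and errors only if all are
  degenerate.
- All randomness flows from integer seeds through numpy `SeedSequence`
  spawning; pipeline reruns are byte-identical except for the recorded
  output path.

## Limitations

- Breslow (not Efron/exact) tie handling; heavy tie structures (coarsely
  discretized follow-up) will drift from exact-likelihood implementations.
- The per-dataset classifier is never applied across cohorts (matching the
  per-dataset design); transfer of a signature to a new cohort is out of
  scope.
- No probe-to-gene collapsing or cross-platform ID mapping: gene IDs are
  opaque strings and must already be harmonized across cohorts.
- The moderated-t hyperparameter estimator uses plain digamma/trigamma
  moment matching without variance-trend or robust options.
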