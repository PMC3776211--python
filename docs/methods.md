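# Methods

This note documents the models, conventions and numerical choices behind
`rapatest`, and what the synthetic data can and cannot show.

## The lymphocyte assay chain

**LDH calibration.** Cell number is taken as proportional to LDH activity
read as absorbance at 490 nm.  The calibration is unweighted ordinary least
squares with an intercept, `A = slope·N + intercept`; the intercept is kept
because blank wells carry background absorbance (whether it should be forced
through zero is not determinable from the assay description, so the more
general model was chosen and the inversion subtracts it symmetrically).
Triplicate wells are summarised by mean and CV = SD/mean; the quality gate is
strict `CV < 0.10`.  Flagged wells are annotated, never silently dropped, so
cohort-level QC behaviour is auditable.  Negative cell estimates (absorbance
below the intercept) are clipped to zero with a warning.

**DNA-histogram deconvolution.** The propidium-iodide histogram is modelled
classically (Dean–Jett–Fox style): a Gaussian G0/G1 peak at mode μ with
SD σ, a Gaussian G2/M peak at r·μ with r constrained to [1.85, 2.10] and SD
r·σ (constant-CV convention), and S phase as a broadened rectangle — a sum of
24 grid Gaussians of SD σ spanning [μ, r·μ] with a common amplitude.  Fit by
trust-region nonlinear least squares on the binned counts; the G1 mode is
seeded from the global histogram mode, G2/M at twice that channel, and the
fit restarts from three deterministically jittered seeds, keeping the best
residual.  Sub-G1 (apoptosis proxy) is gated nonparametrically as observed
mass below μ − kσ with k = 3 (standard apoptosis gating; configurable); the
three fitted component areas share the remaining mass and the four fractions
are renormalised to sum to 1 (tolerance 1e-6 enforced on the result type).
Fits refuse histograms with < 500 events or < 32 channels, and degenerate
inputs (no interior mode, counts in fewer than 3 channels) raise with
diagnostics.  The synthetic generator draws events from this same parametric
family, which closes the generate–refit test loop: 50k-event histograms
refit within ±0.02 per phase over a 20-point Latin-hypercube grid of truths.
Debris/doublet modelling is deliberately excluded — the synthetic data
contains none, so real cytometry files would need upstream gating first.

**Kinetics.** PDT assumes exponential growth over the full 72 h culture
(seed → harvest): `PDT = t·ln2 / ln(N_t/N_0)`; a culture with `N_t ≤ N_0`
gets an infinite PDT with a no-growth flag.  G1 duration uses the
proportional-occupancy convention `T_G1 = PDT · g0g1/(g0g1+s+g2m)` (sub-G1
excluded); the exponential age-distribution correction
`T_G1 = −PDT·log2(1 − occ/2)` is available behind the `age_corrected` flag —
proportional occupancy was made the default for transparency, and the two
differ only in a monotone reparametrisation, which the downstream logistic
model absorbs.  Response ratios (treated/untreated) are capped at 10 when a
treated culture stops growing, keeping logistic features finite; capped and
baseline-non-proliferative subjects carry explicit flags and the latter
never enter the model.

**Non-dividing fraction.** There is no unique operational definition of a
"non-dividing fraction" from a single DNA histogram.  The package uses a
growth-fraction heuristic, `GF = min(1, (s+g2m)/0.35)` with 0.35 the S+G2/M
occupancy of a fully cycling reference population, and reports
`non-dividing = 1 − GF` labelled as a heuristic in output metadata.  It is
isolated in one function so a different convention can be swapped in.

## The diagnostic model

Logistic regression of diagnosis (AD = 1 vs Control = 0; MCI subjects are
scored but never fitted) on {baseline PDT, PDT ratio, G1 ratio}, optionally
plus ApoE4.  Fit by IRLS with tolerance 1e-8 on the log-likelihood and at
most 100 iterations.  Quasi-complete separation — detected as a diverging
coefficient norm or every observation fitted to within 1e-3 — triggers a
refit with a weak ridge penalty (λ = 1e-4, intercept unpenalised) and a
warning; with the default synthetic preset the arms separate almost
completely, so this path is the norm there and the reported coefficients
should be read as rankings, not effect sizes.  Standard errors come from the
inverse observed information.

ROC analysis uses the Mann–Whitney pair-counting AUC (ties count ½), exact
against the exhaustive pair oracle; confidence intervals use a stratified
percentile bootstrap (default 2000 resamples, seed recorded) — one
resampling machinery serves all CIs rather than mixing in DeLong.  Decisions
use the strict rule `score > cutoff` at the 0.5 default.  The diagnostic
odds ratio gets a Woolf log-scale CI with the Haldane–Anscombe 0.5
correction (flagged) for zero cells.  The LR⁺ for an individual's continuous
score is taken from the ROC operating point at that score's threshold;
ApoE4 likelihood ratios are user-supplied published values (defaults 3.5
carrier / 0.56 non-carrier in the pipeline config) and combine with the
lymphocyte LR by sequential odds updates.  The age→prevalence model is
exponential between anchors, `p(age) = 0.023·2^((age−57)/d)` with d ≈ 9.18 y
so that p(95) = 0.405, clipped to [0.023, 0.405]; any user table can replace
it.  Frozen-model validation refuses cohorts that share subject ids with the
training data and never refits.

## The expression screen

Two-class SAM statistic `d_i = (x̄_A − x̄_B)/(s_i + s₀)` with the pooled SE
`s_i = sqrt((1/n_A + 1/n_B)·SS_within/(n−2))`.  The fudge factor s₀ is tuned
classically: candidates are the 0,5,…,100th percentiles of the s
distribution; genes are split into 25 quantile windows of s (25 rather than
100 because the panel has ~1165 genes, not tens of thousands); the candidate
minimising the CV of the within-window MAD of d wins.  The multiclass
statistic is `sqrt((Σ_k 1/n_k)·Σ_k n_k (x̄_k − x̄)²)/(s + s₀)` with
`s = sqrt((Σ_k 1/n_k)·SS_within/(n−K))` — scaled so that at K = 2 it equals
|d| exactly, which is tested.

Significance calling follows the classical quantile-matching rule: order the
observed d, compare to the per-rank mean of the permutation-null order
statistics, and call genes beyond the smallest deviation > δ in each tail
(upper tail only for the one-sided multiclass statistic).  The null comes
from column-label permutations (1000 by default; when fewer distinct
arrangements exist they are enumerated exhaustively and logged).  FDR is
estimated as `π₀ · median(null calls) / observed calls` with π₀ from the
central 50 % of the null distribution, and `tune_delta` returns the smallest
δ with estimated FDR below the target (10 % default).  Duplicate probes
collapse to the max-|d| probe per gene — deterministic and
sensitivity-preserving — with the retained probe recorded.

Clustering reproduces the Cluster/TreeView-era conventions: per-gene
median-centred log ratios, complete-linkage agglomeration on
centred-Pearson-correlation distance (Euclidean by flag), deterministic
tie-breaking by input order, scipy's standard leaf ordering.  A constant
row, whose correlation is undefined, is assigned the maximal distance 1 and
flagged.  The heat map maps 0 → black with red/green ramps saturating at
±3.0 log ratio, and an ordered numeric TSV accompanies every image so the
figure itself is testable.

Enrichment is a Pearson chi-square on the 2×2 table
{panel vs rest-of-universe} × {altered/associated vs not}, reported with and
without continuity correction because the published construction is
ambiguous; the gene universe defaults to 20,000 protein-coding genes (the
panel's printed genome percentages imply a universe of that size).  The
packaged gene lists are synthetic stand-ins: only the six intersection
symbols (A2M, B2M, GSN, LRP1, DDIT4, MAL) are real gene names.

## The synthetic cohort

The generator encodes the study conditions: cohort sizes 68 Control / 27
MCI / 51 AD; ages uniform on 57–95; baseline PDT mean 30 h (typical for
PHA-stimulated lymphoblasts) with log-normal between-subject variation
(CV 0.15) — kinetic quantities are positive, so noise is multiplicative;
mean PDT ratios 1.6 (Control) vs 1.15 (AD, blunted); G1 ratios 1.9 vs 1.25,
deliberately larger than the PDT ratios so that treated cultures show the
expected G1 accumulation (the G0/G1 occupancy scales by g1_ratio/pdt_ratio,
clipped at 0.95 with the realized ratio recorded as truth); triplicate LDH
CV 0.05 (< the 0.10 gate); ApoE4 carrier prevalence 0.25/0.40/0.50 by group
with the response drawn independently of carrier status; untreated phase
fractions (0.04, 0.55, 0.25, 0.16) and a +0.01 apoptotic shift under
treatment.  MCI subjects are a 50/50 mixture of control-like and AD-like
response distributions, since no MCI response model is published.  A single
root seed spawns independent per-subject streams (`numpy` SeedSequence), so
any subject's data is reproducible regardless of cohort composition, and
identical specs yield byte-identical files.

The expression preset mirrors the brain-bank design — 5 Control, 19
limbic-stage, 22 neocortical-stage samples over a 1165-gene panel — with
signature tiers of 33 shared-up, 22 shared-down, 17 limbic-only and 81
neocortical-only genes at 1.5 log2 effect and 0.5 log2 noise.  Stage-
specific signatures are generated as up-regulated; the shared tier carries
both directions.

**What passing tests show — and what they do not.** The generators draw
from the same model families the fitters assume (the DNA histogram model,
exponential growth, log-normal subject variation, Gaussian expression
noise).  Recovery and error-control results therefore validate the
*implementation* — the estimators recover the truth of their own model, the
permutation FDR controls what it claims, the pipeline is deterministic —
but they do not validate the model against real cytometry artefacts
(debris, doublets, drift), real growth curves, or real microarray noise,
and the near-perfect synthetic ROC says nothing about clinical accuracy.
The published patient-cohort performance numbers are not reproducible
without the original cultures and are not targeted; the package reproduces
the in-text arithmetic exactly and the qualitative pattern (blunted AD
response, lymphocyte model ≫ ApoE4-only model, ApoE4-independent response)
by construction plus measurement.

## Problem sizes and numerical conventions

Acceptance-scale simulations use sizes at which the checked statistics are
stable: 50 replicate null matrices at 100 permutations for FDR control,
1000 permutations for the preset screens, 50k events per histogram over a
20-point Latin grid, n = 5000 for logistic recovery, and 100 subjects/arm
through the full measurement chain for the directional comparison.  The
histogram fit treats channel positions scale-free (initialisation relative
to the mode), giving shift/scale equivariance of the fractions.  All
random draws anywhere in the package flow from explicit seeds; derived
seeds stay below 2³¹.
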