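# Methods

## Module perturbation scores

Expression is standardized per gene within a cohort: z = (x − mean)/SD,
with the **sample SD (ddof = 1)**; the convention is recorded in the output
metadata so that cross-validation folds stay consistent. Zero-variance
genes become all-zero rows and NaNs produced by z-scoring are set to 0, so
missing measurements are uninformative for binning and correlation.

For one sample, z-scores are cut into Ne equally populated,
rank-contiguous bins (default Ne = 10; results are robust across 6–15).
Ties are broken by stable input order, and when the gene count is not a
multiple of Ne the extra genes go to the lowest-expression bins, so bin
sizes differ by at most one. The mutual information between module
membership and bin index is computed from the 2 × Ne joint-counts table in
natural log units (z-scores are base-invariant, so the choice does not
propagate). Internally the MI uses the entropy decomposition
N·I = Σ c·ln c − Σ r·ln r − Σ s·ln s + N·ln N with `xlogy` handling empty
cells; unit tests pin it to a literal double-sum oracle at 1e-12.

**Permutation null.** The null permutes the expression vector against the
membership (equivalently, redraws the membership uniformly at random).
Because the bins are equally populated, the member-row bin counts of a
random size-m membership follow a multivariate hypergeometric law over the
bin populations; null draws therefore use
`numpy`'s `multivariate_hypergeometric` (the "count" sampler) — an exact
equivalent of literal permutation at O(Ne) instead of O(genes) per draw.
A KS test against literal membership permutation guards the equivalence.
One null is drawn per (sample, module size) — the null depends on the
membership only through its size, so equally sized modules share
randomizations; substreams are keyed by (root seed, CRC-32 of the sample
id, module size), which makes scores independent of sample order.

**Gate and sign.** The observed MI is significant when strictly greater
than the empirical 99th percentile of the n_rand null values (the
`method="higher"` order statistic; ties fail). The default n_rand is 1000;
the test suite and analysis scripts use 200. The score is
sgn(r) · max(0, (I − μ)/σ) gated on significance, where r is the Pearson
correlation between membership and the sample's z-scores. The printed
step-function form (a ±1/0 score) is available via `magnitude="heaviside"`;
the gated-z magnitude is the default because downstream arm selection ranks
samples by absolute non-zero score, which requires a continuous magnitude.
Modules with fewer than 5 genes in the expression universe are scored 0
with a warning.

**Specificity filters.** Cohort-specific modules are those in the top 50 %
by mean |MPS| and bottom 40 % by variance, with the activation and
repression streams ranked independently and the union returned; a module
must have a nonzero stream mean to be eligible. Tissue-specific modules
require MPS_tumor · MPS_normal < 0 in at least 75 % of matched pairs
(a strict inequality: a pair with one non-significant score never counts).

## Survival statistics

Patients are stratified into MPS⁺/MPS⁻ arms of a fixed per-arm size k: the
k largest positive and k most negative scores, ties broken by sample id;
a (module, k) with fewer than k nonzero scores of either polarity is
skipped. The per-cohort size schedule is `auto_schedule(n)`: every
candidate in {25, 50, 75, 100, 150, 200, 250, 400, 500} strictly below
n/2.

The two-group log-rank test is implemented directly (O − E with the
hypergeometric variance) so that nulls can be computed in batch; it matches
`lifelines` to machine precision. For small included-sample counts (≤ 40)
the asymptotic chi-square p is noticeably anti-conservative, so the p-value
switches to the permutation null of the statistic — enumerated exhaustively
when C(n, n₁) ≤ 5·10⁵, otherwise seeded Monte Carlo with an add-one
estimator. All pipeline stratifications involve ≥ 50 patients and use the
asymptotic p, consistent with the batched empirical-FDR nulls below.

Cox proportional-hazards fits are delegated to `lifelines` (Efron ties,
tolerance 1e-7). Orientation is fixed throughout: `log2_hr` and `wald_z`
are positive when the MPS⁺ arm survives longer; swapping arm labels flips
both signs and leaves p-values unchanged. Kaplan-Meier medians that never
cross 0.5 are reported as NaN, not infinity.

**Empirical FDR.** The significance of a stratification is calibrated
against random disjoint arm pairs of the same size drawn from the same
cohort; the reported FDR is the exceedance fraction
#(null p ≤ observed p)/n_null (an optional add-one pseudo-count guards
exact zeros, off by default). The null depends only on the outcome set and
k — never on the module — so one batch of null p-values per (context, k)
is shared across all modules. Default n_null is 1000; the acceptance runs
use 500 (resolution 0.002 against the 0.01 gates).

**Single loci and aggregation.** Single-gene stratifications split by
mutation status, or by the sign of the CNA/expression z-score (zeros in
neither arm), and are evaluated only when both arms hold strictly more
than 15 patients; Cox p < 0.05 flags a locus prognostic. Module evidence
for a driver is combined with Stouffer's method Σz/√k, and the
module-versus-locus comparison is log2(|Stouffer z| / max-mode |locus z|).

## PCM discovery

The cohort is split 3-fold, stratified by event status (fold sizes within
±1). Each training split is standardized stand-alone; its held-out third
is z-scored with the training means/SDs and scored with its own nulls —
training scores are bit-identical under any perturbation of test values
(verified in the tests). Arms of size k are selected on training; the
boundary propagated to the test fold is the least-extreme selected score
of each polarity (closed comparison). For the repressed arm the source
text reads "most negative value", which would propagate almost no labels;
the default mirrors the activated rule (least-extreme selected negative),
and the literal reading sits behind `literal_repressed=True`. The three
labeled test folds are concatenated and arms re-formed at the same k
(at the achievable size when fewer labels propagated, provided ≥ 10 per
arm, else skipped).

A module is a PCM at size k when: empirical FDR < 0.05 in each training
fold, < 0.01 on the propagated test set, < 0.01 on the full un-split
cohort, and full-cohort Cox p < 0.05. Full-cohort gates use fresh null
draws rather than reusing fold-level ones. Relaxing any α can only grow
the PCM set. Stage association replaces the survival gates with Fisher
tests on the stage × {MPS⁺, MPS⁻} table (gates 0.05/0.01/0.01): exact for
2 × 2, otherwise a seeded fixed-margin Monte-Carlo p (10,000 draws, add-one
numerator) with the table probability as the statistic.

Sub-cohorts are enumerated from clinical attributes (stages merged to
I–IV; ages binned <30, 30–60, >60), the top mutated genes (prevalence
≥ 5 %, ranked by mutations per coding base pair, TTN excluded), and the
top rank-product CNA genes (RP(g) = ascending-rank(|median|) ×
ascending-rank(SD), greedy selection discarding |Pearson r| > 0.5
profiles), with samples categorized deep/shallow amplified/deleted at the
25 % quantile within each sign (33 % for risk-model features). Sub-cohorts
require > 20 samples.

## Redundancy and risk models

Module overlap is the modified Jaccard score |A∩B| / min(|A|, |B|).
Exemplar clustering uses affinity propagation (scikit-learn,
`affinity="precomputed"`, damping 0.9, max 1000 iterations, convergence
window 100), run within module categories, preference defaulting to the
median off-diagonal similarity. Non-convergence falls back to greedy
leader clustering at 0.5 (flagged). A member with zero similarity to its
exemplar carries no overlap evidence and is split into a singleton — this
guards the degenerate all-tied case where message passing collapses
disjoint modules.

Risk models are random survival forests (scikit-survival) under repeated
k-fold cross-validation with event-stratified folds: 1000 trees, terminal
node size 15, mtry = ⌈ln(#features)⌉, log-rank splitting (tests use
smaller forests). Out-of-fold risks are collated so every sample is
predicted exactly once per repeat. Risk groups take the candidate size
nearest ⌊f·N/50⌋·25 from {25, 50, 100, 150, …, 500} (no 75 in the default
list; configurable), ties to the smaller candidate, clipped to ⌊N/2⌋;
f = 0.666 by default, and cross-cohort prediction uses top/bottom 40 %
instead. Feature sets are compared by the per-repeat |log2 HR| of their
risk-group split (one-sided Mann-Whitney, n = repeats).

External validation re-scores discovery PCMs on the new cohort and calls a
module prognostic there when some tested arm size gives log-rank p < 0.05
or |log2 HR| > 0.4, and consistent when the direction matches discovery;
modules with more than half their genes absent are not evaluable. The AUC
summary scores positives by −log10 of their best stratification p and
negatives by the identical procedure on cohorts whose per-sample profiles
were independently permuted; the AUC is the midrank Mann-Whitney identity
U/(n₁·n₂).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset. Baseline expression is i.i.d. standard
normal. Each planted module (default: five 50-gene modules in disjoint
gene blocks) is activated in a fraction of samples (default 0.30), half
with polarity +1 and half −1 — so both activated and repressed arms exist
— and its genes are shifted by polarity × δ (default 2 SD). Survival is
exponential with hazard h₀·exp(Σ β_m·a_mp + γ·stage), h₀ = 1/40 per
month, γ = 0.2 per stage step, and the planted log-HR ladder is
{0.3, 0.6, 0.9, 1.2, 1.5}; censoring is an independent Exp(1/80) time
truncated at 120 months, giving a ~0.65 event fraction whose closed form
(`expected_event_fraction`) is tested against realizations. Decoy modules
are random gene sets with heterogeneous sizes (U{20..100}, as in real
catalogs); the decoy:planted ratio defaults to 50:5. Clinical covariates:
age ~ N(63, 11²) clipped to [25, 90], balanced sex, stages I–IV
(0.30/0.30/0.25/0.15) emitted with sub-stage suffixes to exercise the
merging rules. CNA matrices carry five prominent genes (large |median|
and SD) over sparse background; SNV prevalences are U(0.01, 0.30) plus a
hypermutated TTN; promoter windows are 1 kb with one planted IUPAC motif
instance per planted-module gene.

What the generator does **not** emulate: gene-gene correlation beyond the
module blocks, batch effects, non-exponential baseline hazards (a Weibull
switch would be a one-line extension), treatment effects, or the
count-distribution artifacts of raw sequencing — so passing tests show the
pipeline recovers coherent-shift modules under clean conditions and is
calibrated under an exact global null, not that it is robust to every
pathology of real cohorts.

## Numerical choices and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams; identical seeds reproduce every
table byte for byte. Tie-breaks are stable everywhere (bin assignment by
input order, arm selection by sample id, candidate sizes to the smaller).
The tests and the acceptance script run the study at reduced
randomization counts (MPS nulls 200, FDR nulls 200–500, 3–10 cohort
replicates, forests of 30–200 trees), sizes chosen so the whole suite
completes in minutes on one CPU while every gate retains resolution well
below its threshold; the defaults encode the full-scale values (1000 MPS
randomizations, 1000-tree forests).

## Known limitations

- The empirical "FDR" is a null-exceedance fraction (an empirical
  p-value); a tail-ratio FDR interpretation of the same null is not what
  the gates use.
- Equal-size nulls assume the membership interacts with the sample only
  through its size, which is exact for the permutation null but would not
  hold for a gene-identity-preserving null (e.g., expression-matched
  resampling).
- Affinity propagation on near-tie similarity structure is sensitive to
  the preference; the within-category default works for block-structured
  catalogs but exemplar identity on flat similarity landscapes is
  arbitrary.
- With 30 % activation split across polarities, arms larger than ~15 % of
  the cohort dilute into non-activated samples; sensitivity at the small
  end of the planted ladder (log-HR 0.3) is genuinely limited at n = 600.
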