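# pcmkit — module perturbation scoring and prognostic-module discovery

Single-gene measurements (a mutation, a copy-number call, one transcript's
abundance) are often weak predictors of cancer patient survival. The
coordinated activity of *gene modules* — pathways, regulator target sets,
and regulons defined by shared promoter/3′UTR motifs — is a richer signal.
`pcmkit` implements a complete, testable pipeline for quantifying module
activity in individual tumor transcriptomes and discovering **prognostic
cancer modules (PCMs)**: modules whose perturbation splits patients into
groups with significantly different survival, robustly under
cross-validation.

## The statistic at the core

For a module with membership vector *m* (1 for member genes, 0 otherwise)
and one patient's per-gene expression z-scores, the z-scores are cut into
*Ne* = 10 equally populated bins and the mutual information between
membership and bin is computed from the 2 × *Ne* joint-counts table
C(i, j):

    I(module; expression) = Σᵢ Σⱼ P(i,j) · log [ P(i,j) / (P(i) P(j)) ]

*I* is compared with a permutation null (random memberships of the same
size; 1000 randomizations by default), z-scored against the null's mean μ
and SD σ, gated at the null's top 1 %, and signed by the Pearson
correlation *r* between membership and the z-scores:

    MPS(module; sample) = sgn(r) · max(0, (I − μ)/σ) · 1[I > null 99th pct]

Positive MPS = coherent activation of the module in that tumor; negative =
coherent repression. Downstream, patients are stratified into fixed-size
MPS⁺/MPS⁻ arms, survival differences are measured by log-rank and Cox
statistics and calibrated against an empirical null of random same-size
arms, and a module becomes a PCM only if it clears the gates in all three
training folds, in the label-propagated test set, and in the full cohort.

Because real cohort data are not shipped with the package, a seeded
synthetic-cohort generator (`pcmkit.simulate`) produces expression with
planted coherently shifted modules, survival whose hazard follows the
planted activations, clinical covariates, sparse CNA/SNV matrices and
promoter windows with planted motif instances — with a ground-truth
registry, so every pipeline stage is measurable.

## Worked example

```python
from pcmkit import SyntheticCohortSpec, generate, discover_pcms
from pcmkit.simulate import recoverability_report

cohort = generate(SyntheticCohortSpec(seed=1))   # 600 patients, 2000 genes,
                                                 # 5 planted modules, 50 decoys
decisions = discover_pcms(cohort.expression, cohort.catalog, cohort.outcomes,
                          n_rand=200, n_null=500, seed=201)
report = recoverability_report(cohort.truth, decisions, cohort.catalog)
print(report.sensitivity, report.decoy_pass_rate, report.spearman_beta_z)
```

Running the numbered drivers under `analysis/` reproduces the full study
on this cohort. With seed 1 they print, among other things:

```
per-module significant fraction: planted 0.519 vs decoys 0.010 (nominal null 0.01)
mean correct polarity labeling of activated samples: 1.000
sensitivity 0.80 over 5 planted modules; decoy pass rate 0.000 over 50 decoys
Spearman(planted log-HR, |Wald z|) = 1.00
median |log2 HR| per model: {'pcm_mps': 3.34, 'clinical': 0.31}
externally consistent PCMs: 100% of 4
```

Reading: decoy modules reach significance at exactly the nominal 1 % rate
while planted modules are flagged half the time (they are activated in 30 %
of patients); every activated sample is labeled with the correct polarity;
the four strongest planted effects (log-HR 0.6–1.5) pass all PCM gates
while the weakest (log-HR 0.3) is — correctly, at this cohort size —
underpowered; and a random-survival-forest model over the discovered PCMs
separates risk groups far more strongly than clinical covariates alone.

## Package layout

| module | contents |
| --- | --- |
| `pcmkit.io` | expression/GMT/TSV readers and writers, cohort z-scoring, low-expression filter |
| `pcmkit.motifs` | IUPAC motif scanning over promoter/3′UTR windows → regulons |
| `pcmkit.mps` | expression binning, mutual information, permutation null, MPS, cohort/tissue specificity filters |
| `pcmkit.survival` | log-rank (asymptotic + small-sample exact), Cox delegation, empirical FDR, single-locus prognosis, Stouffer aggregation |
| `pcmkit.discovery` | 3-fold CV discovery, boundary propagation, sub-cohort partitioning, stage association |
| `pcmkit.redundancy` | modified Jaccard similarity, affinity-propagation exemplars |
| `pcmkit.risk` | random-survival-forest risk models, risk-group rule, feature-set comparison, external validation, AUC |
| `pcmkit.simulate` | synthetic cohort generator + ground-truth recoverability report |

`analysis/01…05` are thin narrative drivers over these functions; each
writes its tables under `results/`.

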