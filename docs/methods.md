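# Methods

This note documents the statistical procedures implemented in `xsig`, the
design of the synthetic-data generators, and the numerical conventions
that make every run reproducible.

## Per-gene allele model

Each gene's log2 expression across the mouse cohort is fit by ordinary
least squares on the design `[1 | x_Apc x_Kras x_Braf x_Tp53]`, with
samples wild type in every allele as baseline. Effects are reported with
standard errors and two-sided Wald t-tests on n − 5 degrees of freedom.
The fit is vectorized over genes through the shared `(XᵀX)⁻¹Xᵀ` projector;
the design is rejected up front if it is rank deficient (e.g. an allele
that never varies), naming the offending column.

Exact fits are a numerical special case: when the residual variance is at
rounding level (below `1e-20 ×` the mean squared response), t-ratios are
ratios of rounding noise. Such genes get p = 0 where |β| > 1e-8 and p = 1
otherwise, so noiseless cohorts yield exactly the planted gene sets and
constant genes are never spuriously significant.

Gene lists are thresholded at a raw per-gene α = 0.01 in the direction of
the effect; no multiple-testing correction is applied by default because
the analysis is defined by raw-α lists (Benjamini–Hochberg is available
via the `correction` argument). Signatures take the top k = 100 genes per
direction ranked by ascending p, ties by descending |β| then gene id; a
shortfall below k is recorded in the signature provenance rather than an
error.

## Robust scale estimate (RSE) and probeset collapsing

Probeset variability is measured as the residual scale of an
intercept-only Huber M-estimator fit (tuning constant c = 1.345,
MAD-based scale with consistency constant 1.4826, scale re-estimated each
IRLS iteration, location iterated to a 1e-12 relative tolerance). The
returned value is `1.4826 × median|x − loc|` at the converged location.
It is shift-invariant and scale-equivariant, and a constant vector has
RSE 0. The unit tests pin the estimator to an independently written
scalar IRLS oracle at 1e-8 on random vectors; on a gross-outlier vector
it agrees with the converged M-estimator value (≈ 2.21 on
`[1, 2, 3, 100]`, close to the 2.23 of the R reference implementation of
this estimator family).

Collapsing keeps, per gene, the probeset with maximal RSE; ties go to the
lexicographically smallest probeset id; unmapped probesets are dropped
and counted. The same RSE metric ranks the "top 500 most variable" genes
— one variability convention throughout, switchable in principle but not
duplicated.

## Normalization and scoring

Per-gene normalization subtracts the median across samples and divides by
the inter-quartile range (linear-interpolation quantiles); zero-IQR genes
are centered, left unscaled and flagged. The signature score is the mean
of present up-genes minus the mean of present down-genes; genes missing
from a cohort are excluded silently while each arm retains at least
`min_coverage` (default 0.5, motivated by cross-platform use where only
66/100 and 74/100 signature genes may be measurable) and are an error
below that. Cohort scores are median/IQR-normalized; classification is
strictly `score > 0` (a score of exactly 0 is non-allele-like), or
strictly above the median of a designated subpopulation in
`subpop_median` mode.

Homolog transfer keeps only strict one-to-one pairs — any gene on either
side of a one-to-many relation is dropped entirely — then intersects with
the target cohort's gene universe. This is the conservative reproducible
rule when only final counts are known.

## Survival analysis

Endpoints are overall survival (OS), relapse-free survival (RFS) and
survival after relapse (SAR; clock starts at relapse, defined only for
subjects whose relapse was observed). All analyses first truncate
follow-up at 84 months by administrative censoring (time := cutoff,
event := 0). Kaplan–Meier estimation and Cox proportional-hazards fits
delegate to lifelines with Efron handling of tied event times and a
Newton precision of 1e-9 (pinned against a partial-likelihood grid oracle
at 1e-4); categorical covariates are dummy-coded against a declared
reference level. Clinical enrichment uses two-sided Fisher exact tests
for 2×2 tables and chi-square otherwise, with degenerate tables reported
as p = 1 with a warning.

## Synthetic-data generators

The generators emulate the study design and provide ground truth; they do
not attempt to model probe-sequence effects, batch effects or platform
artifacts, so passing tests demonstrate correctness of the analysis
machinery under the assumed model, not robustness to real-data artifacts.

**Mouse cohort.** Genotype counts default to the emulated training set
(A=7, AK=6, AKP=8, AP=3, AB=4, ABP=5, plus 9 wild-type normals). Gene
baselines are Normal(8, 1.5²) on the log2 scale — a typical microarray
magnitude whose exact value is immaterial downstream. Each allele plants
200 genes (half up, half down) with effect ±1.5 log2 units; a fraction
0.1 of each allele's genes is reused from every previously planted allele
(directions preserved) to create the partially overlapping allele lists
of a shared-pathway design. Probesets per gene are drawn uniformly from
1–3. The first probeset of a gene is its designated representative: it
carries the full signal plus Normal(0, 0.5²) noise, while additional
probesets have signal and noise attenuated by 0.5, emulating
lower-efficiency probes. The representative therefore always has the
larger robust scale, and in the degenerate noiseless case — where robust
scales tie at zero — the collapse rule's lexicographic tie-break still
selects it, keeping the collapsed matrix's noise level exactly at
`noise_sd`.

**Human cohort.** Human genes are one-to-one homologs of the mouse genes.
Mutation labels are mutually exclusive (KRAS 35%, BRAF 10% by default);
mutant samples receive `transfer_fraction` (default 0.8) of the
homologous allele effects. Survival uses two independent exponential
clocks — relapse (rate 1/90 per month) and death (rate 1/120) — whose log
hazards both equal `survival_log_hr` times the normalized Kras score (or
the score > 0 call, `hazard_on="call"`). Because death is exponential,
SAR (death minus relapse given relapse first) is exponential with the
same rate by memorylessness, so **all three endpoints are exactly
proportional-hazards** in the linked covariate; an earlier design that
added a separate post-relapse clock to the death time produced a
hypoexponential OS distribution (an accelerated-failure-time family, not
PH) and a visibly biased Cox estimate. Censoring is Uniform(0, c_max)
with c_max tuned by bisection so the expected censored fraction matches
`censor_fraction` (default 0.3). Additional covariates (stage, grade,
MSI, mucinous, site) are drawn independently of the score so enrichment
tests are calibrated under the null. With `noise_sd=0` and moderate
prevalence the raw score is identical for most wild-type samples and its
IQR can be zero; the generator then falls back to median-centering only
for the survival linkage.

**Cell lines.** Each of 40 lines has a latent pathway activation
a ~ Normal(0,1) added to signature up-genes and subtracted from
down-genes on top of 1,000 background genes. The panel is scored through
the standard pipeline and
`ln IC50 = 1.0 + ic50_slope × score + Normal(0, ic50_noise_sd²)` per
compound (defaults −0.5 and 0.3), so with zero noise the fitted slope
reproduces `ic50_slope` exactly. KRAS-mutant labels go to
above-median-score lines with probability 0.7 (0.2 below).

**Seeding.** Every stage draws from `default_rng(SeedSequence([seed,
crc32(stage)]))`, so identical configurations are bit-identical and
adding a stage never perturbs another's draws. `structure_seed` lets an
independent cohort (new animals, new noise) share the planted biology of
a reference seed — this is how validation cohorts are simulated.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 10,000 | genes in the simulated genome |
| `n_planted_per_allele` | 200 | planted genes per allele (half up/down) |
| `effect_size` | 1.5 | planted log2 effect |
| `noise_sd` | 0.5 | residual SD, log2 units |
| `overlap_fraction` | 0.1 | planted-set sharing between allele pairs |
| `alpha` / `k` | 0.01 / 100 | gene-list threshold / signature arm size |
| `top_n_variable` | 500 | exploratory top-variable gene count |
| `human_cohort_size` | 600 | synthetic patients |
| `survival_log_hr` | ln 2 | log hazard per unit score (or per call) |
| `censor_fraction` | 0.3 | target censored fraction |
| `survival_cutoff` | 84 | months of administrative truncation |
| `n_cell_lines` | 40 | panel size |
| `ic50_slope`, `ic50_noise_sd` | −0.5, 0.3 | score→ln IC50 linkage |

The acceptance script runs at exactly these sizes; the unit-test fixtures
use a reduced genome (2,000 genes, 80 planted per allele) with the same
cohort composition.

## Known limitations

- The generators plant purely additive allele effects; no interactions,
  so the analysis' additivity assumption is satisfied by construction.
- Raw-α gene lists inflate with cohort size; the FDR option exists but is
  off by default to match the analysis definition.
- Real cross-platform transfer involves annotation-version noise the
  homolog generator does not model; coverage handling (`min_coverage`)
  is exercised synthetically only.
- The clustering distance is signed 1 − Pearson (anti-correlated samples
  are maximally distant); an absolute-correlation variant is not
  provided.
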