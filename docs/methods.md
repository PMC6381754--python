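# Methods

`methsig` implements an epigenetic biomarker-discovery workflow for
predicting pathological complete response (residual cancer burden
RCB = 0) to neoadjuvant chemotherapy in triple-negative breast cancer:
per-CpG differential methylation on 450K-style β values, targeted
replication in an independent cohort, a two-gene linear methylation score
with an AIC-selected gene set and a ROC/Youden decision cutoff, and
methylation–expression coupling by ΔΔCt. This note records the models,
the parameters that matter, the numerical conventions, and what the
bundled simulation does and does not establish.

## Statistical core

**Rank-sum test.** Group comparisons use the two-sided Wilcoxon rank-sum
/ Mann–Whitney U test (the two names denote the same test; one
implementation serves every stage). The exact permutation distribution is
used when the combined sample size is ≤ `exact_limit` (default 20) and
the pooled values carry no ties — discovery cohorts of 10 vs 14 per-gene
comparisons sit inside this regime for pyrosequencing data, while
per-probe array comparisons at n = 24 fall back to the normal
approximation with tie and continuity correction. Constant pooled input
is degenerate: U = n₁n₂/2, p = 1, flagged rather than erroring, because a
flat probe carries no evidence either way.

**Spearman correlation** uses midranks for ties and the t-approximation
p-value, t = ρ√((n−2)/(1−ρ²)) on n−2 df; ρ is undefined (raised) for a
constant margin.

**ROC machinery.** AUC is the pairwise-wins probability
U/(n₊·n₋) with ties half-counted, computed from midranks, which makes the
identity AUC = U/(n₊n₋) with the rank-sum U an exact internal invariant
rather than an approximation. Candidate cutoffs are −∞ plus every
observed score; a sample is called positive when score **>** cutoff
(strict). The operating point maximises Youden's J = sensitivity +
specificity − 1, ties broken toward the smallest cutoff so output is
deterministic. Confidence intervals are percentile bootstrap over
unstratified case resamples (default 1000 iterations, seeded); a
resample that loses a class is redrawn and the redraw count reported.
Percentile rather than BCa or normal-theory was chosen as the simplest
convention consistent with "bootstrap CI"; with n in the tens the three
differ little relative to the interval width.

**Logistic regression / AIC.** Model selection uses maximum-likelihood
binomial logistic regression with intercept, AIC = 2k − 2ℓ with k
counting the intercept. The intercept-only null is evaluated in closed
form. Quasi-complete separation has no finite MLE: the fit is flagged
`converged=False` and coefficients/AIC are reported at the iteration cap
(Newton, BFGS fallback, `maxiter=200`), which keeps AIC comparisons
well-defined while making the flag visible downstream.

**Sample-size design.** Two-proportion per-group n uses the unpooled
normal approximation without continuity correction,
n = ⌈(z₁₋α/₂ + z_power)²(p₁q₁ + p₂q₂)/(p₁−p₂)²⌉, and drop-out inflation
is multiplicative, ⌈n·(1+d)⌉. These two conventions jointly reproduce
the canonical worked design for 45% vs 10% at α = 0.05 / power 0.80:
22 per group, 44 total, 51 after 15% drop-out (division by 1−d would
give 52 instead).

## Discovery cascade

Five filters applied in fixed order, each probe recording the *first*
filter it failed (so step counts are monotone non-increasing and
reconcile exactly with the input):

1. **p < 0.05**, unadjusted. No multiple-testing correction is applied at
   this step because the downstream filters, replication cohort and
   direction-concordance requirements carry the burden of false-positive
   control; an optional Benjamini–Hochberg flag (`bh_correct`) exists and
   defaults off.
2. **|Δβ| ≥ 0.20**, where Δβ = mean_NR − mean_R. The absolute value is
   used so both hypermethylated-in-NR and hypermethylated-in-R probes
   pass, which is what produces the two candidate classes.
3. **Promoter island/shore context**: island relation ∈ {Island, N_Shore,
   S_Shore} AND at least one gene-group annotation ∈ {TSS1500, TSS200,
   5'UTR, 1stExon}. The conjunction (rather than island-relation alone)
   is the reading that keeps the filter meaning "regulatory promoter
   CpGs".
4. **Intragroup SD ≤ 0.20 in both groups** — "intragroup" names neither
   group, so both must be tight; a probe wildly variable in either group
   is not a reliable marker.
5. **Consecutive-CpG consistency**: neighbours are tested probes of the
   same gene on the same chromosome within ±`window_bp` (default 1000 bp);
   a neighbour is concordant when it shares the probe's Δβ sign at
   |Δβ| ≥ `concordance_delta` (default 0.10); the probe passes with
   ≥ `min_concordant` concordant neighbours (default 2, or all neighbours
   when fewer exist). Probes with no neighbours fail by default
   (`zero_neighbors_pass` flips this). All three knobs are config keys:
   "consistent profile over consecutive CpGs" is a qualitative criterion
   and this rule is this package's explicit, reproducible reconstruction
   of it.

Probes with > `max_missing_frac` (default 0.2) missing values, or missing
in an entire group, are excluded before testing with a logged reason.
Multi-gene probes (semicolon-joined annotations) support every annotated
gene, so overlapping-transcript loci appear as distinct candidate genes
sharing probes. If a gene somehow collects survivors of both directions,
the direction with the larger total |Δβ| is kept (logged); this did not
occur in any simulation.

## Replication stage

Array β values live in [0,1]; pyrosequencing and everything downstream
use percent (0–100). The conversion happens exactly once, at the
validation boundary (×100). Per-sample gene methylation is the unweighted
mean over the assay's CpGs (missing CpGs dropped per sample). A gene
**replicates** when the rank-sum p beats α = 0.05 *and* the sign of the
percentage difference matches the array direction — direction
concordance is required because a significant flip is evidence against
the candidate, not for it. A direction-concordant p in [α, 0.20) is
annotated as a **trend**; trend-level genes may be carried into model
selection (`allow_trend`, default on) but the annotation never upgrades
a replication verdict. Covariate screens use the rank-sum test for
two-level covariates and Kruskal–Wallis for ≥ 3 levels; numeric
covariates such as age are dichotomized at the median unless `age_cut`
is set (the grouping convention is not standardised, so it is explicit
and configurable).

## Signature model

Candidate subsets of size 1..`max_genes` (default 2) are fit by logistic
regression on the pooled cohorts and compared by AIC against the
intercept-only null. A subset must beat the null by more than
`aic_margin`, default 4 — the conventional ΔAIC threshold below which
models are considered near-equivalent. The margin matters because the
minimum AIC over many candidate subsets is biased downward: with five
pure-noise candidates and margin 0, some subset "beats" the null roughly
half the time by selection alone, whereas margin 4 suppresses essentially
all of these while leaving genuine two-gene signals untouched.

The published form of such rules is an intercept-free weighted sum
compared to a constant. The logistic intercept shifts every score
equally, so it is dropped from the score and absorbed into the cutoff:
score = Σ coefficient_g × methylation_g(%), with the cutoff re-derived on
the score scale by Youden. Consequently the cutoff value is
data-dependent (it moves if the coefficients are rescaled) and is never
hard-coded. Performance is reported as "k out of n (p%)", percentage to
one decimal: the fraction of score-positive samples with RCB = 0
(`rate_above`) and the score-negative analogue (`rate_below`). The model
is fit and evaluated on the pooled cohorts (in-sample, as the small-n
setting dictates); no cross-validated generalisation estimate is
produced, and the reported AUC should be read accordingly.

## Expression coupling

ΔΔCt with perfect doubling: replicate Cts are averaged on the Ct scale
(standard practice — averaging folds would bias the estimate), ΔCt =
target − endogenous control per sample, ΔΔCt references a calibrator
sample (a required, explicit choice), fold = 2^(−ΔΔCt), so the
calibrator's fold is exactly 1 and a common Ct shift of both genes in a
sample cancels. Group comparisons and the demethylating-treatment
contrast (methylation and expression endpoints tested independently) use
the rank-sum test; with the triplicate design (3 vs 3) the smallest
attainable two-sided exact p is 2/20 = 0.1. Methylation–expression
correlation is Spearman.

## Synthetic data

The generator emulates the study design so every stage can be exercised
with known ground truth:

* **Manifest**: genes laid out on synthetic chromosomes; each gene gets a
  promoter run of ⌈c/2⌉ CpGs ~100–160 bp apart (island core of
  ⌈k·islands_fraction⌉ probes flanked by shores — so every gene keeps at
  least one promoter-island probe when the fraction is positive) plus
  body probes placed ≥ 5 kb downstream, outside the neighbour window.
* **β matrix**: unplanted probes share a bimodal per-probe baseline
  (Beta(2,18) / Beta(18,2) / Beta(4,4) mixture at 40/40/20%, mimicking
  the hypo/hyper-methylated modes of array data) with Gaussian noise of
  `noise_sd` (default 0.10) on the β scale, clamped to [0,1]. Noise is
  added on the β scale, not logit, so the SD filter's 0.20 threshold
  means exactly what it says.
* **Planted genes** separate the group means by `delta` on their first
  `n_consecutive_cpgs` promoter CpGs. Within-group SD `sd_within` is
  split 80/20 (variance-wise) into a per-sample biological component
  shared across the gene's CpGs and per-probe technical noise; the
  biological component is returned as the per-sample *latent* truth.
* **Pyrosequencing** re-measures the latent truth with independent noise
  (`pyro_noise_sd`, percentage points) — technical replication — or
  draws fresh biology from the planted means when no latent table is
  supplied (independent-cohort replication). `delta_validation` lets a
  planted gene's effect differ between cohorts, which is how the demo
  emulates discovery hits that fail to replicate.
* **Expression**: ΔCt = `dct_base` − coupling × methylation with
  coupling < 0 in log2-expression units per unit β (default −4), plus
  per-read technical noise (`ct_noise_sd`, default 0.15 cycles), GAPDH-
  style control near `reference_ct`.

Demo defaults: discovery 10 R vs 14 NR, validation 9 R vs 21 NR, 60 genes
× 8 CpGs (480 probes — sized so a full run takes about a second; the
filters operate per probe, so behaviour does not change with manifest
size), six planted genes with |Δβ| 0.24–0.30 and within-group SD
0.10–0.15, of which one replicates fully in the validation cohort and one
at trend level.

What the simulation does **not** emulate: chip/batch effects, cell-type
composition, probe cross-reactivity, copy-number confounding, spatially
correlated noise along the genome, or realistic linkage between clinical
covariates and methylation. Passing the recovery suites therefore shows
the pipeline implements its stated selection logic correctly and has the
expected power under clean planted effects — not that the thresholds are
optimal for real tumour data.

## Determinism and numerical conventions

Every stochastic component takes an explicit integer seed; pipeline
stages receive seeds derived from the config seed via `SeedSequence`, so
an identical config + seed reproduces byte-identical outputs including
the 1000-iteration bootstrap CI. Youden ties break toward the smallest
cutoff; score-positivity is strict (>); Δβ is always mean_NR − mean_R;
manifest positions are 1-based, BED exports 0-based half-open, and the
two converters are inverses. Missing values are empty cells on disk
("NA" accepted on read, never written).

## Known limitations

* The consecutive-CpG consistency rule is a declared reconstruction of a
  qualitative criterion; its window/count/magnitude defaults are this
  package's own and are exposed in config.
* Replication verdicts at validation-cohort size (9 vs 21) are noisy;
  near-null planted genes occasionally replicate by chance, as the
  examples show.
* The signature's performance estimates are in-sample; with ~40–54
  patients and in-sample Youden cutoffs, reported AUCs and rates are
  optimistic relative to external validation.
* AIC pair-recovery under the bundled two-predictive-gene conditions runs
  at roughly 85%: individual 20-seed batches can land a few points either
  side of that.
* Exact rank-sum enumeration is only used for untied samples; heavily
  tied small samples fall back to the corrected normal approximation,
  which is conservative at the extremes.
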