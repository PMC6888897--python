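# Methods

This note documents the statistical procedures implemented in `kdsig`, the
assumptions behind them, the defaults of the synthetic-data generators, and
the numerical conventions that matter for reproducing results.

## The knockdown-signature procedure

The toolkit operationalizes a common transcriptomic workflow: a gene of
interest (in the motivating application, thymidylate synthase, TYMS/TS, in
breast-cancer cells) is knocked down; genes responding to the knockdown
define a two-sided signature; and the signature is used to position patient
tumors along a knockdown-like-to-wildtype-like axis that is then tested for
prognostic value.

**Signature derivation.** Given a knockdown-vs-control expression matrix,
per-gene log2 fold changes are computed on group means — `mean(kd) −
mean(ctrl)` on the log2 scale, `log2(mean(kd)/mean(ctrl))` on the linear
scale (genes with a non-positive group mean are excluded, since their ratio
is undefined). Genes with |log2FC| ≥ log2(cutoff) enter the signature; the
default cutoff is 2-fold and the boundary is inclusive (an exactly-2-fold
gene is admitted). Fold change on means rather than medians matches the
FPKM-style comparisons such signatures are typically derived from. No
significance filter is applied by default because the procedure is defined
by the fold cutoff alone; an optional Welch t-test with Benjamini–Hochberg
correction can be combined with it (`q_filter`), since some pipelines do
restrict fold-change cutoffs to statistically significant genes.

**KD score.** Each gene of the cohort being scored is z-scored across that
cohort's samples (sample SD, n−1 denominator); the cohort is its own
reference population, so each retained gene row has mean 0 and unit SD, and
consequently the KD scores of a cohort always sum to zero — a property the
tests exploit. The score of sample *s* is

    KD(s) = Σ_{g ∈ up} z[g, s] − Σ_{g ∈ down} z[g, s]

A high score means the sample resembles the knockdown state. The sums are
deliberately *not* divided by list length (the score is defined as a sum);
a length-normalized variant (`normalized=True`) exists for comparing
signatures of different sizes. Zero-variance genes are dropped before
z-scoring; signature genes absent from the matrix are skipped and counted.
Scores are computed on the matrix in its declared scale; no re-log
transformation is applied, and the scale used is recorded in the score
table's metadata rather than guessed.

**Stratification.** Median split by default, with ties assigned to the
"low" group (deterministic and documented); tertiles and fixed cutoffs are
available. Median and fixed rules require ≥ 2 samples per resulting group.

## Survival analysis

The Kaplan–Meier product-limit estimator, the two-group log-rank test and
an O/E hazard-ratio approximation are implemented natively.

* KM: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event times; censored
  observations reduce the risk set only. Ties between events and censorings
  at the same time follow the standard convention that events come first.
* Log-rank: at each distinct event time with n at risk, d events and n₁ at
  risk in group 1, E₁ accumulates d·n₁/n and the hypergeometric variance
  accumulates d·(n₁/n)·(1−n₁/n)·(n−d)/(n−1) (zero when n = 1);
  χ² = (O₁−E₁)²/V is referred to chi-square with df = 1. Zero total
  variance raises an explicit degenerate-test error.
* Hazard ratio: (O₁/E₁)/(O₂/E₂), the quantity KM-plot annotations
  conventionally report; it is an approximation, not a Cox estimate — Cox
  regression, multivariate adjustment and competing risks are out of scope.

**Best-cutoff stratification.** Mirroring the "auto select best cutoff"
option of popular KM-plotting services, all distinct score values between
the 10th and 90th percentiles are scanned as thresholds and the one with
the minimum nominal log-rank p is chosen. Because minimum-p scanning
inflates type-I error, a permutation-adjusted p is always computed
alongside: score–survival pairings are permuted (default 1000 times,
seeded) and the adjusted p is the add-one-corrected fraction of
permutations whose minimum p is at least as small as the observed one.
Both values are reported.

**Curve dominance.** The regression-style check "group A's curve is worse
than group B's" is defined on the window where both estimates carry
information: from the first time at which both groups have had an event
(before its first event a group's estimate is the uninformative constant 1)
up to the earlier of the two groups' last observed follow-up times (a KM
curve is not extrapolated beyond its group's last observation). Within the
window, dominance means S_better(t) ≥ S_worse(t) at every distinct event
time. Early crossings — the merged cohort's first events falling in the
better group — still count as violations; with a strong effect they occur
in a minority of replicates and the directionality check tolerates them by
requiring dominance in ≥ 90% of simulated cohorts rather than all.

## Preranked GSEA

Genes are ranked by signal-to-noise ratio (default), Welch t, or Pearson
correlation with a continuous covariate, descending, with lexicographic
gene-id tie-breaking so rankings are identical across platforms. The
signal-to-noise denominator floors each group SD at max(0.2·|group mean|,
0.2), the classic stabilization used by the reference desktop
implementation, so zero-variance genes never divide by zero.

For a set with N_h hits in a list of N genes, the running sum gains
|metric|^p / Σ_hits |metric|^p at each hit and loses 1/(N − N_h) at each
miss; ES is the signed maximum-magnitude deviation. The walk returns to
zero by construction, and |ES| = 1 exactly when all hits precede all misses
(p = 0). The default weight is p = 1 (the cited software's default);
p ∈ {0, 1, 2} is supported.

The null distribution reassigns set membership uniformly at random among
ranked genes (same set size). Gene permutation — rather than phenotype
permutation — is the appropriate null for preranked input and remains valid
for small cohorts; this is a documented divergence from class-label GSEA.
NES = ES / mean(|null ES| of the same sign); nominal p is the add-one
(Laplace) corrected fraction of same-sign null scores at least as extreme,
so p is never exactly 0 and never smaller than 1/(1+n_perm). If no null
score shares the observed sign, p is reported at that floor with a
`sign_underflow` flag and NES as NaN. Null scores are computed by a
vectorized routine that evaluates the walk only at hit positions (between
hits the sum decays linearly, so extrema occur at hits); the tests verify
it against a literal position-by-position walk. FDR q-values across sets
are intentionally not computed by default; NES and nominal p are the
reported quantities.

## Auxiliary metrics

* **H-score** uses the Σ P_i·(i+1) variant over intensity levels i = 0..3,
  giving a 100–400 range — not the more common Σ P_i·i (0–300) form.
  Percentages must sum to 100 (±0.01).
* **EMT classification** by the linear-scale VIM/CDH1 ratio: < 2 epithelial,
  > 2 mesenchymal. A ratio exactly at the threshold maps to "intermediate",
  since strict inequalities leave it unassigned; a three-class split over a
  ratio *band* (e.g. [1.5, 2.5]) is available but must be supplied
  explicitly — no implicit band is assumed for real data.
* **ΔΔCt**: fold = 2^(−ΔΔCt) with ΔΔCt = (Ct_target − Ct_ref)_case −
  (Ct_target − Ct_ref)_ctrl.
* **Relative wound density**: RWD = 100·(w_t − w_0)/(c_t − w_0), clipped to
  [0, 100], undefined unless the outside region is denser than the initial
  wound. This is the vendor-style normalization consistent with
  "proliferation inside the wound normalized to proliferation outside";
  the exact vendor formula is proprietary, so this explicit form is the
  package's documented choice.

## Synthetic-data generators

All generators are pure functions of their parameters and one integer
seed; each operation draws from its own named stream, so adding draws to
one generator never perturbs another.

**Discovery** (`make_discovery`): log2-scale matrix; gene baselines ~
U(3, 12) (typical normalized-array intensity range), i.i.d. Gaussian noise
with SD `sigma` (default 0.3), and a planted subset shifted by
±`effect_log2fc` (default 1.5) in the knockdown group. Defaults: 1000
genes, 5 vs 5 samples, 84 up / 73 down planted genes. Gaussian noise on the
log2 scale (log-normal linear expression) is the standard convention for
normalized array / FPKM-like data; the effect size and noise level are the
package's conventions for a clean knockdown experiment, chosen once.

**Cohort** (`make_cohort`): latent activity a ~ N(0, 1) per patient;
signature up-genes shifted +a·effect, down-genes −a·effect (default effect
1.0, sigma 0.3, 100 unrelated background genes). Survival is exponential
with hazard h₀·exp(−β·a) — the simplest proportional-hazards generator; the
negative sign fixes the direction high activity ⇔ high KD score ⇔ low
hazard, so the *low*-score group is the poor-prognosis group. Defaults
h₀ = 0.02/month (median survival ≈ 35 months, plausible for a mixed
breast-cancer cohort) and independent exponential censoring at
0.01/month (≈ one third censored). Censoring draws use a dedicated
inverse-transform stream, making the censored fraction pathwise monotone in
the censoring rate at fixed seed — a property the tests assert.

**Marker panel** (`make_marker_panel`): linear-scale VIM and CDH1 for a
52-line panel (27 epithelial / 19 mesenchymal / 6 intermediate by default).
Log2 VIM/CDH1 ratios are N(−2, 0.7), N(+3, 0.7) and N(+1, 0.15) for the
three phenotypes, placing intermediates tightly around ratio 2 (inside the
band [1.5, 2.5] exported as `DEFAULT_INTERMEDIATE_BAND`).

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: gene–gene correlation structure, batch and
platform effects, library-size or count-level noise, non-proportional
hazards, informative censoring, and subtype covariate structure beyond a
single latent activity. Results on these synthetic cohorts demonstrate
that the *procedures* are implemented correctly and calibrated, not that
any particular biological signature is prognostic.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks use: 1000 replicate cohorts of n = 100 (null
calibration of the log-rank split at α = 0.05); 50 cohorts of n = 200 at
β = 1 (directionality); 20 discovery replicates at the default 84/73
planting (signature recovery); 100 random instances with N ≤ 20 (enrichment
walk vs brute force); 200 replicates × 200 permutations (GSEA null
uniformity); and 50 random small datasets (KM/log-rank cross-check against
lifelines). These sizes make the binomial/KS acceptance bands decisive
while the whole suite runs in about a minute.

## Numerical conventions and degenerate inputs

* Ties: median/fixed stratification sends ties low; ranking ties break
  lexicographically; simultaneous events/censorings treat events first.
* Duplicate gene ids on load collapse to the highest-mean row; rows with
  missing values are dropped and logged; textual junk in numeric cells is a
  hard format error naming the cell.
* Zero-variance genes are dropped before z-scoring and floored in
  signal-to-noise ranking.
* Single-sample matrices, empty groups, all-tied scores, eventless
  survival data and zero log-rank variance all raise typed errors rather
  than returning NaN.
* Expression TSV round-trips are bit-exact: files are parsed with Python's
  `float()` (pandas' fast path can be one ulp off).

## Known limitations

* The hazard ratio is an O/E approximation, not a Cox estimate; for
  covariate-adjusted effects use a dedicated survival package.
* Gene-permutation GSEA p-values ignore inter-gene correlation; on real
  cohorts they are anti-conservative relative to phenotype permutation.
* The best-cutoff scan's adjusted p controls selection over thresholds,
  not over multiple signatures or datasets.
* Signature derivation has no fold-change shrinkage or dispersion
  modeling; it reproduces the plain cutoff procedure by design.
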