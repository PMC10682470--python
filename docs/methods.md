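# Methods

`interactdeg` analyses gene expression counts from two-factor designs — here
a diet factor (standard diet SD vs Western diet WD) crossed with feeding
duration in weeks — and contrasts two ways of asking "did the diet effect
change over time?" for every gene.

## Count model

For gene *i* and sample *j* the read count is modelled as negative binomial,

    K_ij ~ NB(mu_ij, tau_i),    mu_ij = s_j * q_ij,
    log2(q_ij) = sum_r beta_ir * x_jr,

with variance `mu + tau * mu^2`. The pieces are:

* **Size factors `s_j`** — sample-specific library-size scalars estimated by
  median-of-ratios: over genes with positive counts in every sample, the
  median of `K_ij / geometric_mean_j'(K_ij')`. Robust as long as the
  majority of genes are unaffected by the conditions, which is why the
  synthetic datasets keep most background genes null (see below).
* **Dispersion `tau_i`** — per-gene overdispersion, estimated by maximising
  the Cox–Reid adjusted profile likelihood (the NB log-likelihood at the
  fitted means plus `-0.5 * logdet(X'WX)`). The adjustment compensates for
  estimating the mean coefficients and avoids the systematic downward bias
  of the plain profile MLE at the small per-cell sample sizes (3–8) typical
  of these designs; without it the Wald test's type-I error drifts above its
  nominal level. The search is a vectorised bracketed grid refinement over
  `log(tau)` in `[log(1e-8), log(25)]` (six halving rounds, final relative
  resolution well under 1%), with a method-of-moments fallback when the
  profile is degenerate. Dispersion trends across genes and empirical-Bayes
  shrinkage of dispersions are deliberately not modelled; each gene stands
  alone.
* **Coefficients** — dummy (treatment) coding with reference levels SD and
  the smallest week. For `~ diet + weeks + diet:weeks` on weeks {3, 6}:
  intercept `mu` (log2 expression at SD/week 3), diet main effect `alpha`
  (log2 fold change SD→WD at week 3), week effect `beta_2`, and the
  interaction `gamma_2` — the amount, in log2 units, by which the diet
  effect at week 6 differs from the diet effect at week 3. `gamma_2 = 3`
  therefore means the diet fold change is `2^3 = 8` times larger at week 6.
  Fitting is IRLS on the natural-log scale (all genes vectorised), offset
  `log(s_j)`, initialised from least squares on `log(K/s + 0.5)`, step
  halving on deviance increases, at most 100 iterations, relative deviance
  tolerance 1e-8; reported coefficients and standard errors are divided by
  `ln 2`. One alternation is used: IRLS at a method-of-moments dispersion,
  dispersion re-estimated at the fitted means, final IRLS.

Genes with an all-zero design cell are flagged `degenerate_cell` rather than
reported with infinite fold changes; non-convergence and undefined standard
errors are flagged likewise, and flagged genes propagate NaN statistics.

## Testing and shrinkage

Wald tests divide the raw log2 fold change by its standard error and refer
to the standard normal; p-values are Benjamini–Hochberg adjusted within each
results table (per week for Method I, per interaction contrast for
Method II). Log2 fold changes are additionally shrunk with a zero-centred
normal prior whose variance is estimated from the spread of the raw
estimates in excess of their sampling noise (`mean(lfc^2) - mean(se^2)`);
the shrunken value is the posterior mode `lfc * prior^2 / (prior^2 + se^2)`.
This is a deliberately simple adaptive-prior scheme, not a reimplementation
of heavy-tailed approximate-posterior shrinkage; when the excess spread is
degenerate the raw estimates are returned with a warning. Significance is
always tested on the raw estimate; the relevance threshold is applied to
the shrunken estimate by default (`lfc_basis="raw"` switches this), since
shrinkage is meant to stop noise-driven effects from passing the relevance
bar while leaving precise large effects untouched.

## DEG decisions

With defaults `alpha_fdr = 0.05` and `lfc_threshold = log2(1.5) ≈ 0.585`
(both strict inequalities, applied post hoc):

* **Method I** fits `~ diet` separately per week (size factors and
  dispersions re-estimated within each week's subset — the two weeks are
  genuinely separate datasets). DEG = significant and relevant at the
  target week but not both at the reference week; direction = sign of the
  target-week diet effect. The reference-week disqualification is
  direction-agnostic by default; `ref_rule="same_direction"` implements the
  per-direction bookkeeping needed for directional overlap tables.
* **Method II** fits `~ diet + weeks + diet:weeks` once. DEG = interaction
  coefficient significant and relevant; direction = sign of the interaction.

The effect-plane classifier (`classify_region`) characterises the two rules
geometrically with x = estimated diet main effect at the reference week and
y = x + interaction (the overall diet effect at the target week), both
unshrunken and p-value-free: Method I selects `|x| <= t` and `|y| > t`,
Method II `|y - x| > t`, giving the four regions (neither / I only / both /
II only). A significance-aware variant attaches the per-contrast adjusted
p-value booleans to each gene.

## Synthetic data

The generator emulates the structure the analysis assumes — NB counts with
gene-specific dispersion, sample-specific size factors, a 2x2 (extensible)
diet x week design with per-cell sample sizes in the single digits to tens,
and configurable per-gene main and interaction effects on the log2 scale.
It does **not** emulate a real transcriptome's joint distribution of
baselines, dispersion–mean trends, or correlated genes: passing tests show
the estimators and decision rules behave correctly under the model's own
assumptions, not that the model captures every property of real libraries.

`seven_cases` builds the seven canonical decision scenarios in which the
two methods agree or disagree: (1) no effects; (2) effect only at week 6;
(3) relevant at both weeks, much larger at 6; (4) sign change, both
relevant; (5) both near the relevance threshold and of similar size; (6)
sign change with a negligible week-3 effect; (7) opposite sub-threshold
effects whose difference is large. Expected (Method I, Method II) pattern:
(–,–), (D,D), (–,D), (–,D), (D,–), (D,D), (–,D).

Default parameters were set by a design-time power calculation so that
every binary decision in the pattern has a margin of at least ~2.4 standard
errors: dispersion 0.01 for every gene (the count-data analogue of the
constant residual variance these schematic scenarios assume), baseline
log2 mean `log2(1000)`, 20 samples per cell, "clearly relevant" effects at
3x the threshold, case-5 effects at 0.8x/1.2x and case-7 at ±0.7x the
threshold. Each dataset carries 200 background genes — uniform log2
baselines in [5, 11], 30% with diet effects N(0, 0.8), 15% with their own
interaction — for three reasons: size factors need all-positive,
majority-null genes to anchor the median of ratios (an all-effect
background measurably biases per-week normalisation and flips the
near-threshold cases), the BH adjustment needs a realistic family, and the
shrinkage prior must be wide, as on real data, so near-threshold true
effects are not shrunk below the relevance bound. Sample-specific size
factors are lognormal with sd 0.15 on the log scale, normalised to
geometric mean 1. A single seed expands into per-gene substreams, so
identical seeds give bit-identical matrices.

## Power study

In the balanced 2x2 normal model with dummy coding, the interaction
estimate is a difference of differences of cell means with variance
`4 sigma^2 / n` per cell, versus `sigma^2 / n` for the additive-model main
effect. Power depends on effect/SE and contrast variances scale as `1/n`,
so detecting an interaction of a given size at the power of an equally
sized main effect requires four times the total sample size.
`power_curve` measures power by simulating the sufficient statistics (cell
means and the within-cell sum of squares); `interaction_sample_size_factor`
reports the variance ratio directly. The package-wide Wald z reference is
the default test; with exact t references the two comparisons carry
different residual degrees of freedom (`n_total - 3` vs `n_total - 4`), so
the 4x equality is exact only asymptotically — at a total of 8 samples the
t-based powers differ visibly, which is a property of small-sample t
calibration, not of the variance relationship. `use_t=True` is provided,
and the closed-form noncentral-t check validates that mode. The NB-response
mode simulates replicates as independent genes through the full GLM and is
expected to follow the 4x rule only approximately.

`compare_methods` runs both full pipelines over regenerated case datasets
and tabulates per-method DEG rates with Monte-Carlo standard errors
`sqrt(p(1-p)/n_reps)`, partitioned by whether the true interaction is zero.

## Numerical and design choices

* log2 link everywhere at the interface; natural-log internals.
* Dispersion floor 1e-8 (Poisson limit), ceiling 25.
* Relevance threshold comparisons are strict (`>`), so an effect exactly at
  `log2(1.5)` is not relevant; "more than 50% zeros" and "fewer than ten
  reads total" in the gene filters are likewise strict.
* Week subsetting happens before filtering, so the filter sees exactly the
  per-analysis sample set.
* All randomness flows from `numpy.random.SeedSequence` spawns of one seed.
* Problem sizes used by the packaged checks (chosen for desk-scale
  reproducibility): 2000 genes for calibration/recovery runs, 2000
  Monte-Carlo replicates per power point, 100 seeds for the seven-case
  pattern, 50 samples per cell for the fold-change recovery example.

## Known limitations

* The Wald z reference is slightly anti-conservative at very small per-cell
  n; no exact small-sample correction is attempted.
* Shrinkage uses a single normal prior for all genes of a contrast; strong
  asymmetric or heavy-tailed effect distributions are only approximated.
* No outlier replacement, independent filtering, or likelihood-ratio tests.
* Genes are fitted independently; no information sharing across genes
  beyond the shrinkage prior and the BH family.
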