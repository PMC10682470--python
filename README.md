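# interactdeg

Interaction-aware differential expression analysis for two-factor RNA-seq
designs.

## The problem

A common design in expression studies crosses a treatment with time: mice
receive a standard diet (SD) or a Western diet (WD) and are profiled after
3, 6, … weeks. The biological question is usually *"for which genes does
the diet effect change over time?"* — mathematically, which genes have a
non-zero **interaction effect** between diet and week. In practice many
analyses instead fit a separate two-group comparison per week and intersect
the DEG lists, which answers a related but different question and behaves
differently near the decision thresholds.

`interactdeg` implements both procedures on a shared per-gene negative
binomial GLM with a log2 link,

    K_ij ~ NB(mu_ij, tau_i),  mu_ij = s_j * q_ij,
    log2(q_j) = mu + alpha·d_j + Σ_r beta_r·w_jr + Σ_r gamma_r·d_j·w_jr,

with median-of-ratios size factors `s_j`, Cox–Reid adjusted profile-ML
dispersions `tau_i`, Wald tests with Benjamini–Hochberg FDR control, and
empirical-Bayes shrinkage of log2 fold changes. A gene is a DEG when it is
both *significant* (adjusted p < 0.05) and *relevant* (|log2FC| >
log2(1.5)):

* **Method I (separate)** — fit `~ diet` per week; DEG iff the diet effect
  passes both criteria at week 6 but not at week 3.
* **Method II (interaction)** — fit `~ diet + weeks + diet:weeks` once;
  DEG iff the interaction coefficient `gamma_r` passes both criteria.
  An interaction of `gamma_2 = 3` means the diet fold change is `2^3 = 8`
  times larger at week 6 than at week 3.

The package also ships a synthetic-data generator reproducing the seven
canonical scenarios where the methods disagree, an effect-plane classifier
of the four agreement regions, per-direction overlap tables, interaction-
plot "arrow" decompositions, and a Monte-Carlo power module that exhibits
the classical result that detecting an interaction needs four times the
sample size of an equally sized main effect.

## Worked example

Scenario 7 of the generator: the diet effect is +0.41 log2 units at week 3
and −0.41 at week 6 — each below the relevance threshold log2(1.5) ≈ 0.585,
but their difference (the interaction) is large.

```python
import numpy as np
from interactdeg import seven_cases, run_method_one, run_method_two, crosstab

ds = [d for d in seven_cases(seed=1) if d.spec.case_id == 7][0]
run_i = run_method_one(ds.counts, ds.metadata)
run_ii = run_method_two(ds.counts, ds.metadata, target_week=6)

print(run_ii.fits["interaction"].summary())
gene = ds.signal_gene
t6 = run_i.tests["week6"].loc[gene]
ie = run_ii.tests["diet[WD]:weeks[6]"].loc[gene]
print(f"{gene}: week-6 diet log2FC = {t6.log2fc_shrunk:+.3f} (padj {t6.padj:.2e})")
print(f"{gene}: interaction log2FC = {ie.log2fc_shrunk:+.3f} (padj {ie.padj:.2e})")
print("Method I :", run_i.decisions.loc[gene, "status"])
print("Method II:", run_ii.decisions.loc[gene, "status"])
print(crosstab(run_i.decisions, run_ii.decisions))
```

prints

```
Per-gene negative binomial GLM (log2 link)
  genes: 201   samples: 80
  design columns: ['Intercept', 'diet[WD]', 'weeks[6]', 'diet[WD]:weeks[6]']
  converged: 201/201   flagged: 0
  dispersion quartiles: 0.008376 / 0.009971 / 0.01156
  size factors: min 0.629, max 1.696

case7_signal: week-6 diet log2FC = -0.411 (padj 4.57e-19)
case7_signal: interaction log2FC = -0.718 (padj 4.41e-29)
Method I : not_deg
Method II: deg_down

      a_only  overlap  b_only
up         0        5       1
down       2        5       2
```

The week-6 effect (−0.411) is highly significant but not relevant, so
Method I misses the gene; the interaction (−0.718) is both significant and
relevant, so Method II calls it a down-regulated DEG — the textbook case
for modelling the interaction directly. The overlap table counts
per-direction DEGs among the 201 genes found by Method I only (`a_only`),
both, or Method II only (`b_only`).

A command-line interface mirrors the library:

```sh
interactdeg simulate --kind seven-cases --out sim/ --seed 1
interactdeg call --counts sim/case7_counts.tsv --metadata sim/case7_metadata.tsv \
    --method II --out decisions.tsv
interactdeg power --target interaction --n 5,10,20,40 --effect 1.0 \
    --reps 1000 --seed 1 --out power.tsv
interactdeg run --config pipeline.yaml   # full pipeline with manifest
```

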