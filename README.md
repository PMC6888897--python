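# kdsig

Derive a knockdown gene signature, score patient tumors with it, and test
whether the score stratifies survival — with native Kaplan–Meier / log-rank
statistics and preranked GSEA, plus the small quantitative assays that
accompany such studies.

## The problem

When a regulator gene (the motivating case is thymidylate synthase,
TYMS/TS, in breast cancer) is knocked down in a cell line, the genes that
respond define a two-sided transcriptional signature: a set **up** of genes
induced by the knockdown and a set **down** of genes repressed by it. A
patient tumor whose transcriptome resembles the knockdown state should
score high on this signature; if the regulator drives an aggressive
phenotype, low-scoring (regulator-high-like) patients should fare worse.
`kdsig` implements that entire chain as a tested, reusable pipeline:

1. **Signature derivation** — per-gene log2 fold change on group means;
   genes with |log2FC| ≥ log2(cutoff) (default 2-fold, boundary inclusive)
   enter the signature.
2. **KD score** — each gene is z-scored across the cohort, then for sample
   *s*:

   `KD(s) = Σ_{g∈up} z[g,s] − Σ_{g∈down} z[g,s]`

3. **Stratification and survival** — median split (or tertiles, fixed, or
   minimum-p "best cutoff" with permutation correction), Kaplan–Meier
   product-limit curves, the log-rank test
   `χ² = (O₁−E₁)²/V` with hypergeometric variance, and an (O/E)-ratio
   hazard-ratio annotation.
4. **Preranked GSEA** — signal-to-noise (or t / Pearson) ranking, the
   weighted KS-like running sum (`ES` = signed extremum), gene-permutation
   null, `NES = ES / mean(|null ES| same sign)` and add-one-corrected
   nominal p.
5. **Auxiliary assay math** — VIM/CDH1 EMT ratio calls (< 2 epithelial,
   > 2 mesenchymal), IHC H-score `Σ Pᵢ(i+1)` (range 100–400), ΔΔCt fold
   change `2^(−ΔΔCt)`, and relative wound density
   `100·(w_t−w_0)/(c_t−w_0)`.

Synthetic-data generators (`make_discovery`, `make_cohort`,
`make_marker_panel`) produce all of these inputs with planted ground
truth — planted differentially expressed genes, a latent per-patient
signature activity that drives both expression and an exponential
proportional-hazards survival model, and phenotype-separated marker
panels — so every stage is testable offline. See `docs/methods.md` for the
models, defaults and numerical conventions.

## Worked example

Run the whole pipeline on synthetic data from one config:

```yaml
# run.yaml
outdir: demo_run
seed: 1
cohort:
  synthetic: {n_patients: 150}
gsea:
  n_perm: 200
```

```sh
kdsig run --config run.yaml
kdsig report demo_run
```

prints (abridged):

```
## Signature
- up-regulated genes: 83
- down-regulated genes: 73

## KD scores
- samples scored: 150
- quantiles (min / Q1 / median / Q3 / max): -311.472 / -123.853 / -0.035 / 108.834 / 371.918

## Survival
- log-rank chi-square = 32.1884 (df=1), p = 1.4e-08
- hazard ratio (high vs low): 0.349

## Enrichment (top sets)
- SIGNATURE_UP (size 83): NES = -3.463, p = 0.00877
- SIGNATURE_DOWN (size 73): NES = 3.443, p = 0.00926
```

Reading the numbers: the 2-fold cutoff recovers a 83-up / 73-down
signature from the simulated 5-vs-5 knockdown experiment (84/73 genes were
planted). Scoring a 150-patient cohort whose hazard falls with latent
signature activity and splitting at the median KD score, the high-score
(knockdown-like) group has about a third the event rate of the low-score
group (HR 0.349) and the difference is decisive (log-rank p ≈ 10⁻⁸) — the
low-score group is the poor-prognosis group, as the sign convention
intends. Ranking cohort genes low-vs-high confirms the signature's own
lists are the extreme sets (up-genes depleted in low-score tumors,
NES < 0; down-genes enriched, NES > 0).

Each step is also available separately (`kdsig simulate`, `kdsig
derive-signature`, `kdsig score`, `kdsig stratify`, `kdsig survival`,
`kdsig gsea`, `kdsig metrics ...`), and as plain library calls:

```python
from kdsig import (make_discovery, fold_changes, build_signature,
                   make_cohort, zscore_by_gene, kd_score, stratify,
                   logrank_test)

expr, groups, truth = make_discovery(seed=1)
sig = build_signature(fold_changes(expr, groups, case="kd"))
cexpr, clinical, _ = make_cohort(sig, n_patients=150, seed=1)
scores = kd_score(zscore_by_gene(cexpr), sig)
labels = stratify(scores).reindex(clinical.sample_ids)
print(logrank_test(clinical.time, clinical.event, labels.to_numpy()))
```

## File formats

Expression: TSV, genes × samples, first column gene id (scale declared by
the caller, `log2` or `linear`). Gene sets: GMT. Clinical: CSV with
`sample_id,time,event` plus covariate columns. Signatures: two-column TSV
(`gene`, `up`/`down`). Ranked lists: two-column `.rnk`-style TSV. All
UTF-8, LF newlines.
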