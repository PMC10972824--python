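# depresist

Pharmacogenomic biomarker and dependency analysis for EGFR-inhibitor
resistance in cancer cell-line (CCL) panels.

Only a small subset of tumours — those carrying activating kinase-domain
mutations in *EGFR* — respond durably to EGFR inhibitors (EGFRi), and even
responders eventually relapse. This package re-implements, as a tested and
reusable pipeline, an integrative panel analysis that asks two questions:

1. **Which transcriptomic signatures predict EGFRi sensitivity beyond
   mutation status?** Cell lines are split into sensitive (EGFRi-S) and
   resistant (EGFRi-R) extremes by the lowest and highest deciles of the
   drug-response AUC (lower AUC ⇔ greater sensitivity). Differential
   expression between the extremes uses an empirical-Bayes **moderated t**
   (posterior variance s̃² = (d₀s₀² + d s²)/(d₀ + d), statistic
   t̃ = logFC / (s̃·√(1/n_R + 1/n_S)) on d₀ + d df), with DEGs gated at
   FDR < 0.01 and |FC| > 2. Signatures are scored per sample with
   **ssGSEA** (rank-weighted ECDF difference, weight rank^α, α = 0.25),
   ranked lists with permutation **GSEA** (ES/NES, minSize 10, maxSize 500,
   nperm 100,000 by default), discrete lists with the **hypergeometric
   test**, and each pathway summarised as the signed score
   sign(NES)·(−log₁₀ FDR). Predictors — signature scores and an ordinal
   mutation-class score (none=0 < II=1 < IV=2 < III=3 < V=4, where class V =
   kinase-domain + oncogenic) — are compared by **AUROC** against EGFRi-S
   membership.
2. **Which druggable genes selectively kill resistant lines?** CRISPR
   knockout effect scores (more negative = more essential) are filtered for
   viability impact, tested per gene with a Student's t oriented as
   (mean_S − mean_R) — so a high positive t flags resistant-selective
   essentiality — and the top-20 resistant-selective genes are intersected
   with a druggable-gene list. Clinical relevance utilities (log-rank,
   single-covariate Cox with Efron/Breslow ties, paired t, Fisher's exact)
   and K = 5 complete-linkage clustering of drug-induced expression changes
   complete the workflow.

Because the original inputs are versioned external databases, the package
ships a **synthetic panel generator** that plants all of the structure the
analysis assumes — a latent sensitivity axis coupling AUC, a signature gene
set, class-V mutations in the sensitive tail, group-selective dependencies,
a 5-cluster perturbation response, and survival cohorts with a known hazard
ratio — so every stage runs and is scored against ground truth with no
download.

## Worked example

```python
from depresist import synthetic, cohort, diffexpr, genesets, dependency
from scipy.stats import spearmanr

panel = synthetic.generate_panel(seed=1)          # 300 lines x 1000 genes
b = panel.bundle
auc = b.responses.mean(axis=1)
groups = cohort.assign_sensitivity_groups(auc, fraction=0.10)
print(len(groups.sensitive), len(groups.resistant))
# 30 30

de = diffexpr.moderated_t_test(b.expression, groups.resistant, groups.sensitive)
up, down = diffexpr.select_deg(de, fdr=0.01, fc=2)
print(len(down), len(set(down) & set(panel.truth["signature_genes"])))
# 50 50        <- every planted signature gene is down in the resistant group

sig = genesets.ssgsea_matrix(b.expression, {"SIG": panel.truth["signature_genes"]})
print(round(spearmanr(sig.loc["SIG"], auc).statistic, 3))
# -0.904       <- signature activity tracks sensitivity (low AUC)

dep = dependency.differential_dependency(b.effects, groups.sensitive, groups.resistant)
print(dependency.nominate_targets(dep, ["DEP_R", "G00100"], top_k=20).index[0])
# DEP_R        <- the planted druggable resistant-selective gene is rank 1
```

The same flow is available from the shell:

```sh
depresist run-all --seed 1 --out results/run
depresist simulate --seed 1 --out data/
depresist stratify --responses data/responses.tsv --fraction 0.1 --out groups.tsv
depresist enrich gsea --gene-sets data/gene_sets.gmt --ranking ranked.tsv --out gsea.tsv
```

## Layout

- `depresist.core_io` — matrix/GMT/gene-list/mutation-table I/O, panel
  intersection, config.
- `depresist.synthetic` — panel, perturbation-experiment and survival-cohort
  generators with ground-truth labels.
- `depresist.cohort` — AUC decile stratification, K-S test, drug–drug
  response correlation.
- `depresist.mutclass` — five-class mutation taxonomy and ordinal score.
- `depresist.diffexpr` — moderated t, BH adjustment, DEG selection.
- `depresist.genesets` — ORA, permutation GSEA, ssGSEA, pathway score.
- `depresist.biomarker` — signature–AUC correlation, ROC/AUROC, predictor
  comparison.
- `depresist.dependency` — viability filter, differential dependency, target
  nomination.
- `depresist.perturbcluster` — z-transform, K=5 complete-linkage clustering,
  per-cluster ORA, PCA.
- `depresist.clinical` — log-rank, Cox HR, paired t, recurrence contrast.
- `depresist.pipeline` / `depresist.cli` — orchestration and shell interface.

See `docs/methods.md` for the statistical details and design choices.
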