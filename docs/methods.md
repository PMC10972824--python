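# Methods

## The data model

The unit of observation is a cancer cell line (CCL) observed in up to four
modalities sharing one identifier space: a genes × lines expression matrix on
the log2(TPM+1) scale, a lines × drugs table of dose-response AUC values
(lower AUC ⇔ greater sensitivity), a per-variant mutation table with an
externally supplied oncogenicity annotation, and a genes × lines knockout
effect ("dependency") matrix in which more negative means more essential.
`core_io.intersect_bundle` restricts all components to their common,
consistently ordered line list before any analysis; identifiers are opaque
case-sensitive strings.

## Stratification

`cohort.assign_sensitivity_groups` sorts lines by AUC and takes the lowest
and highest `floor(f·n)` as the sensitive (S) and resistant (R) extremes,
with f = 0.10 by default. Ties at a boundary break by a stable sort on
(AUC, line id), which makes the split deterministic across platforms and
invariant to any order-preserving transform of AUC. For multi-drug panels
the default is a single per-drug (or drug-averaged) grouping; a stricter
consensus rule (a line must occupy the same extreme for every drug) is
provided because inhibitors of one target often behave comparably but no
canonical pooling rule exists.

## Mutation classes and the ordinal score

Protein-changing variants are classified by residue position relative to a
configurable interval approximating the receptor kinase domain (default
688–875, standing in for exons 18–21) crossed with the oncogenicity flag:
outside/not-oncogenic → II, outside/oncogenic → III, inside/not-oncogenic →
IV, inside/oncogenic → V; any variant implies the superset class I. A line
with several variants takes the maximum class under the ordinal mapping
none=0 < II=1 < IV=2 < III=3 < V=4, which ranks annotated oncogenicity above
location. The mapping is a configuration table, not a constant: the ordering
of III vs IV is a judgement call about oncogenic potential, and users with a
different prior can supply their own. Oncogenicity is always an input
column — it is curated external knowledge and never inferred here. Records
whose protein change has no parseable leading residue (splice-site,
frame-shift grammars) are routed to an "unparsed" report rather than being
silently treated as wild-type. Per-class AUC distributions are compared with
the two-sample Kolmogorov–Smirnov test (asymptotic p); classes with fewer
than two lines are reported but skipped.

## Differential expression: the moderated t

One inference engine serves RNA and protein log-abundance alike: a
two-sample empirical-Bayes moderated t on log expression. Per-gene pooled
variances s² (d = n_R + n_S − 2 df) are assumed to follow a scaled-F
hierarchy with prior (s0², d0); the prior is estimated by method of moments
on log s² — the excess variance of log s² over trigamma(d/2) is inverted
through the trigamma function to give d0, and s0² follows from the mean.
When the observed variances are no more dispersed than sampling noise the
fit returns d0 = ∞ and every variance is shrunk to s0² (the statistic is
then referred to a normal). Otherwise

    s̃² = (d0·s0² + d·s²)/(d0 + d),  t̃ = logFC/(s̃·√(1/n_R+1/n_S)),

with p from a t distribution on d0 + d df. d0 → 0 recovers the ordinary
pooled t exactly. Genes with zero variance in both groups get t = 0, p = 1
and a flag — they carry no within-group evidence — and are excluded from the
prior fit. logFC is oriented R minus S throughout, so swapping group labels
negates logFC and t̃ exactly and leaves p unchanged. The count-model Wald
test used by dedicated RNA-seq packages is intentionally not reproduced:
operating on the log2(TPM+1) scale keeps a single engine for both omics
branches, and the substitution is recorded in the result metadata. "FDR"
means Benjamini–Hochberg step-up throughout the package. DEG gates default
to FDR < 0.01 and |FC| > 2.

## Gene-set statistics

*ORA*: upper-tail hypergeometric p = P(X ≥ k) for the overlap k between a
query and a set, both intersected with an explicit universe.

*Preranked GSEA*: genes ranked by a statistic (descending, stable ties); a
set's enrichment score is the largest-magnitude deviation of a running sum
that steps up by |s_i|^p / Σ_set |s|^p on members (p = 1 by default) and
down by 1/(N−K) on non-members; equal-magnitude positive and negative
extrema resolve to the positive one. The null is gene-label permutation
(random K-subsets of positions), as appropriate for preranked input;
sample-label permutation is unsupported. p = (1 + #{same-sign |ES*| ≥
|ES|})/(1 + #same-sign), NES = ES / mean(|ES*| of matching sign), and sets
with no same-sign permutations get p = 1/(nperm+1) and a flag. FDR is BH
across tested sets — a deliberate, well-defined divergence from the original
ES-pooling scheme, matching how FDR thresholds are used elsewhere in the
pipeline. Null permutations are cached per set size within a call, so
collections with a common set size cost one null sample. Defaults: minSize
10, maxSize 500, nperm 100,000 (tests and the bundled pipeline use smaller
budgets; see "Problem sizes").

*ssGSEA*: for one sample, genes are ranked by expression (top gene gets rank
N; ties break by stable input order) and a set's score is Σ_i [P_in^w(i) −
P_out(i)], the summed gap between the rank^α-weighted ECDF of members
(α = 0.25) and the uniform ECDF of non-members. Optional normalisation
divides by the (max − min) of scores across the collection (or across the
whole sample × set matrix in `ssgsea_matrix`), mirroring the common
implementation's behaviour; it is off by default because downstream use here
is ordinal.

*Pathway score*: sign(NES)·(−log₁₀ FDR), with FDR floored at 1/(nperm+1) so
a zero estimated FDR cannot produce an infinite score.

## Predictor comparison

AUROC is computed by the Mann–Whitney identity (ties between classes count
½), so auroc(s) + auroc(−s) = 1 exactly and any strictly increasing score
transform is irrelevant. Positives are EGFRi-S membership — the lowest AUC
decile — and labels derive only from response data, never from the
predictors. `compare_predictors` adds a percentile bootstrap CI (default
1000 replicates, seeded); lines missing any predictor are dropped listwise
with a logged count.

## Differential dependency and target nomination

Genes first pass a viability filter: mean effect < τ (default −0.5, a
configuration knob — the analysis depends only weakly on it because planted
and real essential genes sit near −1) in at least one extreme group. The
per-gene statistic is a Student's pooled two-sample t oriented
(mean_S − mean_R)/SE, fixing the sign convention "low negative t ⇔ essential
in the sensitive group, high positive t ⇔ essential in the resistant group";
Welch's t is available by flag. Genes with fewer than two observations in a
group are flagged and excluded from the BH adjustment. Nomination ranks by
descending t and intersects the top-k (default 20) with a user-supplied
druggable-gene list; an empty intersection is a warning, not an error.

## Perturbation clustering

Genes are z-scored across all samples (n−1 denominator; constant rows are
dropped with a warning because they have no scale) and clustered by
complete-linkage agglomeration on Euclidean distances over the full
replicate matrix, cut to exactly K = 5 clusters. Clustering on the full
matrix rather than on replicate-averaged condition means is a deliberate
choice: after z-scoring, three-condition averages live on a one-dimensional
circle where complete linkage is fragile to single outliers, while the full
replicate matrix keeps clusters well separated (planted-structure recovery
stays above ARI 0.95 across seeds). `average_replicates` remains available
for display and for reading cluster condition profiles. Distance ties during
agglomeration resolve to the smallest row-index pair, and cluster ids are
relabelled 1..K by first appearance, so the assignment is deterministic and
row-permutation invariant up to relabelling. Per-cluster annotation is the
hypergeometric ORA with the clustered genes as universe and BH within each
cluster. PCA is a centred SVD with each component's largest-magnitude
loading forced positive for reproducibility.

## Survival and clinical contrasts

The log-rank test is the Mantel–Haenszel statistic over distinct event times
(delegated to lifelines), referred to χ²(1). The Cox proportional-hazards
model is fit in-package by Newton–Raphson on the partial likelihood for a
single binary covariate, with Efron's tie correction by default and
Breslow's by flag — the two coincide exactly without ties, which the tests
assert, and the Efron fit is cross-checked against lifelines. Steps are
clipped to ±2 for stability; |β| > 15 is reported as monotone likelihood
(complete separation) with a flag rather than an error, and true
non-convergence raises with the iteration trace. HR = exp(β) with a 95% Wald
interval. Paired tumour/normal contrasts use the one-sample t on
differences (a perfectly constant nonzero shift has no valid t and raises);
recurrence-rate contrasts use Fisher's exact test on the 2×2 table, with a
median split provided as the default expression-grouping rule since no
canonical cut-point exists.

## The synthetic generator

`generate_panel` draws a latent sensitivity s_i ~ N(0,1) per line and
couples everything to it: AUC = 0.5·s_i + noise (sd 0.3 per drug, three
drugs behaving comparably), planted-signature expression = baseline −
β_sig·s_i + unit noise (β_sig = 1), class-V-like mutations assigned to the
lowest-AUC decile with probability `mut_ppv` (0.3) and uniformly otherwise,
background class II/III/IV variants spread uniformly, and knockout effects
~N(0, 0.15) with planted genes depressed by −1 only in the resistant
(DEP_R) or sensitive (DEP_S) AUC-decile group. Defaults — 300 lines, 1000
genes, a 50-gene signature, nine 50-gene decoy sets — are the study
conditions every recovery experiment in the tests uses. The generator is a
pure function of (recipe, seed); identical seeds give bit-identical panels.

What it does *not* emulate: mean–variance coupling and zero inflation of
real TPM data, correlated co-expression modules outside the planted set,
copy-number or proteome structure, batch effects, and mutation spectra
beyond a single gene. Passing recovery tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
performance on real panels.

`generate_perturbation_experiment` plants five condition-mean profiles over
(vehicle, drug, drug+inhibitor) × 3 replicates with i.i.d. noise (sd 0.5),
including the "up on drug, reversed by the combination" pattern as cluster
2. `generate_survival_cohort` draws exponential event times (baseline
hazard 0.1) with the hazard multiplied by the planted HR for altered
subjects, and an independent exponential censoring clock calibrated so the
unaltered censoring probability equals `censor_rate`.

## Problem sizes and numerical choices

Simulation-based tests use: 50 seeds × 2000 genes (DE null), 500 random
sets at nperm = 1000 (GSEA null), 100 seeds (dependency null and panel
recovery), 500 replicates (log-rank null), 200 seeds × n = 500 (Cox
recovery), and nperm = 500–2000 for in-test GSEA — sizes chosen so the
planted effects are comfortably identified while the full suite runs in
about a minute. Numerical tolerances: formula-oracle agreements at 1e-10,
algebraic identities at 1e-12, iterative fits (trigamma inversion, Cox
Newton) converge to 1e-9–1e-10 relative steps. Degenerate inputs
(constant rows, zero-variance genes, single-member classes, empty
intersections) are flagged or raised explicitly — nothing is dropped
silently.

## Known limitations

- Only a single binary covariate in the Cox model; no multivariate
  adjustment or stratification.
- GSEA offers gene-label permutation only; collections whose set sizes all
  differ pay one null sample per size.
- The moderated-t engine assumes approximate normality of log expression
  within groups; counts are not modelled.
- No identifier mapping between naming schemes; inputs must share one
  identifier space.
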