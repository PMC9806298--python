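# immunoscore

Immune-infiltration typing and a PCA-based prognostic immune score for bulk
tumour transcriptomes, with prostate cancer as the motivating setting.

Bulk RNA profiles mix tumour cells with infiltrating immune cells, and the
balance of the two carries prognosis: tumours rich in immune infiltrate tend
to progress more slowly and to express more immune-checkpoint machinery
(CTLA-4, PD-L1). `immunoscore` implements a complete analysis chain that
turns a log2 expression matrix plus progression-free survival (PFS) records
into an interpretable per-patient risk score:

1. **ssGSEA infiltration scoring** — for each sample, each of 28 immune-cell
   signatures gets a single-sample enrichment score
   `ES = Σ_i [P_in(i) − P_out(i)]`, the running difference between the
   rank-weighted in-set ECDF (weights `rank^α`, default `α = 0.25`) and the
   out-of-set ECDF. Scores depend only on within-sample ranks, so any
   monotone normalization of the input leaves them unchanged.
2. **Consensus NMF clustering** — the cell-type × sample score matrix is
   factorized (`X ≈ WH`, multiplicative updates for `‖X − WH‖²`) over many
   random restarts; co-assignment frequencies form a consensus matrix whose
   average-linkage clustering yields the sample clusters. Candidate ranks are
   screened by the cophenetic stability coefficient, and among stable ranks
   the one whose clusters best separate PFS (smallest log-rank p, with a
   parsimony margin) is selected. For `k = 2` the cluster with higher
   grand-mean infiltration is named **A** (better prognosis), the other **B**.
3. **Weighted co-expression modules** — unsigned adjacency `|cor|^β` with a
   scale-free soft threshold, topological overlap (TOM), average-linkage
   clustering with a fixed-height cut, module eigengenes (first PC of each
   module), module–trait correlation against the cluster-B indicator, and
   per-gene module membership (MM) and gene significance (GS).
4. **Hub genes** — genes of cluster-associated modules (`|r| ≥ 0.5`,
   `p ≤ 0.05`) with `MM > 0.8` and `GS > 0.5`. For a user-supplied
   protein-interaction edge list, degree and exact maximal-clique-centrality
   (MCC) rankers are provided.
5. **Immune score** — `IS = Σ PC1(B+) − Σ PC1(B−)`: per-module first
   principal components of hub-gene expression, summed over modules
   positively / negatively correlated with cluster B. High IS therefore
   marks immune-poor, poor-prognosis tumours. Samples are dichotomized at
   the maximally selected log-rank cutpoint, and the split is evaluated with
   Kaplan–Meier/log-rank statistics, a 5-year-PFS ROC, and
   covariate-combined stratification (hormone/radiation therapy, nodal
   status, Gleason ≤7 vs >7).

Because the method is meant to be verifiable without any external download,
the package ships a first-class synthetic-cohort generator
(`immunoscore.simulate`) that plants the exact structure the analysis
assumes — two latent infiltration groups, signature-driven co-expression
modules, checkpoint genes tracking infiltration, and group-dependent PFS —
so every stage can be tested against known ground truth.

## Worked example

```python
import immunoscore as im

params = im.SimulationParams(n_samples=200, seed=7)
expr, signatures, clinical, truth = im.generate_cohort(params)
config = im.RunConfig(seed=7, k_min=2, k_max=4, n_restarts=25)
result = im.run_pipeline(expr, signatures, clinical, config)

print(f"chosen NMF rank: k={result.assignment.k}")
print(f"cluster sizes: {result.assignment.labels.value_counts().to_dict()}")
chi2, df, p = result.cluster_logrank
print(f"cluster PFS log-rank: chi2={chi2:.1f} (df={df}), p={p:.2e}")
n_modules = result.modules.labels[result.modules.labels != "grey"].nunique()
print(f"co-expression modules: {n_modules} (beta={result.modules.beta})")
print(f"hub genes: {len(result.hub_genes)}")
print(f"IS cutpoint: {result.immune_score.cutpoint:.2f}")
chi2, df, p = result.is_logrank
print(f"high vs low IS log-rank: chi2={chi2:.1f}, p={p:.2e}")
print(f"5-year PFS AUC: {result.roc_auc:.3f} (n={result.roc_n_used})")
```

Output (about half a minute on one core):

```
chosen NMF rank: k=2
cluster sizes: {'B': 115, 'A': 85}
cluster PFS log-rank: chi2=21.5 (df=1), p=3.48e-06
co-expression modules: 22 (beta=6)
hub genes: 842
IS cutpoint: -92.36
high vs low IS log-rank: chi2=26.5, p=2.60e-07
5-year PFS AUC: 0.804 (n=158)
```

Reading the numbers: rank selection confirms two stable sample clusters
whose PFS differs strongly; the generator's 28 planted signatures surface as
co-expression modules (some merge at this cohort size); their
MM/GS-screened hub genes produce an immune score whose high/low split
(cutpoint −92.36; the scale is that of summed PC1 projections) separates
progression with p ≈ 10⁻⁷ and predicts 5-year progression with AUC ≈ 0.80.
Samples censored before the 5-year horizon are excluded from the ROC
(`n=158` of 200 remain).

## Command line

Each stage is also a subcommand operating on tab-separated files:

```bash
immunoscore --seed 7 --out-dir run/ simulate --n-samples 200
immunoscore --out-dir run/ ssgsea  --expr run/expression.tsv --gmt run/signatures.gmt
immunoscore --out-dir run/ cluster --infiltration run/infiltration.tsv --clinical run/clinical.tsv
immunoscore --out-dir run/ modules --expr run/expression.tsv --clusters run/clusters.tsv
immunoscore --out-dir run/ hubs    --modules run/modules.tsv --module-trait run/module_trait.tsv
immunoscore --out-dir run/ score   --expr run/expression.tsv --hubs run/hub_genes.tsv --clinical run/clinical.tsv
immunoscore --out-dir run/ survival --clinical run/clinical.tsv --groups run/immune_score.tsv \
    --covariate hormone_therapy --stages T3,T4
```

Formats: expression TSV (genes × samples), Broad-dialect GMT signatures,
clinical TSV (`sample_id`, `pfs_time` in months, `pfs_event` 0/1, optional
Gleason / nodal status / therapy flags / T stage), and a two-column edge
list for network ranking.

## Scope

The package analyzes a provided (or simulated) expression matrix; cohort
download, probe-to-gene annotation, batch correction, GO/KEGG enrichment
and Cox modelling are out of scope. See `docs/methods.md` for the model
assumptions, parameter choices, and known limitations.
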