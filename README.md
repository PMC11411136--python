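# mpalkit

Multiomic single-cell analysis toolkit for pooled leukemia studies — built
for mixed-phenotype acute leukemia (MPAL) style datasets where each cell
carries targeted DNA genotypes plus surface-protein (antibody-oligo) counts,
or RNA plus protein, and patients are multiplexed into pooled runs with
hashing antibodies.

The package provides, as a tested library with a thin `mpal` CLI:

* **Genotype QC** — barcode validity from the knee of the read-count rank
  plot plus amplicon coverage (≥60% of intervals at ≥8 reads), per-call
  filtering (GQ < 30, DP < 10, or alternate allele fraction < 20% → missing),
  and a >0.1%-of-cells variant prevalence filter.
* **SNP + hash demultiplexing** — binary SNPs at intermediate mutant
  fractions (10–80%), 5-NN majority-vote imputation of missing calls,
  hierarchical clustering (Ward linkage on cosine dissimilarities) cut at
  the pool size, SNP refinement by exact/χ² association tests (p < 10⁻¹²),
  recursive dendrogram splitting gated by Hotelling's T² on hash CLR values
  (p < 10⁻⁵, ≥10 cells per child), and per-hash positivity thresholds from a
  reflected-background distribution (95th percentile). Clusters positive for
  one hash become patients; ≥2 hashes mark multiplets.
* **Clones and phylogeny** — clones as >10 cells with identical ternary
  genotypes; pairwise mutation co-occurrence (log₂ odds ratio with
  Haldane–Anscombe correction + Fisher's exact test); mutation-tree inference
  under the standard single-cell error model (false-positive rate α = 1%,
  platform false-negative rate β) by exhaustive enumeration of all
  (m+1)^(m−1) rooted labeled trees; founding-vs-subsequent-clone t-statistics
  per surface antibody with Bonferroni adjustment and per-antibody max-t.
* **Stemness scoring** — expression QC (genes in <3 cells, cells with <200
  features or >15% mitochondrial counts), a per-cell differentiation-potential
  score in [0, 1], signature derivation from the ≥0.95 / <0.95 score split
  (Wilcoxon rank-sum, Bonferroni, top genes by log₂ fold change), pseudo-bulk
  aggregation, and a first-principal-component gene-set score per sample:
  z-score each signature gene across samples, project onto PC1, and orient
  the sign toward mean signature expression.
* **Survival** — Kaplan–Meier with Greenwood errors, k-group log-rank tests,
  and multivariable Cox proportional hazards with Wald CIs (via lifelines),
  plus deterministic median/tertile/quantile score stratification.
* **Synthetic data** — fully ground-truthed generators for multiplexed pools
  (patient-discriminating SNPs, bimodal hash counts, doublets), clonal
  patients on a mutation tree with (α, β) genotype noise and clone-coupled
  protein shifts, and expression cohorts with a latent stemness gradient
  driving gene breadth, signature expression, and exponential
  proportional-hazards survival.

## Worked example

Demultiplex a simulated default pool (3 patients × 1000 cells, 30 SNPs,
5% missing calls, 3% doublets):

```python
from mpalkit import synthetic, demux

cfg = synthetic.PoolSimConfig(seed=1)
geno, hashes, truth = synthetic.simulate_pool(cfg)
result = demux.demux(geno, hashes)
print(result.labels.value_counts().to_dict())
```

```
{'HASH0': 1000, 'HASH1': 1000, 'HASH2': 1000, 'multiplet': 90}
```

All 3000 singlets are assigned to their true patient and all 90 simulated
doublets are flagged as multiplets (and would be dropped from downstream
analysis via `result.singlets`).

Infer a patient's mutation tree and its immunophenotype evolution:

```python
from mpalkit import synthetic, clones

cfg = synthetic.CloneSimConfig(
    tree_edges=(("root", "A"), ("A", "B"), ("B", "C"), ("C", "D")),
    clone_fractions=(("root", .2), ("A", .2), ("B", .2), ("C", .2), ("D", .2)),
    protein_shift_map=(("D", (("CD34", 2.0),)),),
    n_cells=300, seed=3,
)
geno, protein, truth = synthetic.simulate_clonal_patient(cfg)
tree = clones.infer_tree_ml(geno, alpha=0.01, beta=0.1, seed=1)
print(tree.newick(), round(tree.log_likelihood, 1))
clone_list, _ = clones.call_clones(geno)
table, max_t = clones.evolution_tstats(clone_list, protein)
print(max_t.idxmax(), round(max_t.max(), 2))
```

```
((((D)C)B)A)root; -607.8
CD34 10.95
```

The exhaustive maximum-likelihood search recovers the planted linear chain
root→A→B→C→D, and CD34 — shifted by +2 SD in the terminal clone — is the
antibody with the largest founding-vs-subsequent-clone t-statistic.

Score a cohort and stratify survival:

```python
from scipy import stats
from mpalkit import synthetic, scoring, survival

counts, sample_of, surv, truth = synthetic.simulate_expression_cohort(
    synthetic.ExpressionSimConfig(seed=2)
)
qc = scoring.qc_filter(counts)
cell_scores = scoring.differentiation_score(qc, seed=0)
sig = scoring.derive_signature(cell_scores, qc.loc[cell_scores.scores.index])
bulk = scoring.pseudo_bulk(qc, sample_of)
sample_scores = scoring.gene_set_score(bulk, sig)
print(round(stats.spearmanr(
    sample_scores, truth.samples["mean_stemness"]).statistic, 3))
strata = survival.stratify_scores(sample_scores)
chi2, p = survival.logrank_test(surv.assign(group=strata))
print(round(p, 4))
```

```
0.997
0.0011
```

The first-PC sample score reconstructs the latent per-sample stemness
(Spearman ρ = 0.997), and the median split separates overall survival
(log-rank p ≈ 0.001) because the cohort was simulated with a log hazard
ratio of 1 per SD of sample stemness.

The same stages are available from the shell: `mpal simulate|demux|clones|
cooccur|tree|evolve|score|survival|run` (see `mpal --help`).

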