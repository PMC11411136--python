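# Methods

This note documents the models and procedures implemented in mpalkit, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Genotype quality control

Calls arrive as per-(cell, variant) records with GATK-style fields. Calls
with genotype quality GQ < 30 or depth DP < 10, and non-reference calls with
alternate allele fraction AF < 20%, are set to *missing*, not to reference:
a failed call carries no evidence for the wild-type allele, and coercing it
to 0 would fabricate wild-type cells. The AF rule is applied to every
non-reference call (heterozygous and homozygous alike). Barcode validity
combines the knee of the log–log read-count rank plot — realized
deterministically as the point of maximum perpendicular distance to the
chord, which is invariant to multiplying all counts by a constant — with the
requirement that ≥60% of a barcode's amplicon intervals are covered by ≥8
reads. Variant prevalence is computed over cells with a non-missing call at
that variant (missing calls carry no evidence either way), and variants
observed mutated in >0.1% of such cells are retained.

## SNP + hash demultiplexing

The demultiplexer treats SNPs as binary (any non-reference call = mutated).
Its stages and constants:

| stage | parameter | default |
| --- | --- | --- |
| SNP preselection | mutant-fraction band | [0.10, 0.80] |
| imputation | nearest neighbors k | 5 |
| initial cut | clusters (pool size) | 3 |
| SNP refinement | association p cutoff | 10⁻¹² |
| cluster splitting | Hotelling p cutoff | 10⁻⁵ |
| cluster splitting | minimum cells per child | 10 |
| hash background | quantile | 0.95 |
| assignment | fraction of positive cells | > 0.50 (strict) |

Imputation distance is the mismatch fraction over co-observed SNPs (Gower's
coefficient restricted to binary data); for each missing entry the majority
vote is taken over the 5 nearest cells *that observed that SNP*, with ties
broken toward wild type (conservative toward no mutation). Clustering is
agglomerative with Ward's Lance–Williams update applied directly to cosine
dissimilarities ("ward.D" semantics). Implementation detail: scipy's Ward
routine applies the update to squared inputs, so the square roots of the
cosine dissimilarities are passed in; merge order — hence every flat cut —
is identical, with heights on a square-root scale.

SNP refinement tests each SNP's 2×k contingency table against cluster
labels: a Freeman–Halton exact enumeration when the table total is ≤200,
otherwise the χ² approximation (at p < 10⁻¹² only near-perfect separations
pass, where the approximation's ranking is stable). One refinement pass is
run; iterating did not change the selected set on the synthetic pools.

Cluster refinement traverses the dendrogram from each initial cluster and
tests the two *children* of a node against each other with the two-sample
Hotelling T² on hash-antibody CLR values,

T² = (n₁n₂/(n₁+n₂)) · d′S⁻¹d,  F = T²·(n₁+n₂−p−1)/(p(n₁+n₂−2)),

with the pooled covariance S ridge-regularized by 10⁻⁶·tr(S)/p when
singular. A split is accepted iff p < 10⁻⁵ and both children have ≥10 cells;
recursion continues inside accepted children. Child-vs-child (rather than
parent-vs-child) is used because the parent mixes the two children — testing
the disjoint halves is the sharper and statistically cleaner reading; the
parent-vs-child variant shares each child's cells with the parent sample and
would correlate the two groups.

Per-hash positivity thresholds assume a bimodal CLR distribution: stained
(right mode) vs background (left mode). The density is a Gaussian KDE with
Silverman bandwidth evaluated on a 512-point grid over the data range; modes
are strict interior local maxima, and a candidate mode must carry at least
5% of the peak density — without that guard, sampling wiggles in the far
tail of a perfectly unimodal sample register as spurious "left modes" and
collapse the background sample. The background distribution is the data at
or below the left mode m together with its reflection 2m − x, and the
threshold is that sample's empirical 95th percentile. Constant input returns
the constant. A cluster is assigned to every hash for which strictly more
than 50% of its cells exceed the threshold: one hash → that patient, two or
more → multiplet, none → unassigned; multiplets and unassigned cells are
excluded from the downstream singlet set.

## Clones, co-occurrence, and mutation trees

Clones are groups of **more than** 10 cells with identical *ternary*
genotype vectors over the patient's pathogenic variants — heterozygous and
homozygous states found distinct clones. Cells with any missing call among
the selected variants are excluded from clone calling rather than imputed;
imputation is appropriate for patient assignment (where the signal is
redundant across many SNPs) but would manufacture clone membership from a
single fabricated call. Co-occurrence and tree inference binarize genotypes
(pairing mutations, not zygosity states).

Pairwise co-occurrence builds a 2×2 table over clones per mutation pair; the
odds ratio uses the Haldane–Anscombe +0.5 correction whenever any cell is
zero, is reported as log₂ OR, and significance is the two-sided Fisher exact
p (sum of hypergeometric probabilities ≤ the observed table's).

Tree likelihood follows the standard single-cell phylogeny error model: one
node per mutation plus a wild-type root, each cell attached to a node with
uniform prior, expected genotype = mutations on the node's root path,
observations passed through the error channel P(1|0) = α (default 0.01),
P(0|1) = β (platform-dependent; 0.1 in the synthetic benchmarks), missing
entries contributing likelihood 1, and the per-cell attachment marginalized.
Zero error rates are floored at log-probability −745 (the double-precision
underflow point) so impossible observations carry effectively zero
likelihood without −inf·0 artifacts. At the small mutation counts this
package targets (m ≤ 7), *all* (m+1)^(m−1) rooted labeled trees are
enumerated via Prüfer sequences and scored — the maximum-likelihood tree is
exact, not a search heuristic; larger panels are refused with a pointer to
MCMC tools. Per-cell maximum-likelihood attachments define inferred clones;
clone-frequency 95% intervals are nonparametric bootstrap percentile
intervals over cells (not MCMC posterior credible intervals; labeled as
such in the output).

Immunophenotype evolution compares the founding clone — the non-wild-type
clone whose mutation set is ancestral to (a subset of) every other mutated
clone's, the largest such clone if several tie — against each subsequent
clone separately, per antibody, with a two-sample Student t on CLR protein
values. Pairwise per-clone comparisons (rather than pooling all subsequent
clones) preserve the per-clone trajectory; p-values are Bonferroni-adjusted
across all clone × antibody tests within a patient, and each antibody's
maximum t across clones summarizes which surface proteins move most with
mutation acquisition. Zero pooled variance yields t = ±∞ with p = 0,
flagged rather than silently dropped.

## Differentiation scoring and the gene-set score

Expression QC removes genes detected in <3 cells and cells with <200
detected features or >15% mitochondrial counts (strict inequality; computed
from gene names with the `MT-` prefix). The gene filter runs before the
cell filter, and the pair is iterated to a fixed point so the operation is
idempotent — a single pass is not, because removing cells can push a gene
back under the 3-cell detection floor.

The built-in per-cell differentiation score is a deliberately simple
stand-in for dedicated differentiation-potential tools, exploiting the same
dominant signal (expressed-gene breadth): average the log-normalized
expression of the 200 genes most correlated with per-cell gene counts,
smooth over 10 nearest neighbors in log-expression space, rank-normalize to
[0, 1] (1 = most stem-like), subsampling to 3000 cells on larger cohorts.
Externally computed scores can be supplied instead and pass through
unchanged; the provenance is recorded on the result. The stand-in recovers
a planted stemness gradient at Spearman ≥ 0.7 but is *not* the published
algorithm and should not be treated as interchangeable with it on real data.

Signature derivation splits leukemia cells at score ≥ 0.95 vs < 0.95
(each group must have ≥20 cells), tests each gene by Wilcoxon rank-sum on
log-normalized expression, keeps genes with Bonferroni-adjusted p < 0.05 and
positive log₂ fold change (fold change of mean linear-scale normalized
expression with a +1 damping pseudocount), ranks by fold change, and
returns the top 50 by default — the signature size and DE test are exposed
as parameters since reasonable pipelines differ here.

Pseudo-bulk is the per-sample **sum** of raw counts (sums preserve the count
scale and total-count conservation; means would be the other defensible
choice). The sample-level gene-set score restricts to signature genes
(absent genes dropped with a warning), log1p-CPM transforms count input,
z-scores each gene across samples, projects onto the first principal
component, and orients the sign to correlate positively with the per-sample
mean z-score; scores therefore have mean zero and an interpretable sign
(higher = more signature-like). Stratification rules (median by default,
tertile and arbitrary quantile available) send ties at a cutoff to the
lower group; the high-vs-low cut point is a configurable choice, not a
statistical estimate.

## Survival

Kaplan–Meier curves carry Greenwood standard errors; with no censoring the
estimator reduces exactly to the empirical survivor function. The log-rank
test is the k-group chi-square form; the Cox model is fit by lifelines'
partial-likelihood Newton iteration, which handles ties by the Breslow
approximation — the simplest correct choice, and the one assumed by the
score-test/log-rank equivalence checked in the tests. Wald 95% intervals
and two-sided Wald p-values are reported per covariate; categorical
covariates are dummy-encoded against their first level (the reference level
is configurable by reordering). Proportional-hazards diagnostics
(Schoenfeld residuals) are out of scope.

## Synthetic data: what it emulates and what it does not

`simulate_pool` plants k patients (default 3 × 1000 cells) with disjoint
blocks of discriminative SNPs (60% of 30 SNPs; the rest common to all
patients and hence filtered by the 10–80% band), 5% missing calls, and 3%
doublets whose genotype is the element-wise max of two patients' calls — a
mixed droplet shows a mutant allele if either cell carries it — and whose
hash counts are signal-level on both patients' hashes. Hash counts are
log-normal (log-scale signal μ = 6, background μ = 2, σ = 0.5), producing
the bimodal per-hash CLR distribution the assignment step assumes.

`simulate_clonal_patient` draws cells from the configured clone fractions on
a mutation tree, corrupts genotypes at rates α (0→1) and β (1→0), and adds
per-clone shifts to unit-variance Gaussian protein values.

`simulate_expression_cohort` (default 40 samples × 100 cells × 800 genes)
gives each sample a stemness center uniform on [0.05, 0.95] and each cell a
latent stemness clipped-normal around it (SD 0.1). Counts are negative
binomial (dispersion θ = 10) with per-gene log-normal base means; the 60
signature genes' means scale as exp(effect · (s − ½)) and every gene's mean
by a capture factor exp(0.6 · effect · (s − ½)), so expressed-gene breadth
tracks stemness. Survival times are exponential with hazard
0.1 · exp(β_surv · z), where z is the *standardized* sample mean stemness —
the log hazard ratio is per SD of sample stemness. The raw [0, 1] scale
would make the default effect size practically undetectable at cohort sizes
of tens of samples, so the standardized parameterization is the one under
which the generator's default β_surv = 1 represents a realistic, detectable
prognostic effect. Censoring is an independent exponential calibrated to
the configured censor fraction (default 20%).

Setting `stemness_effect = 0` and `survival_log_hr = 0` yields an
exchangeable null cohort used for calibration checks.

What the generators do **not** model: read-level noise, ambient RNA or
ambient hash contamination, batch effects, doublets of more than two
patients, copy-number events, cell-cycle structure, and non-proportional
hazards. Passing the benchmarks therefore demonstrates the correctness of
the implemented statistics and the recoverability of planted structure
under the stated noise model — not robustness to every artifact of real
single-cell data.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run at the reference scales:
demultiplexing on the default 3×1000-cell pool; Hotelling calibration at
2000 null replicates (p = 3, n = 100 + 100); background thresholding at 100
replicates of n = 5000; tree recovery over 20 seeds of 300 cells on a
4-mutation chain (125 enumerated trees each); signature recovery on 600
cells × 200 genes with a 50-replicate permutation null; the end-to-end
scoring chain over 20 seeds of the default cohort; Cox recovery over 50
replicates of n = 300; and 500 log-rank null replicates. These sizes were
chosen so each planted effect sits well inside the detectable regime while
the whole battery completes in minutes on a single CPU.
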