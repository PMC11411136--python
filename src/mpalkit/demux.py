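"""SNP + hash-antibody demultiplexing of pooled single-cell runs.

Pools of patients are demultiplexed in two phases. Genotypes drive an initial
partition: SNPs with intermediate mutant fractions are selected, missing calls
are imputed by a k-nearest-neighbor majority vote, cells are clustered
hierarchically (Ward linkage on cosine dissimilarities) and cut at the pool
size, and the SNP set is refined by testing each SNP's association with
cluster membership. Hashing-antibody CLR values then refine the partition:
clusters are recursively split down the dendrogram wherever the two children
differ by Hotelling's T² test, a per-hash background distribution is
estimated by reflecting values below the left density mode about that mode,
and each cluster is assigned to the hash (patient) whose threshold a majority
of its cells exceed — to two or more hashes for multiplets, to none for
unassignable cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.special import gammaln

__all__ = [
    "DemuxConfig",
    "ClusterTree",
    "DemuxResult",
    "clr_normalize",
    "select_informative_snps",
    "impute_knn",
    "cluster_cells",
    "snp_cluster_association",
    "refine_snps",
    "hotelling_t2",
    "split_clusters",
    "estimate_hash_background",
    "assign_clusters",
    "demux",
]

MULTIPLET = "multiplet"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DemuxConfig:
    snp_low: float = 0.10
    snp_high: float = 0.80
    knn_k: int = 5
    k_pool: int = 3
    fisher_alpha: float = 1e-12
    hotelling_alpha: float = 1e-5
    min_cluster: int = 10
    bg_quantile: float = 0.95
    assign_frac: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 < self.snp_low < self.snp_high < 1.0:
            raise ValueError("need 0 < snp_low < snp_high < 1")
        if self.k_pool < 2 or self.min_cluster < 2:
            raise ValueError("k_pool >= 2 and min_cluster >= 2 required")


@dataclass
class ClusterTree:
    """Agglomerative dendrogram with a flat partition.

    ``linkage_matrix`` is a scipy linkage array whose merge heights are
    non-decreasing (Ward monotonicity); ``labels`` is the current flat
    partition over ``cells``.
    """

    linkage_matrix: np.ndarray
    cells: pd.Index
    labels: np.ndarray

    def partition(self) -> dict[int, pd.Index]:
        return {
            int(c): self.cells[self.labels == c] for c in np.unique(self.labels)
        }


@dataclass
class DemuxResult:
    labels: pd.Series  # per cell: hash/patient id, "multiplet", or "unassigned"
    clusters: pd.Series  # per cell: final cluster id
    selected_snps: list[str]
    thresholds: dict[str, float]
    cluster_hashes: pd.DataFrame  # clusters x hashes boolean positivity
    tree: ClusterTree | None = None
    log: dict = field(default_factory=dict)

    @property
    def singlets(self) -> pd.Index:
        """Cells assigned to exactly one patient (multiplets/unassigned excluded)."""
        return self.labels.index[~self.labels.isin([MULTIPLET, UNASSIGNED])]


# ---------------------------------------------------------------------------


def clr_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio normalization of a cells x antibody count matrix.

    Per cell: ``log(x + 1)`` minus the mean of ``log(x + 1)`` across
    antibodies, so every row has mean zero.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("antibody counts must be nonnegative")
    logged = np.log1p(counts.astype(float))
    return logged.sub(logged.mean(axis=1), axis=0)


def select_informative_snps(
    G: pd.DataFrame, snp_low: float = 0.10, snp_high: float = 0.80
) -> list[str]:
    """SNPs with mutant fraction in [snp_low, snp_high] among non-missing calls."""
    observed = G.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = (G > 0).sum(axis=0) / observed.replace(0, np.nan)
    keep = [c for c in G.columns if snp_low <= frac[c] <= snp_high]
    if not keep:
        raise ValueError(
            "no SNP has an intermediate mutant fraction; pool cannot be demultiplexed"
        )
    return keep


def _mismatch_distance(X: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Pairwise mismatch fraction over co-observed binary SNPs."""
    a1 = np.where(obs, X, 0.0)
    a0 = np.where(obs, 1.0 - X, 0.0)
    co = obs.astype(float) @ obs.T.astype(float)
    mism = a1 @ a0.T + a0 @ a1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = mism / co
    d[co == 0] = np.inf
    return d


def impute_knn(G: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing binary calls by a k-nearest-neighbor majority vote.

    Distance between cells is the mismatch fraction over co-observed SNPs.
    For each missing entry the vote is taken over the ``k`` nearest cells
    that have an observed value at that SNP; ties break toward 0 (wild type).
    """
    X = G.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (~obs.any(axis=1)).any():
        bad = G.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"cells with no observed SNP cannot be imputed: {bad[:5]}")
    if obs.all():
        return G.copy()
    Xz = np.where(obs, X, 0.0)
    D = _mismatch_distance(Xz, obs)
    np.fill_diagonal(D, np.inf)
    out = X.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        order = np.argsort(D[i], kind="stable")
        order = order[np.isfinite(D[i][order])]
        for j in np.flatnonzero(~obs[i]):
            donors = order[obs[order, j]][:k]
            if donors.size == 0:
                raise ValueError(
                    f"SNP {G.columns[j]!r} has no observed donor for cell {G.index[i]!r}"
                )
            votes = X[donors, j]
            out[i, j] = 1.0 if votes.sum() > votes.size / 2 else 0.0
    return pd.DataFrame(out, index=G.index, columns=G.columns)


def cluster_cells(G: pd.DataFrame, k: int) -> ClusterTree:
    """Hierarchical clustering: Ward linkage on cosine dissimilarities.

    The Lance-Williams Ward update is applied directly to the cosine
    dissimilarities (classic ``ward.D`` semantics). scipy's Ward routine
    applies the update to squared inputs, so the square roots of the cosine
    dissimilarities are passed in; the resulting merge order and flat cuts are
    identical, with heights on a square-root scale.
    """
    X = G.to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} cells")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm rows: cosine distance undefined")
    D = pdist(X, metric="cosine")
    D = np.clip(D, 0.0, None)  # numerical negatives from pdist
    Z = linkage(np.sqrt(D), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterTree(linkage_matrix=Z, cells=G.index, labels=labels)


# ---------------------------------------------------------------------------
# SNP refinement


def _exact_2xk_pvalue(table: np.ndarray) -> float:
    """Freeman-Halton exact test for a 2 x k contingency table.

    Enumerates all tables with the observed margins; the p-value is the total
    probability of tables no more probable than the observed one. Feasible
    for the small-n regime it is reserved for.
    """
    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    log_denom = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)

    def log_prob(xs: tuple[int, ...]) -> float:
        lp = -log_denom
        for x, c in zip(xs, cols):
            lp += gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
        return lp

    obs_lp = log_prob(tuple(int(v) for v in table[0]))
    total = 0.0
    k = len(cols)

    def rec(j: int, remaining: int, xs: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = log_prob(tuple(xs + [remaining]))
                if lp <= obs_lp + 1e-10:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(cols[j + 1 :].sum()))
        hi = min(cols[j], remaining)
        for x in range(lo, hi + 1):
            rec(j + 1, remaining - x, xs + [x])

    rec(0, r1, [])
    return min(1.0, total)


def snp_cluster_association(
    snp: np.ndarray, labels: np.ndarray, exact_max_n: int = 200
) -> float:
    """P-value for association between a binary SNP and k cluster labels.

    Exact (Freeman-Halton) when the total count is at most ``exact_max_n``,
    otherwise the chi-square approximation — at the extreme significance
    levels used for SNP refinement only near-perfect separations pass, where
    the approximation's ranking is stable.
    """
    cats = np.unique(labels)
    table = np.array(
        [
            [(snp[labels == c] == 1).sum() for c in cats],
            [(snp[labels == c] == 0).sum() for c in cats],
        ],
        dtype=float,
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return 1.0
    if table.sum() <= exact_max_n:
        return _exact_2xk_pvalue(table)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def refine_snps(
    G: pd.DataFrame, labels: np.ndarray, alpha: float = 1e-12
) -> tuple[list[str], pd.Series]:
    """Select SNPs associated with cluster membership at p < ``alpha``.

    Returns the selected SNP names and the per-SNP p-values. Falls back to
    the full SNP set (with a warning) when none passes.
    """
    pvals = pd.Series(
        {c: snp_cluster_association(G[c].to_numpy(), labels) for c in G.columns}
    )
    selected = [c for c in G.columns if pvals[c] < alpha]
    if not selected:
        warnings.warn(
            "no SNP passed the cluster-association refinement; keeping all SNPs",
            stacklevel=2,
        )
        selected = list(G.columns)
    return selected, pvals


# ---------------------------------------------------------------------------
# Hotelling T² and dendrogram splitting


def hotelling_t2(X: np.ndarray, Y: np.ndarray) -> tuple[float, float, float]:
    """Two-sample Hotelling T² test.

    Returns ``(T2, F, p)``. T² = (n1 n2 / (n1+n2)) d' S⁻¹ d with pooled
    covariance S; the F transform has (p, n1+n2-p-1) degrees of freedom. A
    singular pooled covariance is ridge-regularized by 1e-6 · trace(S)/p.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share dimensionality")
    n1, n2, p = X.shape[0], Y.shape[0], X.shape[1]
    if n1 + n2 <= p + 1:
        raise ValueError("need n1 + n2 > p + 1 for the F transform")
    d = X.mean(axis=0) - Y.mean(axis=0)
    S = ((n1 - 1) * np.cov(X, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(Y, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * np.trace(S) / p
        if ridge <= 0:
            raise ValueError("degenerate pooled covariance") from None
        sol = np.linalg.solve(S + ridge * np.eye(p), d)
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    f_stat = t2 * (n1 + n2 - p - 1) / (p * (n1 + n2 - 2))
    pval = float(stats.f.sf(f_stat, p, n1 + n2 - p - 1))
    return t2, float(f_stat), pval


def _cut_nodes(root, k: int) -> list:
    """Nodes of the dendrogram corresponding to a maxclust cut at k."""
    nodes = [root]
    while len(nodes) < k:
        splittable = [nd for nd in nodes if not nd.is_leaf()]
        if not splittable:
            break
        top = max(splittable, key=lambda nd: nd.dist)
        nodes.remove(top)
        nodes.extend([top.get_left(), top.get_right()])
    return nodes


def split_clusters(
    tree: ClusterTree,
    hash_clr: pd.DataFrame,
    cfg: DemuxConfig,
) -> ClusterTree:
    """Refine a flat partition by recursive dendrogram splitting.

    For each cluster of the initial cut the dendrogram split into its two
    children is tested with Hotelling's T² on the children's hash-antibody
    CLR values; the split is accepted iff p < ``hotelling_alpha`` and both
    children have at least ``min_cluster`` cells, and recursion continues
    into accepted children.
    """
    root = to_tree(tree.linkage_matrix)
    clr = hash_clr.loc[tree.cells].to_numpy(dtype=float)
    p_dim = clr.shape[1]
    final: list[np.ndarray] = []

    def leaves(node) -> np.ndarray:
        return np.array(node.pre_order(lambda x: x.id))

    def rec(node) -> None:
        if node.is_leaf():
            final.append(leaves(node))
            return
        left, right = node.get_left(), node.get_right()
        li, ri = leaves(left), leaves(right)
        if min(len(li), len(ri)) < cfg.min_cluster or len(li) + len(ri) <= p_dim + 1:
            final.append(leaves(node))
            return
        _, _, pval = hotelling_t2(clr[li], clr[ri])
        if pval < cfg.hotelling_alpha:
            rec(left)
            rec(right)
        else:
            final.append(leaves(node))

    for node in _cut_nodes(root, cfg.k_pool):
        rec(node)

    labels = np.empty(len(tree.cells), dtype=int)
    for cid, idx in enumerate(final, start=1):
        labels[idx] = cid
    return ClusterTree(
        linkage_matrix=tree.linkage_matrix, cells=tree.cells, labels=labels
    )


# ---------------------------------------------------------------------------
# hash background and assignment


def estimate_hash_background(
    values: np.ndarray,
    bg_quantile: float = 0.95,
    grid_size: int = 512,
    min_rel_density: float = 0.05,
) -> tuple[float, float]:
    """Estimate a hash antibody's background mode and positivity threshold.

    The per-hash CLR distribution in a multiplexed pool is bimodal: a left
    (background, unstained) mode and a right (stained) mode. A Gaussian KDE
    with Silverman bandwidth is evaluated on a ``grid_size``-point grid; the
    left mode m is the smallest-valued strict local maximum carrying at least
    ``min_rel_density`` of the peak density (sampling wiggles in the KDE
    tails are not population modes). A symmetric
    background sample is built by reflecting the data at or below m about m,
    and the threshold is that sample's ``bg_quantile`` empirical quantile.
    Returns ``(left_mode, threshold)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise ValueError("need at least 50 values to estimate a background")
    if np.ptp(values) == 0:
        v = float(values[0])
        return v, v
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    ) + 1
    interior = interior[dens[interior] >= min_rel_density * dens.max()]
    mode = float(grid[interior[0]] if interior.size else grid[np.argmax(dens)])
    below = values[values <= mode]
    background = np.concatenate([below, 2 * mode - below])
    return mode, float(np.quantile(background, bg_quantile))


def assign_clusters(
    tree: ClusterTree,
    hash_clr: pd.DataFrame,
    thresholds: dict[str, float],
    assign_frac: float = 0.50,
) -> DemuxResult:
    """Assign each cluster to hashes whose threshold >50% of its cells exceed.

    One positive hash labels the cluster (and its cells) with that patient;
    two or more mark a multiplet; none leaves it unassigned.
    """
    hashes = list(hash_clr.columns)
    missing = [h for h in hashes if h not in thresholds]
    if missing:
        raise ValueError(f"no threshold for hashes: {missing}")
    part = tree.partition()
    pos = pd.DataFrame(False, index=sorted(part), columns=hashes)
    labels = pd.Series(index=tree.cells, dtype=object)
    clusters = pd.Series(index=tree.cells, dtype=int)
    for cid, cells in part.items():
        sub = hash_clr.loc[cells]
        for h in hashes:
            pos.loc[cid, h] = (sub[h] > thresholds[h]).mean() > assign_frac
        n_pos = int(pos.loc[cid].sum())
        if n_pos == 1:
            label = pos.columns[pos.loc[cid].to_numpy()][0]
        elif n_pos >= 2:
            label = MULTIPLET
        else:
            label = UNASSIGNED
        labels.loc[cells] = label
        clusters.loc[cells] = cid
    return DemuxResult(
        labels=labels,
        clusters=clusters,
        selected_snps=[],
        thresholds=dict(thresholds),
        cluster_hashes=pos,
        tree=tree,
    )


def demux(
    G: pd.DataFrame, hash_counts: pd.DataFrame, cfg: DemuxConfig | None = None
) -> DemuxResult:
    """Full SNP + hash demultiplexing of a pooled run.

    ``G`` is a cells x SNP ternary/binary genotype matrix with NaN missing;
    ``hash_counts`` is the cells x hash raw count matrix over the same
    barcodes. Returns a :class:`DemuxResult`; multiplets and unassignable
    cells are excluded from the ``singlets`` view used downstream.
    """
    cfg = cfg or DemuxConfig()
    common = G.index.intersection(hash_counts.index)
    if len(common) != len(G.index) or len(common) != len(hash_counts.index):
        raise ValueError("genotype and hash matrices must share a barcode universe")

    binary = (G > 0).astype(float).where(G.notna())
    snps = select_informative_snps(binary, cfg.snp_low, cfg.snp_high)
    imputed = impute_knn(binary[snps], k=cfg.knn_k)
    tree = cluster_cells(imputed, cfg.k_pool)
    refined, pvals = refine_snps(imputed, tree.labels, cfg.fisher_alpha)
    if set(refined) != set(imputed.columns):
        tree = cluster_cells(imputed[refined], cfg.k_pool)

    clr = clr_normalize(hash_counts.loc[G.index])
    tree = split_clusters(tree, clr, cfg)
    thresholds = {
        h: estimate_hash_background(clr[h].to_numpy(), cfg.bg_quantile)[1]
        for h in clr.columns
    }
    result = assign_clusters(tree, clr, thresholds, cfg.assign_frac)
    result.selected_snps = refined
    result.log = {"snp_pvalues": pvals.to_dict(), "config": cfg}
    return result
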