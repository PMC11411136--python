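"""Differentiation-potential scoring and gene-set signature derivation.

The scoring chain mirrors a standard stemness-signature workflow: QC-filter a
cells x genes count matrix, assign each cell a differentiation-potential
score in [0, 1] (1 = least differentiated), derive a signature gene set by
differential expression between cells scoring at or above 0.95 and the rest,
aggregate raw counts to pseudo-bulk, and score samples by projecting
z-scored signature expression onto its first principal component.

The built-in per-cell scorer is a deliberately simple gene-count-based
stand-in (expressed-gene breadth is the dominant signal in dedicated
differentiation-potential tools): a 200-gene "gene-count signature" is
averaged, smoothed over transcriptional nearest neighbors, and
rank-normalized. Scores computed by any external tool can be supplied
instead and are passed through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CellScores",
    "SignatureGeneSet",
    "qc_filter",
    "lognormalize",
    "differentiation_score",
    "derive_signature",
    "pseudo_bulk",
    "gene_set_score",
    "subset_top_fraction",
    "spearman_correlate",
]


@dataclass
class CellScores:
    scores: pd.Series  # per cell, in [0, 1]
    provenance: str  # "internal" or "external"


@dataclass
class SignatureGeneSet:
    """Ordered signature gene list with per-gene DE evidence."""

    table: pd.DataFrame  # index: gene; columns: log2_fc, p, p_bonferroni

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def qc_filter(
    counts: pd.DataFrame,
    min_cells: int = 3,
    min_features: int = 200,
    max_mito: float = 0.15,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Quality-filter a cells x genes count matrix.

    Genes detected in fewer than ``min_cells`` cells are removed, then cells
    with fewer than ``min_features`` detected genes or a mitochondrial count
    fraction strictly above ``max_mito`` are removed. The two filters are
    iterated to a fixed point (gene filter first in each round) so the
    operation is idempotent.
    """
    out = counts
    while True:
        detected_in = (out > 0).sum(axis=0)
        out2 = out.loc[:, detected_in >= min_cells]
        features = (out2 > 0).sum(axis=1)
        mito_cols = [g for g in out2.columns if str(g).startswith(mito_prefix)]
        totals = out2.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mito_frac = (
                out2[mito_cols].sum(axis=1) / totals.replace(0, np.nan)
            ).fillna(0.0)
        keep = (features >= min_features) & (mito_frac <= max_mito)
        out2 = out2.loc[keep]
        if out2.shape == out.shape:
            break
        out = out2
    if out2.size == 0:
        raise ValueError("QC filtering removed all cells or genes")
    return out2


def lognormalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Library-size normalization: scale each cell to ``target_sum``, then log1p."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0].tolist()
        raise ValueError(f"zero-count cells (run QC first): {bad[:5]}")
    return np.log1p(counts.div(totals, axis=0) * target_sum)


def differentiation_score(
    counts: pd.DataFrame,
    mode: str = "internal",
    external_scores: pd.Series | None = None,
    n_subsample: int = 3000,
    n_signature_genes: int = 200,
    n_neighbors: int = 10,
    seed: int = 0,
) -> CellScores:
    """Per-cell differentiation-potential score in [0, 1].

    ``external`` mode validates and passes through supplied scores. The
    internal stand-in: (1) count expressed genes per cell; (2) average the
    log-normalized expression of the ``n_signature_genes`` genes most
    Pearson-correlated with those gene counts; (3) smooth the average over
    ``n_neighbors`` nearest neighbors in log-expression space; (4)
    rank-normalize to [0, 1] (1 = most stem-like). Cohorts larger than
    ``n_subsample`` cells are scored on a random subsample.
    """
    if mode == "external":
        if external_scores is None:
            raise ValueError("external mode requires external_scores")
        s = external_scores.astype(float)
        if (s < 0).any() or (s > 1).any():
            raise ValueError("external scores must lie in [0, 1]")
        return CellScores(scores=s, provenance="external")
    if mode != "internal":
        raise ValueError(f"unknown mode {mode!r}")

    if len(counts) > n_subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(counts), size=n_subsample, replace=False)
        counts = counts.iloc[np.sort(idx)]

    logn = lognormalize(counts)
    gene_counts = (counts > 0).sum(axis=1).astype(float)
    X = logn.to_numpy()
    gc = gene_counts.to_numpy()
    gc_c = gc - gc.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (gc_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc * gc_c[:, None]).sum(axis=0) / denom
    corr = np.nan_to_num(corr)
    top = np.argsort(-corr, kind="stable")[: min(n_signature_genes, X.shape[1])]
    raw = X[:, top].mean(axis=1)

    k = min(n_neighbors, len(counts))
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, nbrs = nn.kneighbors(X)
    smoothed = raw[nbrs].mean(axis=1)

    ranks = stats.rankdata(smoothed, method="average")
    if len(ranks) > 1:
        scores = (ranks - 1) / (len(ranks) - 1)
    else:
        scores = np.ones(1)
    return CellScores(
        scores=pd.Series(scores, index=counts.index), provenance="internal"
    )


def derive_signature(
    scores: CellScores,
    counts: pd.DataFrame,
    threshold: float = 0.95,
    n_genes: int = 50,
    min_group: int = 20,
    alpha: float = 0.05,
) -> SignatureGeneSet:
    """Derive a stemness signature from the high/low score split.

    Cells scoring at or above ``threshold`` are compared with the rest by a
    per-gene Wilcoxon rank-sum test on log-normalized expression. Genes with
    Bonferroni-adjusted p < ``alpha`` and positive log2 fold change are
    ranked by fold change and the top ``n_genes`` returned.
    """
    s = scores.scores.loc[counts.index]
    high = counts.loc[s >= threshold]
    low = counts.loc[s < threshold]
    if len(high) == 0:
        raise ValueError(f"no cells with score >= {threshold}")
    if len(low) == 0:
        raise ValueError(f"no cells with score < {threshold}")
    if min(len(high), len(low)) < min_group:
        raise ValueError(f"both score groups need >= {min_group} cells")

    logn = lognormalize(counts)
    hi, lo = logn.loc[high.index].to_numpy(), logn.loc[low.index].to_numpy()
    res = stats.mannwhitneyu(hi, lo, axis=0, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    # fold change of mean normalized (linear-scale) expression
    mh = np.expm1(hi).mean(axis=0)
    ml = np.expm1(lo).mean(axis=0)
    lfc = np.log2((mh + 1.0) / (ml + 1.0))

    p_adj = np.minimum(1.0, pvals * counts.shape[1])
    table = pd.DataFrame(
        {"log2_fc": lfc, "p": pvals, "p_bonferroni": p_adj}, index=counts.columns
    )
    passing = table[(table["p_bonferroni"] < alpha) & (table["log2_fc"] > 0)]
    passing = passing.sort_values("log2_fc", ascending=False)
    if len(passing) < n_genes:
        warnings.warn(
            f"only {len(passing)} genes pass the signature criteria "
            f"(requested {n_genes})",
            stacklevel=2,
        )
    return SignatureGeneSet(table=passing.head(n_genes))


def pseudo_bulk(counts: pd.DataFrame, sample_of_cell: pd.Series) -> pd.DataFrame:
    """Sum raw counts to the sample level. Conserves total counts exactly."""
    missing = counts.index.difference(sample_of_cell.index)
    if len(missing):
        raise ValueError(f"cells without a sample label: {list(missing[:5])}")
    return counts.groupby(sample_of_cell.loc[counts.index]).sum()


def gene_set_score(
    bulk: pd.DataFrame,
    signature: SignatureGeneSet | list[str],
    input_is_counts: bool = True,
) -> pd.Series:
    """First-principal-component gene-set score per sample.

    Expression is restricted to the signature genes (absent genes dropped
    with a warning), log1p-CPM transformed when ``input_is_counts``, and each
    gene z-scored across samples (zero-variance genes dropped). Per-sample
    scores are the projections onto the first principal component, sign-
    oriented to correlate positively with the per-sample mean z-score. The
    scores have mean zero across samples.
    """
    genes = signature.genes if isinstance(signature, SignatureGeneSet) else list(signature)
    if bulk.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    present = [g for g in genes if g in bulk.columns]
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} signature genes absent from the "
            "expression matrix",
            stacklevel=2,
        )
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    X = bulk[present].to_numpy(dtype=float)
    if input_is_counts:
        totals = bulk.sum(axis=1).to_numpy()
        if (totals == 0).any():
            raise ValueError("zero-count samples present")
        X = np.log1p(X / totals[:, None] * 1e6)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all signature genes have zero variance across samples")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    proj = U[:, 0] * S[0]
    mean_z = Z.mean(axis=1)
    if np.corrcoef(proj, mean_z)[0, 1] < 0:
        proj = -proj
    return pd.Series(proj, index=bulk.index, name="gene_set_score")


def subset_top_fraction(scores: pd.Series, frac: float = 0.10) -> pd.Index:
    """Samples whose score reaches the top ``frac`` empirical quantile.

    Ties at the cutoff are all included.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    cutoff = np.quantile(scores.to_numpy(dtype=float), 1.0 - frac)
    return scores.index[scores >= cutoff]


def spearman_correlate(
    scores: CellScores | pd.Series, protein: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of per-cell scores with each antibody's CLR values."""
    s = scores.scores if isinstance(scores, CellScores) else scores
    common = s.index.intersection(protein.index)
    if len(common) < 3:
        raise ValueError("need at least 3 matched cells")
    sv = s.loc[common].to_numpy(dtype=float)
    if np.ptp(sv) == 0:
        raise ValueError("constant scores: correlation undefined")
    rows = {}
    for ab in protein.columns:
        y = protein.loc[common, ab].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"constant antibody values: {ab}")
        rho, p = stats.spearmanr(sv, y)
        rows[ab] = {"rho": float(rho), "p": float(p)}
    return pd.DataFrame(rows).T
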