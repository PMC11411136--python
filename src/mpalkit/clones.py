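"""Clone calling, mutation co-occurrence, and mutation-tree inference.

Genetic clones are groups of more than ten cells with identical ternary
genotype calls across the patient's pathogenic variants (heterozygous and
homozygous states are distinct clones). Clone-level mutation co-occurrence is
summarized as a log2 odds ratio with Fisher's exact test. Mutation trees are
inferred under the standard single-cell phylogeny error model — a false
positive rate alpha for wild-type entries observed as mutant and a false
negative rate beta for mutant entries observed as wild type, with cells
attached to tree nodes and marginalized uniformly over attachments. At the
small mutation counts targeted here the maximum-likelihood tree is found by
exhaustive enumeration of all rooted labeled trees rather than MCMC search.
Immunophenotype evolution along the tree is quantified by two-sample
t-statistics of each surface antibody between the founding clone and every
subsequent clone.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Clone",
    "MutationTree",
    "call_clones",
    "cooccurrence",
    "tree_log_likelihood",
    "enumerate_trees",
    "infer_tree_ml",
    "founding_clone",
    "evolution_tstats",
    "point_biserial",
]


@dataclass
class Clone:
    genotype: tuple[float, ...]
    cells: pd.Index
    mutations: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def mutation_set(self) -> frozenset[str]:
        """Mutations carried (any non-reference state)."""
        return frozenset(m for m, g in zip(self.mutations, self.genotype) if g > 0)


@dataclass
class MutationTree:
    """A rooted mutation tree with per-cell attachments.

    ``parents[i]`` is the parent node index of mutation i; node 0 is the
    wild-type root and mutation i occupies node i+1. ``clone_frequencies``
    has one row per node with the fraction of cells attached there and a
    nonparametric bootstrap 95% interval over cells.
    """

    mutations: tuple[str, ...]
    parents: np.ndarray  # parent node index per node (root's parent = -1)
    alpha: float
    beta: float
    log_likelihood: float
    attachments: pd.Series  # per cell: ML attachment node index
    clone_frequencies: pd.DataFrame

    def node_name(self, node: int) -> str:
        return "root" if node == 0 else self.mutations[node - 1]

    def newick(self) -> str:
        children: dict[int, list[int]] = {}
        for node in range(1, len(self.parents)):
            children.setdefault(int(self.parents[node]), []).append(node)

        def fmt(node: int) -> str:
            kids = children.get(node, [])
            label = self.node_name(node)
            if not kids:
                return label
            return "(" + ",".join(fmt(c) for c in sorted(kids)) + ")" + label

        return fmt(0) + ";"


# ---------------------------------------------------------------------------
# clone calling


def call_clones(
    G: pd.DataFrame, min_cells: int = 10
) -> tuple[list[Clone], pd.Index]:
    """Group cells by identical ternary genotype; keep groups of > ``min_cells``.

    Cells with any missing call among the selected variants are excluded from
    clone calling and returned as the second element. Clones are ordered by
    decreasing size.
    """
    mutations = tuple(G.columns)
    complete = G.dropna()
    clones: list[Clone] = []
    for geno, sub in complete.groupby(list(G.columns), sort=False):
        if len(sub) > min_cells:
            geno_t = geno if isinstance(geno, tuple) else (geno,)
            clones.append(
                Clone(
                    genotype=tuple(float(g) for g in geno_t),
                    cells=sub.index,
                    mutations=mutations,
                )
            )
    clones.sort(key=lambda c: -c.size)
    assigned = set()
    for c in clones:
        assigned.update(c.cells)
    unassigned = G.index[[cell not in assigned for cell in G.index]]
    return clones, unassigned


# ---------------------------------------------------------------------------
# co-occurrence


def cooccurrence(clone_mutations: pd.DataFrame) -> pd.DataFrame:
    """Clone-level mutation pair co-occurrence.

    ``clone_mutations`` is a clones x mutations binary matrix. For each
    unordered mutation pair a 2x2 contingency table over clones is built;
    the odds ratio uses the Haldane-Anscombe 0.5 correction whenever any cell
    is zero, and significance is the two-sided Fisher exact p-value.
    """
    if clone_mutations.shape[0] < 2 or clone_mutations.shape[1] < 2:
        raise ValueError("need at least 2 clones and 2 mutations")
    M = clone_mutations.to_numpy() > 0
    rows = []
    for i, j in combinations(range(M.shape[1]), 2):
        a = int((M[:, i] & M[:, j]).sum())
        b = int((M[:, i] & ~M[:, j]).sum())
        c = int((~M[:, i] & M[:, j]).sum())
        d = int((~M[:, i] & ~M[:, j]).sum())
        if min(a, b, c, d) == 0:
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "mutation_a": clone_mutations.columns[i],
                "mutation_b": clone_mutations.columns[j],
                "log2_odds_ratio": float(np.log2(orr)),
                "fisher_p": float(p),
                "n11": a,
                "n10": b,
                "n01": c,
                "n00": d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tree likelihood and exhaustive ML inference


def _attachment_genotypes(parents: np.ndarray, m: int) -> np.ndarray:
    """(m+1) x m binary matrix: mutations carried by a cell attached at each node."""
    A = np.zeros((m + 1, m), dtype=float)
    for node in range(1, m + 1):
        cur = node
        while cur != 0:
            A[node, cur - 1] = 1.0
            cur = int(parents[cur])
    return A


def _obs_log_probs(
    X: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry log P(obs | true=1) and log P(obs | true=0); missing -> 0.

    Zero error rates are floored at exp(-745) (the double-precision underflow
    point) so that impossible observations carry effectively zero likelihood
    without producing -inf * 0 artifacts in the attachment matmul.
    """
    floor = -745.0
    la = np.log(alpha) if alpha > 0 else floor
    lb = np.log(beta) if beta > 0 else floor
    l1a, l1b = np.log1p(-alpha), np.log1p(-beta)
    L1 = np.where(X == 1, l1b, np.where(X == 0, lb, 0.0))
    L0 = np.where(X == 1, la, np.where(X == 0, l1a, 0.0))
    return L1, L0


def _cell_attachment_loglik(
    X: np.ndarray, parents: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    m = X.shape[1]
    A = _attachment_genotypes(parents, m)
    L1, L0 = _obs_log_probs(X, alpha, beta)
    # n x (m+1): log-likelihood of each cell under each attachment
    return L1 @ A.T + L0 @ (1.0 - A).T

def tree_log_likelihood(
    parents: np.ndarray,
    X: np.ndarray,
    alpha: float = 0.01,
    beta: float = 0.1,
) -> float:
    """Log marginal likelihood of binary genotype data under a mutation tree.

    Each cell attaches to one of the m+1 nodes with uniform prior; its
    expected genotype is the set of mutations on the node's root path, and
    entries are observed through the (alpha, beta) error channel. Missing
    entries (NaN) contribute likelihood 1.
    """
    if not (0 <= alpha < 0.5 and 0 <= beta < 0.5):
        raise ValueError("alpha and beta must be in [0, 0.5)")
    ll = _cell_attachment_loglik(np.asarray(X, dtype=float), parents, alpha, beta)
    m1 = ll.shape[1]
    cell_ll = np.logaddexp.reduce(ll, axis=1) - np.log(m1)
    return float(cell_ll.sum())


def enumerate_trees(m: int) -> list[np.ndarray]:
    """All rooted labeled mutation trees on m mutations plus a root.

    Enumerated via Pruefer sequences on m+1 labeled nodes (node 0 = root),
    giving the Cayley count (m+1)^(m-1) trees.
    """
    n = m + 1
    if m == 1:
        return [np.array([-1, 0])]
    trees = []
    for seq in product(range(n), repeat=n - 2):
        degree = np.ones(n, dtype=int)
        for v in seq:
            degree[v] += 1
        adj: dict[int, list[int]] = {v: [] for v in range(n)}
        avail = sorted(v for v in range(n) if degree[v] == 1)
        seq_list = list(seq)
        heap = avail[:]
        heapq.heapify(heap)
        for v in seq_list:
            leaf = heapq.heappop(heap)
            adj[leaf].append(v)
            adj[v].append(leaf)
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(heap, v)
        u, v = heapq.heappop(heap), heapq.heappop(heap)
        adj[u].append(v)
        adj[v].append(u)
        # root at node 0
        parents = np.full(n, -1, dtype=int)
        stack = [0]
        seen = {0}
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    parents[nb] = cur
                    seen.add(nb)
                    stack.append(nb)
        trees.append(parents)
    return trees


def infer_tree_ml(
    G: pd.DataFrame,
    alpha: float = 0.01,
    beta: float = 0.1,
    max_mutations: int = 7,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> MutationTree:
    """Exhaustive maximum-likelihood mutation-tree inference.

    ``G`` is a cells x mutations binary matrix (NaN = missing). All
    (m+1)^(m-1) rooted labeled trees are scored by marginal likelihood and
    the maximum is returned (first in enumeration order on ties). Per-cell
    maximum-likelihood attachments define clones; clone frequencies carry
    nonparametric bootstrap 95% percentile intervals over cells.
    """
    m = G.shape[1]
    if m > max_mutations:
        raise ValueError(
            f"{m} mutations exceed max_mutations={max_mutations}: exhaustive "
            "enumeration is infeasible; use a dedicated MCMC tree tool"
        )
    if m < 1:
        raise ValueError("need at least one mutation")
    X = G.to_numpy(dtype=float)
    best_ll, best_parents = -np.inf, None
    for parents in enumerate_trees(m):
        ll = tree_log_likelihood(parents, X, alpha, beta)
        if ll > best_ll:
            best_ll, best_parents = ll, parents

    cell_ll = _cell_attachment_loglik(X, best_parents, alpha, beta)
    attach = cell_ll.argmax(axis=1)
    n = len(G)
    node_names = ["root"] + list(G.columns)
    freqs = np.bincount(attach, minlength=m + 1) / n

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, m + 1))
    for b in range(n_bootstrap):
        resampled = attach[rng.integers(0, n, n)]
        boot[b] = np.bincount(resampled, minlength=m + 1) / n
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    clone_freq = pd.DataFrame(
        {"frequency": freqs, "ci_low": lo, "ci_high": hi}, index=node_names
    )
    return MutationTree(
        mutations=tuple(G.columns),
        parents=best_parents,
        alpha=alpha,
        beta=beta,
        log_likelihood=best_ll,
        attachments=pd.Series(attach, index=G.index),
        clone_frequencies=clone_freq,
    )


# ---------------------------------------------------------------------------
# immunophenotype evolution


def founding_clone(clones: list[Clone]) -> Clone:
    """The clone whose mutation set is ancestral to all other mutated clones.

    The founding clone is the non-wild-type clone whose mutations are a
    subset of every other mutated clone's mutations; the largest such clone
    is taken when several qualify.
    """
    mutated = [c for c in clones if c.mutation_set]
    if not mutated:
        raise ValueError("no mutated clone present")
    candidates = [
        c
        for c in mutated
        if all(c.mutation_set <= other.mutation_set for other in mutated)
    ]
    if not candidates:
        raise ValueError("no clone is ancestral to all others; tree is ambiguous")
    return max(candidates, key=lambda c: c.size)


def evolution_tstats(
    clones: list[Clone],
    protein: pd.DataFrame,
    founding: Clone | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Immunophenotype change from the founding clone to each subsequent clone.

    For every non-founding clone and every antibody a two-sample Student
    t-statistic (clone minus founding) is computed on the CLR protein values,
    with two-sided p-values Bonferroni-adjusted across all antibody x clone
    comparisons within the patient. Returns the long-format table and the
    per-antibody maximum t across clones.
    """
    founding = founding or founding_clone(clones)
    others = [c for c in clones if c.genotype != founding.genotype]
    if not others:
        raise ValueError("need at least one non-founding clone")
    base = protein.loc[founding.cells]
    rows = []
    n_tests = len(others) * protein.shape[1]
    for clone in others:
        sub = protein.loc[clone.cells]
        if len(sub) < 2 or len(base) < 2:
            raise ValueError("need >= 2 cells per compared clone")
        name = "+".join(sorted(clone.mutation_set)) or "WT"
        for ab in protein.columns:
            res = stats.ttest_ind(sub[ab], base[ab], equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
            if not np.isfinite(t):  # zero pooled variance
                t = np.inf if sub[ab].mean() > base[ab].mean() else -np.inf
                p = 0.0
            rows.append(
                {
                    "clone": name,
                    "antibody": ab,
                    "t": t,
                    "p": p,
                    "p_bonferroni": min(1.0, p * n_tests),
                }
            )
    table = pd.DataFrame(rows)
    max_t = table.groupby("antibody")["t"].max()
    return table, max_t


def point_biserial(membership: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Point-biserial correlation between binary clone membership and a value.

    Equivalent to the Pearson correlation of the 0/1 indicator with y; the
    p-value is from the t transform with n-2 degrees of freedom.
    """
    membership = np.asarray(membership, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant values: correlation undefined")
    if membership.min() == membership.max():
        raise ValueError("both membership groups must be nonempty")
    res = stats.pointbiserialr(membership, y)
    return float(res.correlation), float(res.pvalue)
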