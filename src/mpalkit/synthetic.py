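"""Ground-truthed synthetic data generators.

Three generators emulate the statistical structure of a pooled multiomic
leukemia study:

* :func:`simulate_pool` — a multiplexed run of ``n_patients`` samples, each
  stained with a unique hashing antibody, with patient-discriminating binary
  SNPs, missing genotype calls, and two-patient doublets.
* :func:`simulate_clonal_patient` — one patient's tumor with clonal
  substructure on a mutation tree, genotype false-positive/false-negative
  noise, and surface-protein shifts coupled to mutation acquisition.
* :func:`simulate_expression_cohort` — a cohort of expression samples with a
  latent per-cell stemness gradient driving both expressed-gene breadth and a
  block of signature genes, plus survival times under a proportional-hazards
  effect of sample-level stemness.

Every generator takes an explicit seed and is bit-reproducible; no global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PoolSimConfig",
    "CloneSimConfig",
    "ExpressionSimConfig",
    "SimulatedTruth",
    "simulate_pool",
    "simulate_clonal_patient",
    "simulate_expression_cohort",
]


@dataclass(frozen=True)
class PoolSimConfig:
    """Configuration for a multiplexed pool of patients.

    Hash counts are drawn log-normal: stained cells from
    ``exp(N(hash_signal_mu, hash_signal_sigma))`` and unstained background
    from ``exp(N(hash_background_mu, hash_background_sigma))``, producing the
    bimodal per-hash distribution the assignment step assumes.
    """

    n_patients: int = 3
    cells_per_patient: int = 1000
    n_snps: int = 30
    discriminative_fraction: float = 0.6
    missing_rate: float = 0.05
    doublet_rate: float = 0.03
    hash_signal_mu: float = 6.0
    hash_signal_sigma: float = 0.5
    hash_background_mu: float = 2.0
    hash_background_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("discriminative_fraction", "missing_rate", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cells_per_patient < 1 or self.n_snps < 1:
            raise ValueError("cells_per_patient and n_snps must be positive")


@dataclass(frozen=True)
class CloneSimConfig:
    """Configuration for one patient's clonal structure.

    ``tree_edges`` are parent->child mutation edges; the parent of a truncal
    mutation is the literal string ``"root"``. Every tree node (including the
    wild-type root) is a clone, and ``clone_fractions`` gives the expected
    fraction of cells per clone. ``alpha_fp`` is the per-entry genotype
    false-positive rate (0 observed as 1) and ``beta_fn`` the false-negative
    rate (1 observed as 0).
    """

    tree_edges: tuple[tuple[str, str], ...] = (("root", "DNMT3A"), ("DNMT3A", "NPM1"))
    clone_fractions: tuple[tuple[str, float], ...] = (
        ("root", 0.2),
        ("DNMT3A", 0.4),
        ("NPM1", 0.4),
    )
    alpha_fp: float = 0.01
    beta_fn: float = 0.1
    protein_shift_map: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    antibodies: tuple[str, ...] = ("CD34", "CD38", "CD117", "HLA-DR")
    protein_noise_sd: float = 1.0
    n_cells: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_fp < 0.5 or not 0.0 <= self.beta_fn < 0.5:
            raise ValueError("alpha_fp and beta_fn must be in [0, 0.5)")
        fracs = dict(self.clone_fractions)
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError("clone_fractions must sum to 1")
        parents = self.parent_map()
        nodes = set(parents) | {"root"}
        if set(fracs) != nodes:
            raise ValueError("clone_fractions must cover every tree node incl. root")
        # acyclicity / rootedness: walking up from each node must reach root
        for node in parents:
            seen = set()
            cur = node
            while cur != "root":
                if cur in seen:
                    raise ValueError("tree_edges contain a cycle")
                seen.add(cur)
                cur = parents[cur]

    def parent_map(self) -> dict[str, str]:
        parents: dict[str, str] = {}
        for parent, child in self.tree_edges:
            if child in parents:
                raise ValueError(f"mutation {child!r} has more than one parent")
            parents[child] = parent
        return parents


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration for the expression + survival cohort.

    ``stemness_effect`` scales both the per-cell capture efficiency (so that
    expressed-gene breadth increases with latent stemness) and the fold-change
    of the ``signature_size`` stemness-tracking genes. ``survival_log_hr`` is
    the log hazard ratio per standard deviation of sample-level mean stemness;
    with both set to 0 the cohort is an exchangeable null.
    """

    n_samples: int = 40
    cells_per_sample: int = 100
    n_genes: int = 800
    stemness_effect: float = 1.0
    signature_size: int = 60
    survival_log_hr: float = 1.0
    censor_rate: float = 0.2
    n_mito_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if min(self.n_samples, self.cells_per_sample, self.n_genes) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class SimulatedTruth:
    """Ground truth for a simulated dataset.

    ``cells`` is indexed by barcode and carries whichever per-cell truth the
    generator produced (patient label, doublet flag, clone id, latent
    stemness). ``samples``, ``tree`` and ``survival_params`` are populated by
    the generators to which they apply.
    """

    cells: pd.DataFrame
    samples: pd.DataFrame | None = None
    tree: dict[str, str] | None = None
    survival_params: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# pooled run


def simulate_pool(cfg: PoolSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Simulate a multiplexed pool.

    Returns ``(genotypes, hash_counts, truth)``. ``genotypes`` is a
    cells x SNP frame of calls in {0, 1} with NaN for missing; each patient
    carries a disjoint block of discriminative SNPs, and the remaining SNPs
    are common to all patients (and hence uninformative). ``hash_counts`` is
    a cells x hash integer count frame. Doublets (appended after the
    singlets) take the element-wise max of two distinct patients' genotypes
    and show signal-level counts on both patients' hashes.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_patients
    n_disc = max(k, int(round(cfg.discriminative_fraction * cfg.n_snps)))
    n_disc = min(n_disc, cfg.n_snps)

    # patient genotype patterns: discriminative SNPs assigned round-robin,
    # the rest mutated in every patient
    patterns = np.zeros((k, cfg.n_snps), dtype=float)
    for s in range(n_disc):
        patterns[s % k, s] = 1.0
    patterns[:, n_disc:] = 1.0

    n_singlets = k * cfg.cells_per_patient
    patient_of = np.repeat(np.arange(k), cfg.cells_per_patient)
    n_doublets = int(rng.binomial(n_singlets, cfg.doublet_rate))
    pair_a = rng.integers(0, k, size=n_doublets)
    pair_b = (pair_a + 1 + rng.integers(0, k - 1, size=n_doublets)) % k

    geno = patterns[patient_of]
    if n_doublets:
        geno = np.vstack([geno, np.maximum(patterns[pair_a], patterns[pair_b])])
    n_total = n_singlets + n_doublets

    missing = rng.random(geno.shape) < cfg.missing_rate
    geno = geno.copy()
    geno[missing] = np.nan

    # hash counts: signal on own hash(es), background elsewhere
    stained = np.zeros((n_total, k), dtype=bool)
    stained[np.arange(n_singlets), patient_of] = True
    if n_doublets:
        rows = n_singlets + np.arange(n_doublets)
        stained[rows, pair_a] = True
        stained[rows, pair_b] = True
    log_counts = rng.normal(cfg.hash_background_mu, cfg.hash_background_sigma, (n_total, k))
    log_signal = rng.normal(cfg.hash_signal_mu, cfg.hash_signal_sigma, (n_total, k))
    log_counts[stained] = log_signal[stained]
    counts = np.round(np.exp(log_counts)).astype(np.int64)

    barcodes = [f"BC{i:06d}" for i in range(n_total)]
    snp_names = [f"SNP{j:03d}" for j in range(cfg.n_snps)]
    hash_names = [f"HASH{p}" for p in range(k)]

    genotypes = pd.DataFrame(geno, index=barcodes, columns=snp_names)
    hashes = pd.DataFrame(counts, index=barcodes, columns=hash_names)

    labels = [f"HASH{p}" for p in patient_of] + ["doublet"] * n_doublets
    truth_cells = pd.DataFrame(
        {
            "patient": labels,
            "is_doublet": [False] * n_singlets + [True] * n_doublets,
            "doublet_a": [None] * n_singlets + [f"HASH{p}" for p in pair_a],
            "doublet_b": [None] * n_singlets + [f"HASH{p}" for p in pair_b],
        },
        index=barcodes,
    )
    return genotypes, hashes, SimulatedTruth(cells=truth_cells)


# ---------------------------------------------------------------------------
# clonal patient


def _root_paths(parents: dict[str, str]) -> dict[str, frozenset[str]]:
    """Mutation set carried by the clone attached at each node."""
    paths: dict[str, frozenset[str]] = {"root": frozenset()}

    def resolve(node: str) -> frozenset[str]:
        if node in paths:
            return paths[node]
        paths[node] = resolve(parents[node]) | {node}
        return paths[node]

    for node in parents:
        resolve(node)
    return paths


def simulate_clonal_patient(
    cfg: CloneSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Simulate one patient's cells from a clonal mutation tree.

    Returns ``(genotypes, proteins, truth)``. Observed genotype entries flip
    0->1 with probability ``alpha_fp`` and 1->0 with probability ``beta_fn``.
    Protein values are standard-normal noise (SD ``protein_noise_sd``) plus
    the additive per-clone shifts in ``protein_shift_map``.
    """
    rng = np.random.default_rng(cfg.seed)
    parents = cfg.parent_map()
    mutations = sorted(parents)
    paths = _root_paths(parents)
    clones = [name for name, _ in cfg.clone_fractions]
    fracs = np.array([f for _, f in cfg.clone_fractions], dtype=float)

    clone_idx = rng.choice(len(clones), size=cfg.n_cells, p=fracs / fracs.sum())
    true_geno = np.array(
        [[1.0 if m in paths[clones[c]] else 0.0 for m in mutations] for c in clone_idx]
    )
    flips = rng.random(true_geno.shape)
    observed = true_geno.copy()
    observed[(true_geno == 0) & (flips < cfg.alpha_fp)] = 1.0
    observed[(true_geno == 1) & (flips < cfg.beta_fn)] = 0.0

    proteins = rng.normal(0.0, cfg.protein_noise_sd, (cfg.n_cells, len(cfg.antibodies)))
    shift_map = {clone: dict(shifts) for clone, shifts in cfg.protein_shift_map}
    for j, ab in enumerate(cfg.antibodies):
        shifts = np.array([shift_map.get(clones[c], {}).get(ab, 0.0) for c in clone_idx])
        proteins[:, j] += shifts

    barcodes = [f"CELL{i:05d}" for i in range(cfg.n_cells)]
    geno_df = pd.DataFrame(observed, index=barcodes, columns=mutations)
    prot_df = pd.DataFrame(proteins, index=barcodes, columns=list(cfg.antibodies))
    truth = SimulatedTruth(
        cells=pd.DataFrame({"clone": [clones[c] for c in clone_idx]}, index=barcodes),
        tree=dict(parents),
    )
    return geno_df, prot_df, truth


# ---------------------------------------------------------------------------
# expression cohort


def simulate_expression_cohort(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SimulatedTruth]:
    """Simulate a cohort of expression samples with survival outcomes.

    Returns ``(counts, sample_of_cell, survival, truth)``:

    * ``counts`` — cells x genes raw negative-binomial counts. The first
      ``signature_size`` genes (``SIG####``) have means scaled by
      ``exp(stemness_effect * (stemness - 0.5))``; every gene's mean is
      additionally scaled by a per-cell capture factor
      ``exp(0.6 * stemness_effect * (stemness - 0.5))`` so that expressed-gene
      breadth tracks stemness. ``n_mito_genes`` genes named ``MT-*`` carry no
      stemness signal.
    * ``survival`` — per sample: ``time`` (exponential PH model with linear
      predictor ``survival_log_hr * z``, ``z`` the standardized sample mean
      stemness) and ``event`` (0 under independent exponential censoring).
    """
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_samples * cfg.cells_per_sample

    centers = rng.uniform(0.05, 0.95, cfg.n_samples)
    stem = np.clip(
        np.repeat(centers, cfg.cells_per_sample) + rng.normal(0.0, 0.1, n_cells), 0.0, 1.0
    )

    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base = base / base.mean() * 2.0  # mean expression ~2 counts/gene at stemness 0.5
    capture = np.exp(0.6 * cfg.stemness_effect * (stem - 0.5))
    mu = np.outer(capture, base)
    sig_scale = np.exp(cfg.stemness_effect * (stem - 0.5))
    mu[:, : cfg.signature_size] *= sig_scale[:, None]

    theta = 10.0  # NB dispersion: var = mu + mu^2/theta
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    gene_names = [f"SIG{j:04d}" for j in range(cfg.signature_size)] + [
        f"GENE{j:04d}" for j in range(cfg.signature_size, cfg.n_genes - cfg.n_mito_genes)
    ] + [f"MT-G{j}" for j in range(cfg.n_mito_genes)]
    barcodes = [f"CELL{i:06d}" for i in range(n_cells)]
    sample_names = [f"SAMPLE{s:03d}" for s in range(cfg.n_samples)]
    sample_of_cell = pd.Series(
        np.repeat(sample_names, cfg.cells_per_sample), index=barcodes, name="sample"
    )
    counts_df = pd.DataFrame(counts, index=barcodes, columns=gene_names)

    sample_mean = stem.reshape(cfg.n_samples, cfg.cells_per_sample).mean(axis=1)
    sd = sample_mean.std(ddof=0)
    z = (sample_mean - sample_mean.mean()) / sd if sd > 0 else np.zeros_like(sample_mean)
    base_rate = 0.1
    hazard = base_rate * np.exp(cfg.survival_log_hr * z)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        c_rate = base_rate * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, cfg.n_samples)
    else:
        t_censor = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    survival = pd.DataFrame({"time": time, "event": event}, index=sample_names)

    truth = SimulatedTruth(
        cells=pd.DataFrame(
            {"stemness": stem, "sample": sample_of_cell.values}, index=barcodes
        ),
        samples=pd.DataFrame(
            {"mean_stemness": sample_mean, "stemness_z": z}, index=sample_names
        ),
        survival_params={"log_hr_per_sd": cfg.survival_log_hr, "base_rate": base_rate},
    )
    return counts_df, sample_of_cell, survival, truth
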