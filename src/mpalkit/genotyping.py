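"""Per-barcode and per-call genotype quality control.

Produces the clean cells x variants genotype matrix downstream clonal and
demultiplexing analyses consume. Calls arrive as a long-format table of
per-(cell, variant) records with GATK-style fields: ternary genotype GT
(0 = reference, 1 = heterozygous, 2 = homozygous alternate), genotype quality
GQ, read depth DP, and alternate allele fraction AF.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "call_valid_barcodes",
    "filter_variant_calls",
    "prevalence_filter",
    "calls_to_matrix",
    "binarize",
]

CALL_COLUMNS = ("cell", "variant", "GT", "GQ", "DP", "AF")


def _knee_rank(counts: np.ndarray) -> int:
    """Index (0-based, in descending-count order) of the rank-plot knee.

    The knee is the point of maximum perpendicular distance to the chord of
    the log-log rank curve — a deterministic realization of the inflection
    point of the barcode rank plot. Invariant to monotone rescaling of the
    counts up to log-affine transforms.
    """
    n = len(counts)
    if n < 3:
        return n - 1
    x = np.log10(np.arange(1, n + 1))
    y = np.log10(counts.astype(float))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return n - 1
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(np.argmax(dist))


def call_valid_barcodes(
    rank_counts: pd.Series,
    coverage: pd.DataFrame | None = None,
    min_interval_frac: float = 0.60,
    min_reads: int = 8,
) -> pd.Index:
    """Select valid cell barcodes.

    A barcode is valid if it lies above (inclusive) the knee of the read-count
    rank plot and, when ``coverage`` (cells x amplicon-interval read counts)
    is given, at least ``min_interval_frac`` of its intervals are covered by
    ``min_reads`` or more reads.
    """
    if len(rank_counts) == 0:
        raise ValueError("rank_counts is empty")
    if (rank_counts <= 0).all():
        raise ValueError("all barcode counts are zero")
    counts = rank_counts[rank_counts > 0].sort_values(ascending=False)
    knee = _knee_rank(counts.to_numpy())
    valid = counts.index[: knee + 1]
    if coverage is not None:
        if (coverage.to_numpy() < 0).any():
            raise ValueError("interval coverage must be nonnegative")
        frac = (coverage >= min_reads).mean(axis=1)
        covered = frac.index[frac >= min_interval_frac]
        valid = valid.intersection(covered)
    return pd.Index(valid)


def filter_variant_calls(
    table: pd.DataFrame,
    min_gq: float = 30,
    min_dp: float = 10,
    min_af: float = 0.20,
) -> pd.DataFrame:
    """Mask low-quality genotype calls as missing.

    Any call with GQ < ``min_gq`` or DP < ``min_dp``, and any non-reference
    call with AF < ``min_af``, has its GT and AF set to missing (NaN). Calls
    are masked rather than coerced to reference: a failed call carries no
    evidence for the wild-type allele. Idempotent.
    """
    missing = [c for c in CALL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"call table missing columns: {missing}")
    if (table["DP"].dropna() < 0).any() or (table["GQ"].dropna() < 0).any():
        raise ValueError("negative DP or GQ in call table")
    out = table.copy()
    bad = (out["GQ"] < min_gq) | (out["DP"] < min_dp)
    bad |= (out["GT"] > 0) & (out["AF"] < min_af)
    out.loc[bad, ["GT", "AF"]] = np.nan
    return out


def calls_to_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long call table to a cells x variants ternary matrix (NaN = missing)."""
    dup = table.duplicated(subset=["cell", "variant"])
    if dup.any():
        raise ValueError("duplicate (cell, variant) rows in call table")
    return table.pivot(index="cell", columns="variant", values="GT")


def binarize(G: pd.DataFrame) -> pd.DataFrame:
    """Binary view of a ternary genotype matrix: any non-reference call -> 1.

    Missing entries stay missing.
    """
    return (G > 0).astype(float).where(G.notna())


def prevalence_filter(G: pd.DataFrame, min_cell_frac: float = 0.001) -> pd.DataFrame:
    """Keep variants mutated in strictly more than ``min_cell_frac`` of cells.

    The denominator is the number of cells with a non-missing call at the
    variant; variants with no observed calls are dropped.
    """
    if G.shape[0] == 0 or G.shape[1] == 0:
        raise ValueError("empty genotype matrix")
    observed = G.notna().sum(axis=0)
    mutated = (G > 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = mutated / observed.replace(0, np.nan)
    keep = frac > min_cell_frac
    return G.loc[:, keep.fillna(False)]
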