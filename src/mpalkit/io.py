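"""Readers, writers, configuration, and provenance.

Tabular results travel as TSV, matrices as either dense TSV or MatrixMarket
MTX with ``barcodes.tsv``/``features.tsv`` sidecars, configuration as YAML,
and mutation trees as Newick. Every pipeline run writes a provenance
manifest with the resolved configuration, seed, and SHA-256 hashes of its
input files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "FormatError",
    "read_matrix",
    "write_matrix",
    "read_genotype_calls",
    "write_genotype_calls",
    "read_config",
    "write_config",
    "file_sha256",
    "write_manifest",
    "derive_seed",
]

GENOTYPE_COLUMNS = ["cell", "variant", "GT", "GQ", "DP", "AF"]


class FormatError(ValueError):
    """A file did not match the expected on-disk dialect."""


def _check_unique(labels: pd.Index, what: str, path: Path) -> None:
    dup = labels[labels.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate {what} {dup[0]!r} in {path}")


def read_matrix(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a cells x features matrix.

    ``mtx`` format expects ``<stem>.mtx`` plus ``barcodes.tsv`` and
    ``features.tsv`` sidecars in the same directory (one label per line,
    matching the MTX rows and columns respectively); ``tsv`` is a dense
    tab-separated table with barcodes in the first column.
    """
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "mtx":
        try:
            mat = scipy_io.mmread(path)
        except Exception as exc:
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        barcodes = pd.read_csv(path.parent / "barcodes.tsv", header=None, sep="\t")[0]
        features = pd.read_csv(path.parent / "features.tsv", header=None, sep="\t")[0]
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"{path}: matrix is {dense.shape} but sidecars declare "
                f"({len(barcodes)}, {len(features)})"
            )
        df = pd.DataFrame(dense, index=pd.Index(barcodes), columns=pd.Index(features))
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    _check_unique(df.index, "barcode", path)
    _check_unique(df.columns, "feature", path)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy_io.mmwrite(path.with_suffix(".mtx"), sparse.csr_matrix(df.to_numpy()))
        pd.Series(df.index).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False
        )
        pd.Series(df.columns).to_csv(
            path.parent / "features.tsv", sep="\t", index=False, header=False
        )
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_genotype_calls(path: str | Path) -> pd.DataFrame:
    """Read a long-format genotype call table (cell, variant, GT, GQ, DP, AF).

    Missing calls are encoded as ``"."`` in the GT and AF columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("GT", "GQ", "DP", "AF"):
        df[col] = pd.to_numeric(df[col].replace(".", np.nan), errors="raise")
    bad_af = df["AF"].dropna()
    if ((bad_af < 0) | (bad_af > 1)).any():
        v = bad_af[(bad_af < 0) | (bad_af > 1)].iloc[0]
        raise FormatError(f"{path}: AF value {v} outside [0, 1]")
    return df


def write_genotype_calls(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[GENOTYPE_COLUMNS].copy()
    for col in ("GT", "GQ", "DP", "AF"):
        out[col] = out[col].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config: dict, seed: int, inputs: list[str | Path]
) -> Path:
    """Write a provenance manifest next to a run's outputs."""
    import mpalkit

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "mpalkit",
        "version": mpalkit.__version__,
        "seed": seed,
        "config": config,
        "input_hashes": {str(p): file_sha256(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out from one global seed.

    Hashing the stage name makes each stage's stream independent of the
    order in which stages run.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
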