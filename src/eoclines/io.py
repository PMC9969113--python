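"""Readers and writers for count/expression matrices and sample metadata.

Counts live on disk either as a TSV (genes x samples, first column gene ids)
or as a MatrixMarket coordinate file with ``genes.txt``/``samples.txt``
sidecars. Expression matrices are written as TSV with a JSON sidecar that
records the transform chain and parameters, so provenance survives the trip
through the filesystem.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class CountMatrixError(ValueError):
    """Raised when an on-disk count matrix violates the format contract."""


def _validate_counts(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CountMatrixError(f"{origin}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise CountMatrixError(f"{origin}: duplicate sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountMatrixError(f"{origin}: non-numeric entries present")
    if np.isnan(values.astype(float)).any():
        raise CountMatrixError(f"{origin}: missing values present")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise CountMatrixError(
            f"{origin}: negative count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise CountMatrixError(
            f"{origin}: non-integer count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    return df.astype(np.int64)


def read_counts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample count matrix (TSV or MatrixMarket).

    ``format`` is inferred from the suffix when not given. MatrixMarket files
    require ``genes.txt`` and ``samples.txt`` sidecars next to the ``.mtx``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header/body
            raise CountMatrixError(f"{path}: cannot parse TSV: {exc}") from exc
        if df.shape[1] == 0:
            raise CountMatrixError(f"{path}: no sample columns found")
        df.index = df.index.astype(str)
        df.index.name = None  # the id column header is a format artifact
        df.columns = df.columns.astype(str)
        return _validate_counts(df, str(path))
    if fmt == "mtx":
        genes_path = path.parent / "genes.txt"
        samples_path = path.parent / "samples.txt"
        for side in (genes_path, samples_path):
            if not side.exists():
                raise CountMatrixError(f"{path}: missing sidecar {side.name}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise CountMatrixError(f"{path}: cannot parse MatrixMarket: {exc}") from exc
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if dense.shape != (len(genes), len(samples)):
            raise CountMatrixError(
                f"{path}: dimensions {dense.shape} do not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
        return _validate_counts(df, str(path))
    raise ValueError(f"unknown count format {fmt!r} (expected 'tsv' or 'mtx')")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata TSV; requires sample_id and batch columns."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "batch"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata lacks required column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta


def write_expression(
    expr: pd.DataFrame, path: str | Path, sidecar: dict | None = None
) -> Path:
    """Write an expression matrix as TSV plus a JSON provenance sidecar.

    The sidecar records the transform chain from ``expr.attrs['transforms']``
    merged with any extra parameters supplied.
    """
    path = Path(path)
    expr.rename_axis("gene_id").to_csv(path, sep="\t")
    record = {"transforms": expr.attrs.get("transforms", [])}
    record.update(sidecar or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(record, indent=2, default=str) + "\n"
    )
    return path


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV written by :func:`write_expression`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: expression matrix has non-finite entries")
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        df.attrs["transforms"] = json.loads(sidecar.read_text()).get("transforms", [])
    return df
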