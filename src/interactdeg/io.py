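"""Reading, writing and validating count matrices and sample metadata.

Counts live in a genes x samples :class:`pandas.DataFrame` of nonnegative
integers (gene identifiers in the index, sample identifiers in the columns).
Sample metadata is a DataFrame indexed by sample identifier with the two
design factors as columns: ``diet`` (e.g. ``SD``/``WD``) and ``weeks``
(integer feeding duration).

Supported on-disk formats are TSV/CSV (genes in rows, header row of sample
ids) and MatrixMarket triplets with two plain-text index sidecar files
(``<stem>.genes.txt`` and ``<stem>.samples.txt``, one identifier per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

REQUIRED_METADATA_COLUMNS = ("diet", "weeks")


class CountDataError(ValueError):
    """Raised for malformed count or metadata input."""


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a counts DataFrame and return it with an integer dtype.

    Raises :class:`CountDataError` on negative or non-integer entries and on
    duplicated gene or sample identifiers.
    """
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountDataError(f"duplicated gene identifiers: {dupes[:5]}")
    if counts.columns.duplicated().any():
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise CountDataError(f"duplicated sample identifiers: {dupes[:5]}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise CountDataError("counts must be numeric")
    if np.isnan(arr.astype(float)).any():
        raise CountDataError("counts contain missing values")
    if (arr < 0).any():
        raise CountDataError("counts contain negative entries")
    if not np.allclose(arr, np.round(arr.astype(float))):
        raise CountDataError("counts contain non-integer entries")
    return counts.astype(np.int64)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"tsv", "txt"}:
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise CountDataError(f"cannot infer count format from {path.name!r}")


def read_counts(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV, CSV or MTX."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in {"tsv", "csv"}:
        sep = "\t" if fmt == "tsv" else ","
        counts = pd.read_csv(path, sep=sep, index_col=0)
    elif fmt == "mtx":
        mat = spio.mmread(path)
        genes = _read_index(path.with_suffix("").with_suffix(".genes.txt"))
        samples = _read_index(path.with_suffix("").with_suffix(".samples.txt"))
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise CountDataError(
                f"MTX shape {dense.shape} does not match index files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        counts = pd.DataFrame(dense, index=genes, columns=samples)
    else:  # pragma: no cover - _infer_format already rejects
        raise CountDataError(f"unknown format {fmt!r}")
    counts.index.name = "gene_id"
    return validate_counts(counts)


def _read_index(path: Path) -> list[str]:
    if not path.exists():
        raise CountDataError(f"missing MTX index sidecar {path.name!r}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_counts(counts: pd.DataFrame, path: str | Path, fmt: str | None = None) -> Path:
    """Write a count matrix as TSV/CSV, or MTX plus index sidecars."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in {"tsv", "csv"}:
        counts.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.csr_matrix(counts.to_numpy()))
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns ``sample``, ``diet``, ``weeks``."""
    meta = pd.read_csv(path, sep="\t")
    if "sample" not in meta.columns:
        raise CountDataError("metadata must contain a 'sample' column")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise CountDataError(f"metadata missing required columns: {missing}")
    if meta["sample"].duplicated().any():
        raise CountDataError("duplicated sample identifiers in metadata")
    meta = meta.set_index("sample")
    meta["weeks"] = meta["weeks"].astype(int)
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metadata.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)
    return path


def align(counts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reordered to the count matrix columns.

    Every sample in the counts must be described in the metadata; the error
    names the first offending sample.
    """
    missing = [s for s in counts.columns if s not in metadata.index]
    if missing:
        raise CountDataError(
            f"sample {missing[0]!r} present in counts but absent from metadata"
        )
    return metadata.loc[list(counts.columns)]
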