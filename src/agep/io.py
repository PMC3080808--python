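"""Readers and writers for the plain-text formats agep consumes and emits.

Expression matrices are read from TSV (first column gene id, header row of
sample ids, empty cells = missing) or GCT 1.2; tissue labels come from a
two-column sample/tissue TSV; gene sets from GMT.  All writers are
deterministic: floats are formatted at 6 significant digits, gzip members
carry no timestamp, and every output starts with a provenance header naming
the tool version and the configuration hash.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import Config
from .data import ExpressionMatrix
from .enrichment import GeneSetCollection
from .exceptions import InputError
from .scoring import AlignmentResult

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _provenance(config: Config) -> str:
    return f"# agep {__version__} config={config.hash}"


# ---------------------------------------------------------------------------
# expression matrices


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV: sample id, tissue label (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if {first[0].lower(), first[1].lower()} & {"sample", "sample_id", "tissue"}:
        df = df.iloc[1:]
    labels = pd.Series(df[1].values, index=df[0].values, name="tissue")
    if labels.index.duplicated().any():
        raise InputError(f"{path}: duplicate sample ids in label file")
    return labels


def _read_values_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(float)


def _read_values_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise InputError(f"{path}:1: expected GCT version header '#1.2'")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise InputError(f"{path}:2: expected '<n_genes>\\t<n_samples>'")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
        raise InputError(
            f"{path}:2: declared {n_genes}x{n_samples} but found "
            f"{df.shape[0]}x{df.shape[1] - 2}"
        )
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    return df.astype(float)


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    fmt: str | None = None,
) -> ExpressionMatrix:
    """Read a labelled expression matrix from TSV or GCT 1.2.

    ``fmt`` may be "tsv" or "gct"; by default it is inferred from the file
    extension.  Empty cells become missing values, never zeros.
    """
    matrix_path = Path(matrix_path)
    if fmt is None:
        fmt = "gct" if matrix_path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        values = _read_values_gct(matrix_path)
    elif fmt == "tsv":
        values = _read_values_tsv(matrix_path)
    else:
        raise InputError(f"unknown expression format {fmt!r}")
    return ExpressionMatrix(values, read_labels(labels_path))


def read_query(path: str | Path) -> pd.Series:
    """Two-column TSV (gene id, value) query profile."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two tab-separated columns")
    if not np.issubdtype(np.asarray(df.iloc[0, 1]).dtype, np.number):
        try:
            float(df.iloc[0, 1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
    return pd.Series(
        df[1].astype(float).values, index=df[0].astype(str).values, name="query"
    )


def write_matrix_tsv(
    matrix: ExpressionMatrix, matrix_path: str | Path, labels_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", float_format=FLOAT_FMT,
                         index_label="gene")
    matrix.tissue_labels.rename_axis("sample").to_csv(labels_path, sep="\t")


def write_matrix_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", float_format=FLOAT_FMT, index_label="Name")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT: one set per line -- name, description, then member gene ids."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    "and at least one member"
                )
            name, description, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                log.info("%s:%d: %d duplicate members removed from %r",
                         path, lineno, len(members) - len(unique), name)
            sets[name] = unique
            descriptions[name] = description
    if not sets:
        log.warning("%s: empty gene set file", path)
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# alignment output


def _write_frame(df: pd.DataFrame, path: Path, config: Config, index_label: str) -> None:
    header = _provenance(config) + "\n"
    body = df.to_csv(sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    if path.suffix == ".gz":
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write((header + body).encode())
    else:
        path.write_text(header + body)


def write_alignment(result: AlignmentResult, outdir: str | Path, config: Config) -> None:
    """Write similarity ranking, score matrices, typicality and scatter tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = pd.DataFrame(
        {
            "similarity": result.similarity[result.ranking],
            "rank": range(1, len(result.ranking) + 1),
            "n_genes": result.coverage[result.ranking],
            "n_specific": result.specific_counts[result.ranking],
        }
    )
    _write_frame(sim, outdir / "similarity.tsv", config, "tissue")
    _write_frame(result.tm, outdir / "tm.tsv.gz", config, "gene")
    _write_frame(result.ts, outdir / "ts.tsv.gz", config, "gene")
    _write_frame(result.typicality, outdir / "typicality.tsv.gz", config, "gene")
    _write_frame(result.scatter(), outdir / "scatter.tsv", config, "gene")


def read_alignment_frame(path: str | Path) -> pd.DataFrame:
    """Re-read a matrix written by :func:`write_alignment`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
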