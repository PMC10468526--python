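"""Reading and writing the pipeline's on-disk formats.

Count matrices use the CellRanger-style triple: ``matrix.mtx`` (Matrix
Market coordinate format, genes x rows orientation on disk, 1-based
indices), ``genes.tsv`` (gene_id, symbol; row order defines gene order) and
``barcodes.tsv`` (one cell id per line). Matrices are transposed to
cells x genes internally. Everything else is TSV or YAML; undefined
correlation entries serialise as ``"-"``.

All writers go through an atomic replace (write to a temporary file in the
target directory, then rename) so a crashed run never leaves a truncated
output behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as scipy_io
from scipy import sparse

from .coexpression import CorrelationMatrix, GeneSet
from .errors import ConfigurationError, InputFormatError
from .simulate import SimulationConfig, SimTruth

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_groups",
    "write_truth",
    "read_gene_set",
    "write_gene_set",
    "write_correlation_matrix",
    "read_simulation_config",
    "write_simulation_config",
    "atomic_write_text",
    "atomic_write_dataframe",
]

UNDEFINED_MARKER = "-"


def _atomic(path: Path, write: Callable[[Path], None]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # keep the target's suffix: some writers (mmwrite) key behaviour on it
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.stem}.", suffix=path.suffix)
    os.close(fd)
    try:
        write(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_text(path: Path, text: str) -> None:
    _atomic(Path(path), lambda tmp: tmp.write_text(text))


def atomic_write_dataframe(path: Path, df: pd.DataFrame, **to_csv_kwargs) -> None:
    kwargs = {"sep": "\t", "index": False}
    kwargs.update(to_csv_kwargs)
    _atomic(Path(path), lambda tmp: df.to_csv(tmp, **kwargs))


# ---------------------------------------------------------------- count matrix

def write_count_matrix(adata: AnnData, outdir: Path) -> None:
    """Write the CellRanger-style matrix.mtx / genes.tsv / barcodes.tsv triple."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.csr_matrix(adata.X)
    if X.dtype.kind not in "iu":
        if not np.allclose(X.data, np.round(X.data)):
            raise InputFormatError("count matrix is not integral; refusing to write")
        X = X.astype(np.int64)
    _atomic(
        outdir / "matrix.mtx",
        lambda tmp: scipy_io.mmwrite(str(tmp), X.T.tocoo(), field="integer"),
    )
    symbols = (
        adata.var["symbol"]
        if "symbol" in adata.var.columns
        else pd.Series(list(adata.var_names), index=adata.var_names)
    )
    genes = pd.DataFrame({"gene_id": list(adata.var_names), "symbol": list(symbols)})
    atomic_write_dataframe(outdir / "genes.tsv", genes, header=False)
    atomic_write_text(outdir / "barcodes.tsv", "\n".join(adata.obs_names) + "\n")


def read_count_matrix(indir: Path) -> AnnData:
    """Read a matrix.mtx / genes.tsv / barcodes.tsv triple as cells x genes.

    The matrix is genes x cells on disk (CellRanger convention) with 1-based
    coordinate indices; ``%`` comment lines are ignored. Dimension or index
    inconsistencies raise :class:`~agescreen.errors.InputFormatError`.
    """
    indir = Path(indir)
    paths = {name: indir / name for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv")}
    for name, p in paths.items():
        if not p.is_file():
            raise InputFormatError(f"missing input file: {p}")
    try:
        mat = scipy_io.mmread(str(paths["matrix.mtx"]))
    except Exception as exc:  # scipy raises bare ValueError on bad indices
        raise InputFormatError(f"malformed Matrix Market file {paths['matrix.mtx']}: {exc}") from exc
    try:
        genes = pd.read_csv(paths["genes.tsv"], sep="\t", header=None, dtype=str)
    except Exception as exc:
        raise InputFormatError(f"malformed genes.tsv {paths['genes.tsv']}: {exc}") from exc
    barcodes = [
        line.strip() for line in paths["barcodes.tsv"].read_text().splitlines() if line.strip()
    ]
    mat = sparse.coo_matrix(mat)
    if mat.shape[0] != len(genes):
        raise InputFormatError(
            f"{paths['matrix.mtx']}: {mat.shape[0]} rows but genes.tsv lists {len(genes)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise InputFormatError(
            f"{paths['matrix.mtx']}: {mat.shape[1]} columns but barcodes.tsv lists "
            f"{len(barcodes)} cells"
        )
    data = mat.data
    if data.size and (np.any(data != np.round(data)) or np.any(data < 0)):
        raise InputFormatError(f"{paths['matrix.mtx']}: counts must be nonnegative integers")
    X = sparse.csr_matrix(mat.T).astype(np.int64)
    gene_ids = genes.iloc[:, 0].tolist()
    symbols = genes.iloc[:, 1].tolist() if genes.shape[1] > 1 else gene_ids
    var = pd.DataFrame({"gene_id": gene_ids, "symbol": symbols}, index=gene_ids)
    var.index.name = None
    obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    return AnnData(X=X, obs=obs, var=var)


# ------------------------------------------------------------------ annotation

_ANNOTATION_COLUMNS = ["gene_id", "symbol", "length_bp", "is_mitochondrial", "ortholog_symbol"]


def write_annotation(annotation: pd.DataFrame, path: Path) -> None:
    out = annotation[_ANNOTATION_COLUMNS].copy()
    out["is_mitochondrial"] = out["is_mitochondrial"].astype(bool)
    atomic_write_dataframe(Path(path), out, na_rep="")


def read_annotation(path: Path) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise InputFormatError(f"missing annotation file: {path}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"gene_id": str, "symbol": str, "ortholog_symbol": "string"},
        )
    except Exception as exc:
        raise InputFormatError(f"malformed annotation file {path}: {exc}") from exc
    missing = [c for c in _ANNOTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing annotation columns {missing}")
    if "ortholog_symbol" not in df.columns:
        df["ortholog_symbol"] = pd.array([None] * len(df), dtype="string")
    df["is_mitochondrial"] = df["is_mitochondrial"].astype(bool)
    df["length_bp"] = df["length_bp"].astype(np.int64)
    if (df["length_bp"] <= 0).any():
        bad = df.loc[df["length_bp"] <= 0, "gene_id"].tolist()[:10]
        raise InputFormatError(f"{path}: non-positive transcript lengths for {bad}")
    return df[_ANNOTATION_COLUMNS]


# ---------------------------------------------------------------- groups/truth

def write_truth(truth: SimTruth, path: Path) -> None:
    atomic_write_dataframe(Path(path), truth.cells)


def read_groups(path: Path) -> pd.Series:
    """Read a cell_id -> group TSV (columns cell_id, group)."""
    path = Path(path)
    if not path.is_file():
        raise InputFormatError(f"missing group file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "group"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing column {col!r}")
    if df["cell_id"].duplicated().any():
        raise InputFormatError(f"{path}: duplicate cell ids")
    return pd.Series(df["group"].values, index=df["cell_id"].values)


# -------------------------------------------------------------------- gene set

def write_gene_set(gene_set: GeneSet, path: Path) -> None:
    lines = [f"# name={gene_set.name}"] + list(gene_set.symbols)
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_gene_set(path: Path) -> GeneSet:
    """Plain-text gene set: first line ``# name=<set>``, one symbol per line."""
    path = Path(path)
    if not path.is_file():
        raise InputFormatError(f"missing gene-set file: {path}")
    lines = path.read_text().splitlines()
    name = path.stem
    symbols = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("name="):
                name = body[len("name="):].strip()
            continue
        symbols.append(line)
    if not symbols:
        raise InputFormatError(f"{path}: gene set is empty")
    return GeneSet(name=name, symbols=tuple(dict.fromkeys(symbols)))


# ----------------------------------------------------------------- correlation

def write_correlation_matrix(corr: CorrelationMatrix, path: Path) -> None:
    """Serialise a correlation matrix with ``"-"`` for undefined entries."""
    df = corr.matrix.copy()
    atomic_write_dataframe(
        Path(path),
        df.reset_index().rename(columns={"index": "gene"}),
        na_rep=UNDEFINED_MARKER,
        float_format="%.6f",
    )


# ---------------------------------------------------------------------- config

def write_simulation_config(config: SimulationConfig, path: Path) -> None:
    atomic_write_text(Path(path), yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_simulation_config(path: Path) -> SimulationConfig:
    path = Path(path)
    if not path.is_file():
        raise InputFormatError(f"missing configuration file: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise InputFormatError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of SimulationConfig fields")
    return SimulationConfig.from_dict(data)
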