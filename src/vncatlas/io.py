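"""Reading and writing 10x-style MTX count triplets.

The in-memory container for UMI counts is an :class:`anndata.AnnData` with

* ``X``          -- sparse non-negative integer matrix, cells x genes
* ``obs_names``  -- unique cell barcodes
* ``var_names``  -- unique gene symbols
* ``obs``        -- per-cell metadata (replicate, sex, ground-truth columns)
* ``var``        -- optionally a secondary ``gene_id`` column (FlyBase IDs);
                   carried through but never used for matching.

Both Cell Ranger v2 (``genes.tsv``) and v3 (``features.tsv.gz``) dialects are
auto-detected by filename.  On disk the matrix is stored genes x cells (the
Cell Ranger convention); the reader normalises orientation to cells x genes
using the barcode/feature counts.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError

__all__ = ["read_counts_10x", "write_counts_10x", "validate_counts"]

_MATRIX_NAMES = ["matrix.mtx", "matrix.mtx.gz"]
_BARCODE_NAMES = ["barcodes.tsv", "barcodes.tsv.gz"]
_FEATURE_NAMES = ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"]


def _find(path: Path, candidates: list[str], what: str) -> Path:
    for name in candidates:
        p = path / name
        if p.exists():
            return p
    raise FormatError(f"no {what} file found in {path} (looked for {candidates})")


def _read_tsv_column(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.empty:
        raise FormatError(f"{path} is empty")
    return df


def validate_counts(adata: ad.AnnData) -> None:
    """Check the CountMatrix invariants, raising IntegrityError on violation."""
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise IntegrityError("count matrix has zero cells or zero genes")
    if adata.obs_names.duplicated().any():
        dup = adata.obs_names[adata.obs_names.duplicated()][0]
        raise IntegrityError(f"duplicate barcode: {dup!r}")
    if adata.var_names.duplicated().any():
        dup = adata.var_names[adata.var_names.duplicated()][0]
        raise IntegrityError(f"duplicate gene symbol: {dup!r}")
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and data.min() < 0:
        raise IntegrityError("count matrix has negative entries")
    if data.size and not np.allclose(data, np.round(data)):
        raise IntegrityError("count matrix has non-integer entries (UMI counts only)")


def read_counts_10x(path: str | Path) -> ad.AnnData:
    """Read an MTX triplet directory into a cells x genes AnnData.

    Raises
    ------
    FormatError
        if one of the three files is missing or unparseable.
    IntegrityError
        if the triplet files disagree on dimensions, contain duplicate
        barcodes/genes, or the matrix holds non-integer or negative values.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not a directory")
    mtx_path = _find(path, _MATRIX_NAMES, "matrix.mtx")
    bc_path = _find(path, _BARCODE_NAMES, "barcodes.tsv")
    ft_path = _find(path, _FEATURE_NAMES, "features/genes.tsv")

    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"could not parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    barcodes = _read_tsv_column(bc_path)[0].tolist()
    features = _read_tsv_column(ft_path)
    if features.shape[1] >= 2:
        gene_ids = features[0].tolist()
        genes = features[1].tolist()
    else:
        gene_ids = None
        genes = features[0].tolist()

    n_genes, n_cells = len(genes), len(barcodes)
    if mat.shape == (n_genes, n_cells):
        mat = mat.T  # on-disk genes x cells -> cells x genes
    elif mat.shape == (n_cells, n_genes):
        pass
    else:
        raise IntegrityError(
            f"matrix shape {mat.shape} matches neither genes x cells "
            f"({n_genes} x {n_cells}) nor cells x genes"
        )

    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise IntegrityError("MTX file contains non-integer values (UMI counts only)")

    X = sp.csr_matrix(mat, dtype=np.int64)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if gene_ids is not None:
        var["gene_id"] = gene_ids
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = path / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={0: str})
        missing = set(barcodes) - set(meta.index)
        if missing:
            raise IntegrityError(f"cell_meta.tsv missing {len(missing)} barcodes")
        obs = meta.loc[barcodes]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    validate_counts(adata)
    return adata


def write_counts_10x(
    adata: ad.AnnData,
    path: str | Path,
    *,
    dialect: str = "v2",
    sanitize: bool = True,
) -> None:
    """Write a cells x genes AnnData as an on-disk MTX triplet (genes x cells).

    ``dialect="v2"`` writes plain ``matrix.mtx / barcodes.tsv / genes.tsv``;
    ``dialect="v3"`` writes the gzipped ``features.tsv.gz`` flavour.
    Gene symbols containing tabs or newlines are replaced with underscores
    when ``sanitize`` is true, otherwise rejected.
    """
    validate_counts(adata)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    genes = list(adata.var_names)
    bad = [g for g in genes if ("\t" in g or "\n" in g)]
    if bad:
        if not sanitize:
            raise IntegrityError(f"gene symbol contains a delimiter: {bad[0]!r}")
        genes = [g.replace("\t", "_").replace("\n", "_") for g in genes]
    gene_ids = (
        adata.var["gene_id"].tolist() if "gene_id" in adata.var.columns else genes
    )

    X = sp.csc_matrix(adata.X).T.astype(np.int64)  # genes x cells, integer
    gz = dialect == "v3"
    suffix = ".gz" if gz else ""
    opener = gzip.open if gz else open

    with opener(path / f"matrix.mtx{suffix}", "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(X), field="integer")
    with opener(path / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    feat_name = "features.tsv" if dialect == "v3" else "genes.tsv"
    with opener(path / f"{feat_name}{suffix}", "wt") as fh:
        for gid, sym in zip(gene_ids, genes):
            if dialect == "v3":
                fh.write(f"{gid}\t{sym}\tGene Expression\n")
            else:
                fh.write(f"{gid}\t{sym}\n")
    if adata.obs.shape[1]:  # per-cell metadata rides along as plain TSV
        adata.obs.to_csv(path / "cell_meta.tsv", sep="\t")
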