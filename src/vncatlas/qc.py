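"""Cell and gene quality-control filters and replicate-concordance checks.

Default gates: 1200 <= nUMI <= 10000, nGene >= 200, prop_mito <= 0.15, and
genes detected in fewer than 3 surviving cells are dropped.  The upper nUMI
bound can be disabled (``max_umi=None``) when studying cells with very high
transcriptional output, whose totals legitimately exceed the outlier cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .errors import ValidationError

__all__ = [
    "compute_cell_qc",
    "detect_lower_umi_bound",
    "UmiBound",
    "apply_filters",
    "pseudobulk_correlate",
]


def _mito_mask(adata: ad.AnnData, mito_genes) -> np.ndarray:
    if mito_genes is None:
        return np.asarray(adata.var_names.str.startswith("mt:"))
    mito_genes = set(mito_genes)
    missing = mito_genes - set(adata.var_names)
    if missing:
        warnings.warn(f"{len(missing)} mitochondrial genes not in matrix: {sorted(missing)[:5]}")
    return adata.var_names.isin(mito_genes)


def compute_cell_qc(
    adata: ad.AnnData,
    mito_genes=None,
    *,
    min_umi: float = 1200,
    max_umi: float | None = 10000,
    min_genes: int = 200,
    max_mito: float = 0.15,
) -> pd.DataFrame:
    """Per-cell QC table: nUMI, nGene, prop_mito and the pass flag.

    ``mito_genes`` defaults to all genes with the FlyBase ``mt:`` prefix.
    ``max_umi=None`` disables the upper outlier bound.
    """
    if adata.n_obs == 0:
        raise ValidationError("empty matrix")
    X = sp.csr_matrix(adata.X)
    numi = np.asarray(X.sum(axis=1)).ravel()
    ngene = X.getnnz(axis=1)
    mito = _mito_mask(adata, mito_genes)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros_like(numi)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_mito = np.where(numi > 0, mito_counts / np.maximum(numi, 1), 0.0)
    ok = (numi >= min_umi) & (ngene >= min_genes) & (prop_mito <= max_mito)
    if max_umi is not None:
        ok &= numi <= max_umi
    return pd.DataFrame(
        {
            "nUMI": numi.astype(int),
            "nGene": ngene.astype(int),
            "prop_mito": prop_mito,
            "pass": ok,
        },
        index=adata.obs_names.copy(),
    )


@dataclass
class UmiBound:
    threshold: float
    fallback_used: bool


def detect_lower_umi_bound(
    numi,
    *,
    bandwidth: float = 0.05,
    bin_width: float = 0.01,
    fallback: float = 1200.0,
) -> UmiBound:
    """Locate the debris/cell trough of the nUMI histogram.

    The log10(nUMI) histogram is smoothed with a Gaussian kernel
    (``bandwidth`` decades); the threshold is the nUMI at the deepest local
    minimum strictly between the two dominant modes (ties resolved to the
    smallest nUMI).  If the smoothed histogram has no two modes, the
    configured ``fallback`` is returned with ``fallback_used=True``.
    """
    numi = np.asarray(numi, dtype=float)
    numi = numi[numi > 0]
    if numi.size < 100:
        raise ValidationError("need at least 100 positive nUMI values")
    log = np.log10(numi)
    if np.ptp(log) < 1e-12:
        warnings.warn("all nUMI equal; using fallback lower bound")
        return UmiBound(fallback, True)
    edges = np.arange(log.min() - 3 * bandwidth, log.max() + 3 * bandwidth + bin_width, bin_width)
    hist, _ = np.histogram(log, bins=edges)
    smooth = gaussian_filter1d(hist.astype(float), sigma=bandwidth / bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    interior = (smooth[1:-1] > smooth[:-2]) & (smooth[1:-1] >= smooth[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) < 2:
        warnings.warn("nUMI histogram is unimodal; using fallback lower bound")
        return UmiBound(fallback, True)
    # two most prominent modes bracket the debris/cell trough
    top2 = peaks[np.argsort(smooth[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        warnings.warn("modes not separated; using fallback lower bound")
        return UmiBound(fallback, True)
    inner = smooth[lo + 1 : hi]
    k = lo + 1 + int(np.argmin(inner))  # argmin takes the first (smallest nUMI) tie
    return UmiBound(float(10 ** centers[k]), False)


def apply_filters(
    adata: ad.AnnData,
    qc: pd.DataFrame,
    min_cells_per_gene: int = 3,
) -> ad.AnnData:
    """Remove failing cells first, then genes detected in fewer than
    ``min_cells_per_gene`` of the surviving cells."""
    if not set(adata.obs_names).issubset(qc.index):
        raise ValidationError("qc table does not cover all barcodes")
    keep = qc.loc[adata.obs_names, "pass"].to_numpy(dtype=bool)
    out = adata[keep].copy()
    if out.n_obs == 0:
        raise ValidationError("no cells survive QC")
    detected = sp.csr_matrix(out.X).getnnz(axis=0)
    out = out[:, detected >= min_cells_per_gene].copy()
    return out


def _pseudobulk(obj) -> pd.Series:
    """Summed per-gene expression from an AnnData, or a user-supplied bulk
    table (Series, or single-column / 'expression'-column DataFrame)."""
    if isinstance(obj, ad.AnnData):
        v = np.asarray(sp.csr_matrix(obj.X).sum(axis=0)).ravel()
        return pd.Series(v, index=obj.var_names)
    if isinstance(obj, pd.Series):
        return obj.astype(float)
    if isinstance(obj, pd.DataFrame):
        col = "expression" if "expression" in obj.columns else obj.columns[0]
        return obj[col].astype(float)
    raise ValidationError(f"cannot interpret {type(obj)} as expression table")


def pseudobulk_correlate(a, b, min_shared: int = 100) -> tuple[float, int]:
    """Pearson r of log1p summed expression over the shared gene symbols.

    Returns ``(r, n_shared_genes)``; raises if fewer than ``min_shared``
    genes are shared.
    """
    sa, sb = _pseudobulk(a), _pseudobulk(b)
    shared = sa.index.intersection(sb.index)
    if len(shared) < min_shared:
        raise ValidationError(f"only {len(shared)} shared genes (< {min_shared})")
    r, _ = pearsonr(np.log1p(sa.loc[shared]), np.log1p(sb.loc[shared]))
    return float(r), len(shared)
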