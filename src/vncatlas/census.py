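"""Neuropeptide expression census, extreme-expression statistics, and the
ambient-background vs bona fide expression split.

Preproneuropeptide genes are among the most highly expressed genes in the
nervous system: the census keeps panel genes reaching a per-cell raw count
threshold (default 10) in at least one cell, and the percentile-of-maxima
statistic ranks each gene's maximum observed count among the maxima of all
retained genes.  For a gene whose transcripts flood the ambient pool after
cell rupture, counts split into a low background band (1-10 counts, spread
across clusters) and bona fide expression (>= 100 counts, confined to the
true expressing cells)."""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ValidationError
from .panels import MarkerPanel

__all__ = [
    "census_neuropeptides",
    "max_expression_percentile",
    "transcriptome_fraction",
    "BackgroundSplit",
    "split_background_bonafide",
]


def _max_counts(adata: ad.AnnData) -> np.ndarray:
    X = sp.csc_matrix(adata.X)
    out = np.zeros(adata.n_vars)
    for j in range(adata.n_vars):
        seg = X.data[X.indptr[j] : X.indptr[j + 1]]
        if seg.size:
            out[j] = seg.max()
    return out


def census_neuropeptides(
    adata: ad.AnnData,
    np_panel: MarkerPanel | list[str],
    min_count: int = 10,
) -> pd.DataFrame:
    """Panel genes whose maximum raw count in any single cell reaches
    ``min_count``.  Returns a table (gene, max_count, n_cells_expressing),
    restricted to the passing genes."""
    genes = np_panel.genes if isinstance(np_panel, MarkerPanel) else list(np_panel)
    if not genes:
        raise ValidationError("empty neuropeptide panel")
    present = [g for g in genes if g in adata.var_names]
    X = sp.csc_matrix(adata.X)
    rows = []
    for g in present:
        j = adata.var_names.get_loc(g)
        seg = X.data[X.indptr[j] : X.indptr[j + 1]]
        mx = int(seg.max()) if seg.size else 0
        if mx >= min_count:
            rows.append({"gene": g, "max_count": mx, "n_cells_expressing": int((seg > 0).sum())})
    return pd.DataFrame(rows, columns=["gene", "max_count", "n_cells_expressing"])


def max_expression_percentile(adata: ad.AnnData, genes=None) -> pd.DataFrame:
    """Per-gene maximum observed count and its percentile among the maxima
    of all genes in the matrix (mean rank for ties, scaled to 0-100).

    ``genes`` restricts the *reported* rows; the percentile denominator is
    always every gene in the (filtered) matrix."""
    if adata.n_obs == 0 or adata.n_vars < 2:
        raise ValidationError("need a non-empty matrix with at least 2 genes")
    maxima = _max_counts(adata)
    pct = 100.0 * rankdata(maxima, method="average") / adata.n_vars
    df = pd.DataFrame(
        {
            "gene": adata.var_names,
            "max_count": maxima.astype(int),
            "rank": rankdata(maxima, method="average"),
            "percentile": pct,
        }
    ).set_index("gene")
    if genes is not None:
        keep = [g for g in genes if g in df.index]
        df = df.loc[keep]
    return df


def transcriptome_fraction(adata: ad.AnnData, gene: str, barcode: str) -> float:
    """Fraction of a cell's captured transcripts contributed by one gene."""
    if gene not in adata.var_names:
        raise ValidationError(f"unknown gene {gene!r}")
    if barcode not in adata.obs_names:
        raise ValidationError(f"unknown barcode {barcode!r}")
    i = adata.obs_names.get_loc(barcode)
    j = adata.var_names.get_loc(gene)
    row = np.asarray(sp.csr_matrix(adata.X)[i].todense()).ravel()
    total = row.sum()
    if total <= 0:
        raise ValidationError(f"cell {barcode!r} has zero total counts")
    return float(row[j] / total)


@dataclass
class BackgroundSplit:
    gene: str
    n_background_cells: int
    n_bonafide_cells: int
    n_indeterminate_cells: int
    background_cluster_spread: int
    n_clusters: int


def split_background_bonafide(
    adata: ad.AnnData,
    gene: str,
    labels,
    low: tuple[int, int] = (1, 10),
    high_cut: int = 100,
) -> BackgroundSplit:
    """Count cells in the ambient-background band (``low`` inclusive) and at
    or above ``high_cut`` (bona fide), plus how many clusters contain
    background cells.  Cells strictly between the bands are reported as
    indeterminate, never silently assigned."""
    lo, hi = low
    if hi >= high_cut:
        raise ValidationError(f"low band upper edge {hi} must be below high_cut {high_cut}")
    if gene not in adata.var_names:
        raise ValidationError(f"gene {gene!r} not present")
    labels = np.asarray(labels)
    y = np.asarray(sp.csr_matrix(adata.X)[:, adata.var_names.get_loc(gene)].todense()).ravel()
    back = (y >= lo) & (y <= hi)
    bona = y >= high_cut
    indet = (y > hi) & (y < high_cut)
    return BackgroundSplit(
        gene=gene,
        n_background_cells=int(back.sum()),
        n_bonafide_cells=int(bona.sum()),
        n_indeterminate_cells=int(indet.sum()),
        background_cluster_spread=int(pd.unique(labels[back]).size),
        n_clusters=int(pd.unique(labels).size),
    )
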