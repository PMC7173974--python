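"""Per-cluster average expression profiles and negative-binomial marker
detection with the published gates (ln fold change >= 0.5, Bonferroni
adjusted p < 0.05, positive markers only)."""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._nb import nb_lrt
from .errors import ValidationError
from .preprocess import log_normalize

__all__ = ["cluster_average_expression", "find_markers_nb"]


def cluster_average_expression(
    values,
    labels,
    genes,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Cluster x gene average expression table.

    For the ``lognorm`` layer the average is taken in expression space
    (mean of expm1, re-logged); for the ``scaled`` layer it is the plain
    arithmetic mean of the z-scored values.
    """
    labels = np.asarray(labels)
    if sp.issparse(values):
        values = np.asarray(values.todense())
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(labels):
        raise ValidationError("labels do not cover all cells")
    rows = {}
    for lab in pd.unique(labels):
        m = labels == lab
        if m.sum() == 0:
            raise ValidationError(f"empty cluster {lab}")
        if layer == "lognorm":
            rows[lab] = np.log1p(np.expm1(values[m]).mean(axis=0))
        elif layer == "scaled":
            rows[lab] = values[m].mean(axis=0)
        else:
            raise ValidationError(f"unknown layer {layer!r}")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(genes))
    return df.sort_index()


def find_markers_nb(
    adata: ad.AnnData,
    labels,
    covariates: pd.DataFrame | None = None,
    logfc_min: float = 0.5,
    alpha: float = 0.05,
    min_pct: float = 0.1,
    min_cells: int = 3,
    genes=None,
    scale: float = 1e4,
) -> pd.DataFrame:
    """One-vs-rest NB marker test per (gene, cluster).

    Counts are modelled as NB with a log(nUMI) offset; the cluster indicator
    is the tested term (likelihood-ratio p-value).  Genes are pre-screened
    to those detected in at least ``min_pct`` of in-cluster cells.  Reported
    rows satisfy avg_logFC >= ``logfc_min`` (positive markers only) and
    Bonferroni-adjusted p < ``alpha``; Bonferroni is over all (gene, cluster)
    tests actually performed.  ``covariates`` with a ``replicate`` column
    switches to a full NB regression including replicate terms.

    Fold change: ln of the ratio of (mean expm1 log-normalised expression
    + 1) inside vs outside the cluster, matching the convention the 0.5
    gate was printed for.
    """
    labels = np.asarray(labels)
    X = sp.csr_matrix(adata.X)
    N = np.asarray(X.sum(axis=1)).ravel().astype(float)
    ln = log_normalize(X, scale=scale)
    expr = ln.copy()
    expr.data = np.expm1(expr.data)

    gene_names = np.asarray(adata.var_names)
    if genes is not None:
        cols = np.flatnonzero(np.isin(gene_names, np.asarray(genes)))
    else:
        cols = np.arange(len(gene_names))

    use_covariates = covariates is not None and "replicate" in getattr(covariates, "columns", [])
    if use_covariates:
        rep_dummies = pd.get_dummies(covariates["replicate"], drop_first=True).to_numpy(float)

    records: list[dict] = []
    n_tests = 0
    for lab in pd.unique(labels):
        m = labels == lab
        if m.sum() < min_cells:
            warnings.warn(f"cluster {lab}: fewer than {min_cells} cells, skipped")
            continue
        Xin, Xout = X[m], X[~m]
        pct1 = Xin.getnnz(axis=0) / m.sum()
        pct2 = Xout.getnnz(axis=0) / (~m).sum()
        mean_in = np.asarray(expr[m].mean(axis=0)).ravel()
        mean_out = np.asarray(expr[~m].mean(axis=0)).ravel()
        logfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        screened = cols[(pct1[cols] >= min_pct) & (logfc[cols] > 0)]
        for j in screened:
            y = np.asarray(X[:, j].todense()).ravel()
            if use_covariates:
                p = _nb_regression_p(y, N, m, rep_dummies)
                fb = False
            else:
                p, _, fb = nb_lrt(y, N, m)
            n_tests += 1
            records.append(
                {
                    "gene": gene_names[j],
                    "cluster": lab,
                    "avg_logFC": logfc[j],
                    "p_val": p,
                    "pct.1": pct1[j],
                    "pct.2": pct2[j],
                    "dispersion_fallback": fb,
                }
            )
    if not records:
        return pd.DataFrame(
            columns=["gene", "cluster", "avg_logFC", "p_val", "p_val_adj", "pct.1", "pct.2", "dispersion_fallback"]
        )
    df = pd.DataFrame(records)
    df["p_val_adj"] = np.minimum(df["p_val"] * n_tests, 1.0)
    df = df[(df["avg_logFC"] >= logfc_min) & (df["p_val_adj"] < alpha)]
    df = df.sort_values(["cluster", "p_val_adj", "gene"]).reset_index(drop=True)
    return df[["gene", "cluster", "avg_logFC", "p_val", "p_val_adj", "pct.1", "pct.2", "dispersion_fallback"]]


def _nb_regression_p(y, N, in_cluster, rep_dummies) -> float:
    """NB regression LR p-value with replicate covariates (statsmodels)."""
    import statsmodels.api as sm
    from scipy.stats import chi2

    base = np.hstack([np.ones((len(y), 1)), rep_dummies])
    full = np.hstack([base, in_cluster.astype(float)[:, None]])
    offset = np.log(N)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = sm.NegativeBinomial(y, base, offset=offset).fit(disp=0, maxiter=200)
        m1 = sm.NegativeBinomial(y, full, offset=offset).fit(disp=0, maxiter=200)
    stat = max(2.0 * (m1.llf - m0.llf), 0.0)
    return float(chi2.sf(stat, df=1))
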