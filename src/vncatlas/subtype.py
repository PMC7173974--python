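"""Sub-clustering of selected cell subsets (monoaminergic, glial) and
biomarker-based subtype labelling.

Presets mirror the published sub-analyses: monoaminergic cells are Vmat
expressing cells drawn from Vmat-enriched clusters (7 dimensions,
resolution 1.2); the glial run takes cells of glial-classified clusters
after removing any cell expressing a neuronal gene (elav, nSyb, VAChT,
VGlut, Gad1; 6 dimensions, resolution 0.9).  "Expressing" for exclusion
gates means raw count > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .preprocess import (
    cca_reduce,
    cluster_louvain,
    log_normalize,
    regress_and_scale,
    select_variable_genes,
)

__all__ = ["SubclusterRun", "subcluster_cells", "label_by_biomarkers", "PRESETS"]

PRESETS = {
    "monoaminergic": {
        "select_genes": ["Vmat"],
        "exclude_genes": [],
        "dims": 7,
        "resolution": 1.2,
        "min_cluster_gene_pct": 0.5,
    },
    "glial": {
        "select_genes": [],
        "exclude_genes": ["elav", "nSyb", "VAChT", "VGlut", "Gad1"],
        "dims": 6,
        "resolution": 0.9,
        "select_classes": ["glial"],
    },
}


@dataclass
class SubclusterRun:
    cell_index: np.ndarray  # positions of the selected cells in the parent
    barcodes: list[str]
    labels: np.ndarray
    dims: int
    resolution: float
    selection_rule: dict = field(default_factory=dict)
    subtype_labels: dict = field(default_factory=dict)  # subcluster -> label

    @property
    def n_subclusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _gene_counts(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    idx = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
    if not idx:
        return np.zeros((adata.n_obs, 0))
    return np.asarray(sp.csr_matrix(adata.X)[:, idx].todense())


def subcluster_cells(
    adata: ad.AnnData,
    labels,
    select: dict,
    exclude_genes: list[str] | None = None,
    dims: int = 7,
    resolution: float = 1.2,
    seed: int = 42,
    covariates: pd.DataFrame | None = None,
) -> SubclusterRun:
    """Re-cluster a rule-selected subset of cells.

    ``select`` is a dict with any of:

    * ``genes``: keep cells with raw count > 0 for at least one listed gene
    * ``clusters``: restrict to these parent cluster labels
    * ``classes`` + ``class_per_cluster``: restrict by annotated class
    * ``min_cluster_gene_pct``: with ``genes``, restrict to parent clusters
      where at least this fraction of cells detect a selection gene

    ``exclude_genes`` removes any selected cell with count > 0 for a gated
    gene.  Variable genes, scaling and CCA (between sexes, when present in
    ``covariates``) are re-run on the subset before Louvain clustering.
    """
    labels = np.asarray(labels)
    exclude_genes = exclude_genes or []
    keep = np.ones(adata.n_obs, dtype=bool)

    sel_genes = select.get("genes", [])
    if sel_genes:
        gc = _gene_counts(adata, sel_genes)
        if gc.shape[1] == 0:
            raise ValidationError(f"selection genes {sel_genes} absent from matrix")
        detected = (gc > 0).any(axis=1)
        keep &= detected
        pct_min = select.get("min_cluster_gene_pct")
        if pct_min:
            ok_clusters = {
                lab
                for lab in pd.unique(labels)
                if detected[labels == lab].mean() >= pct_min
            }
            keep &= np.isin(labels, list(ok_clusters))
    if "clusters" in select:
        keep &= np.isin(labels, list(select["clusters"]))
    if "classes" in select:
        cls = select["class_per_cluster"]
        ok = set(cls.index[cls.isin(select["classes"])])
        keep &= np.isin(labels, list(ok))

    if exclude_genes:
        gc = _gene_counts(adata, exclude_genes)
        if gc.shape[1]:
            keep &= ~(gc > 0).any(axis=1)

    if not keep.any():
        raise ValidationError("selection rule matches zero cells")
    sub = adata[keep].copy()
    idx = np.flatnonzero(keep)

    ln = log_normalize(sub)
    cov = covariates.loc[sub.obs_names] if covariates is not None else sub.obs
    sexes = cov["sex"].to_numpy() if "sex" in cov else None
    groups = sexes if (sexes is not None and len(pd.unique(sexes)) == 2) else None
    var_genes = select_variable_genes(ln, sub.var_names, groups=groups)
    cols = np.flatnonzero(sub.var_names.isin(var_genes))

    # small-subset neighbourhood: cap k below the expected block size
    k = int(min(30, max(10, sub.n_obs // 10)))
    if groups is not None:
        order = []
        blocks = []
        for s in pd.unique(sexes):
            m = sexes == s
            order.append(np.flatnonzero(m))
            blocks.append(regress_and_scale(ln[m], cov[m], columns=cols))
        d = min(dims, min(b.shape[0] for b in blocks) - 1, len(cols) - 1)
        space = cca_reduce(blocks[0], blocks[1], d=d)
        emb = np.empty((sub.n_obs, d))
        emb[np.concatenate(order)] = space.embedding
    else:
        scaled = regress_and_scale(ln, cov, columns=cols)
        d = min(dims, scaled.shape[1] - 1, scaled.shape[0] - 1)
        u, s, _ = np.linalg.svd(scaled - scaled.mean(axis=0), full_matrices=False)
        emb = u[:, :d] * s[:d]

    clus = cluster_louvain(emb, resolution=resolution, k_neighbors=min(k, sub.n_obs - 1), seed=seed)
    return SubclusterRun(
        cell_index=idx,
        barcodes=list(sub.obs_names),
        labels=clus.labels,
        dims=d,
        resolution=resolution,
        selection_rule={"select": select, "exclude": exclude_genes},
    )


def label_by_biomarkers(
    run: SubclusterRun,
    lognorm,
    genes,
    biomarker_map: dict[str, list[str]],
) -> dict:
    """Label each subcluster by the subtype whose biomarker shows the
    largest positive margin of average log-normalised expression over the
    mean of the other subclusters (so two subclusters of the same subtype do
    not cancel each other).  Subclusters with no positive margin stay
    unlabeled (None); exact ties emit a warning and stay unlabeled."""
    genes = list(genes)
    labels = run.labels
    V = lognorm
    if sp.issparse(V):
        V = np.asarray(V.todense())
    out: dict = {}
    n_sub = run.n_subclusters
    means = {}
    for subtype, markers in biomarker_map.items():
        cols = [genes.index(g) for g in markers if g in genes]
        if not cols:
            continue
        sig = V[:, cols].mean(axis=1)
        means[subtype] = np.array([sig[labels == c].mean() for c in range(n_sub)])
    for c in range(n_sub):
        margins = []
        for subtype, m in means.items():
            other = np.delete(m, c)
            margin = m[c] - (other.mean() if other.size else 0.0)
            margins.append((margin, subtype))
        margins.sort(reverse=True)
        if not margins or margins[0][0] <= 0:
            out[c] = None
        elif len(margins) > 1 and abs(margins[0][0] - margins[1][0]) < 1e-12:
            warnings.warn(f"subcluster {c}: tied biomarker margins, left unlabeled")
            out[c] = None
        else:
            out[c] = margins[0][1]
    run.subtype_labels = out
    return out
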